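# Methods

This note documents the models, parameter choices, numerical conventions,
and validation design behind `stressglm`, and states what the synthetic
cohort does and does not establish about real data.

## Paradigm and regressors

The default design is three phases (PreStress, Stress, PostStress) of five
blocks, each 60 s active task followed by 40 s rest, at TR 2 s: 1500 s of
task, 750 retained scans, plus 5 discarded dummy volumes (755 acquired).
Onsets are expressed relative to the first retained scan.

Regressors are built at microtime resolution (16 bins per TR, dt = 0.125 s)
and sampled at scan onsets after convolution.  The HRF is the canonical
double-gamma (peak delay 6 s, undershoot delay 16 s, unit dispersions,
peak:undershoot ratio 6, 32 s support), peak-normalized as a kernel.  For
convolution the kernel is rescaled to unit sum, so a sustained unit boxcar
plateaus at 1 and betas read directly as signal change per unit regressor
(per bpm for the HR modulator).  A delta kernel therefore reproduces the
boxcar exactly, which several tests exploit.

Parametric modulators are mean-centered before convolution and *not*
serially orthogonalized against the task regressor: centering alone leaves
both betas interpretable (task beta = response at the cohort's mean heart
rate), at the cost of a mild variance inflation when task and modulator
correlate.  Centering scope follows each model's contrast scope: across all
15 active blocks for the blockwise and volumewise models, within phase for
the phasewise model.  The volumewise modulator has support only on
active-block scans (centered over those scans), so a per-block-constant
volume trace reproduces the blockwise modulator exactly.

Drift is modeled by a discrete-cosine basis with periods ≥ 256 s,
K = floor(2·N·TR/cutoff) columns with the constant kept separate (11 drift
columns for the default design).  Onset-transient control analyses move the
first 10 s (or 20 s) of each active block into a separate regressor of no
interest and rebuild the task/modulator regressors on the remaining block
portion; block HR values are unchanged.

## Physiology

PPG is polyphase-resampled to 100 Hz (FIR anti-aliasing at 0.45·target
rate).  Beats are local maxima of the 0.5–8 Hz zero-phase band-passed
signal with adaptive prominence threshold 0.4 × rolling 10 s IQR (floored
at 30 % of the global IQR so dropouts do not admit noise peaks) and a 0.3 s
refractory period.

Inter-beat intervals are accepted when within physiological bounds
(300–2000 ms) and within ±12 % of the mean instantaneous HR of the last 50
accepted beats.  A pure running-mean rule self-locks after a sustained
genuine HR shift (the stale reference rejects everything that follows), so
the filter re-acquires: ten consecutive in-bounds rejections that are
mutually consistent (each within tolerance of their own mean) re-seed the
reference.  Isolated ectopic beats shift one beat by ±50 % of the local
interval, producing alternating short/long intervals that are never
mutually consistent — they remain rejected without exception.

Quality is rated on a 3-point surrogate for visual inspection: rating 1 if
the rejected fraction is < 5 % and the longest beat gap < 3 s; rating 2 if
< 15 % and < 10 s; otherwise 3.  Only rating 3 excludes a recording.

Blockwise HR is the mean of 60000/IBI over accepted intervals whose
midpoint falls in the block; volumewise HR linearly interpolates
instantaneous HR to scan midtimes with edge hold.  HF-HRV cubic-interpolates
instantaneous HR to a 4 Hz grid and integrates the linearly-detrended FFT
periodogram over 0.15–0.40 Hz in 300 s windows shifted by 30 s; window
values are stamped at window centers and averaged per active block (blocks
without a window center borrow the nearest one).

## First level and group level

Nuisance handling is two-stage.  Stage 1 residualizes each voxel against a
constant, linear trend, the six rigid-body motion parameters, their first
differences, and one-hot regressors for dvars spikes (median + 1.5·IQR
rule), re-adding the voxel mean.  Stage 2 (the model fit) includes CompCor
components — by default the top 5 left singular vectors of the
variance-normalized voxel series of the combined WM+CSF mask, sign-aligned
to their top-loading voxel; a config switch gives 5 per tissue — *and the
spike one-hots again*: stage 1 replaces spiked scans with the voxel mean,
and the resulting task-signal notch would otherwise bleed into task and
modulator betas (measurably inflating the null error rate before this was
fixed).  Subjects with mean framewise displacement (Power convention,
50 mm rotation radius) above 1.5 mm, or physio rating 3, are excluded with
a machine-readable reason.

Smoothing is a separable Gaussian, FWHM 6 mm converted to per-axis voxel
sigmas through the affine; periodic boundary handling keeps the global mean
exactly conserved (the synthetic brain never touches the volume edge, so
wrap-around mixes only zeros into zeros).

Voxelwise fits are plain OLS — no AR(1) prewhitening.  Within-subject
autocorrelation biases first-level t-values but not betas, and only betas
are forwarded to the random-effects group test, which is therefore
calibrated regardless (verified empirically below).  The group test is a
one-sample t across subjects per direction; family-wise error is controlled
by Bonferroni over in-mask voxels instead of random-field theory — exact or
conservative under any dependence, and directly testable by simulation.
Clusters form under 18-connectivity with extent threshold k ≥ 25.

## ROI statistics and behavior

ROI timecourses are the first right singular vector of the temporally
centered in-ROI voxel × time matrix, sign-aligned to the ROI mean series
and z-scored.  Block-locked averages take each phase's five active-block
onsets, average the 100 s active+rest segments within subject, then report
the across-subject mean with pointwise t-based 95 % confidence bands (no
multiplicity correction — a descriptive figure analog).

Model variants are compared per ROI by Cohen's d on per-subject mean betas,
d = (mean_a − mean_b)/√((var_a + var_b)/2), with a paired t-test p-value
since the same subjects underlie every variant.  Note the variants' betas
live in different units (per bpm, per bpm² of HF power, per unit contrast),
so d's sign and size reflect scale as well as sensitivity; the validation
checks its *ordinal* structure only.

Swing metrics: upswing = mean(Stress active-block HR) − mean(PreStress),
downswing = mean(Stress) − mean(PostStress), proportional downswing =
downswing/upswing (undefined below |upswing| = 0.1 bpm).  Rating
correlations are Pearson, with alpha divided by the Nyholt effective number
of tests m_eff = 1 + (M−1)(1 − Var(λ)/M) over the eigenvalues of the rating
correlation matrix, used unrounded.  Nyholt's estimate is not monotone
under duplicating a variable (duplicating one of four independent variables
raises it from 4 to 4.6); the Li–Ji estimator, which is better behaved
there, is available as `meff(..., method="liji")`.

## The synthetic cohort

The simulator is the package's testbed; its defaults *are* the study
conditions every validation number is computed under.

Heart rate: HR(t) = baseline + drive + wander + RSA, where baseline is
subject-level N(74, 8²) bpm truncated at ±2.5 sd (a screened cohort has no
extreme resting HR; an untruncated 4.2 σ draw once violated the 30–200 bpm
sanity guard), drive adds +2 bpm in every active block, +7 bpm in Stress
active blocks, and a 1 bpm onset transient, all passed through a 6 s
first-order lag (stress tachycardia rises over seconds, not instantly);
wander is Ornstein–Uhlenbeck with sd 2.5 bpm and 60 s timescale.  RSA is a
0.25 Hz sinusoid whose amplitude is 3 bpm at 70 bpm, falls linearly by
2.7 % per bpm of slow HR (clipped to [0.25, 2] × and capped at 5 % of HR so
beat-to-beat changes stay physiological and within the artifact filter's
tolerance on clean data), with a ±30 % between-subject factor.  This
bounded-linear amplitude map replaced an earlier log-linear one whose
heavy-tailed HF power made the pooled HR↔HF-HRV Pearson correlation
unstable between cohorts.  Beats come from time-rescaling the integrated
rate — exact and invertible.  Under these defaults the pooled HR↔HF-HRV
correlation across cohorts of 100–150 subjects sits near −0.5 (spread
roughly −0.56 to −0.42), and the recovered Stress elevation is ≈ 6.2 bpm of
the injected 7 (the rise lag eats the difference).

PPG: a gamma-shaped systolic pulse centered on each beat time, 0.2 Hz
baseline wander, white noise at the requested SNR (20 dB default; −20 dB
renders a recording the quality gate rejects), optional dropouts and
ectopics.

BOLD: a 24³ grid of 2 mm voxels (a desk-scale stand-in for a brain — small
enough for minutes-long end-to-end runs, large enough for genuine cluster
structure); a central "gray" sphere (task beta 0.5 % signal) containing
three radius-3 blobs — positive HR coupling +0.08 %/bpm ("insula-like"),
negative −0.08 %/bpm ("amygdala/hippocampus-like"), negative task coupling
("DMN-like") — plus disjoint WM and CSF spheres whose voxels carry two
shared low-frequency components that also leak (15 %) into gray, giving
CompCor something real to remove.  Noise is AR(1) (coefficient 0.3, sd 1 %
signal); drift is a slow cosine mixture below the 256 s cutoff; motion is a
small random walk with occasional spike frames that also bump global
intensity by 3 %.  Ratings are generated with item-level changes correlated
0.3 (arousal) and −0.3 (relaxation) with the true HR upswing, plus a shared
factor so the rating correlation matrix is non-diagonal and m_eff < M.

Cohorts written to disk are BIDS-like (events TSV, physio TSV.GZ + JSON,
motion TSV, BOLD NIfTI, truth masks and coupling maps, manifest with every
parameter and per-subject seed = master seed + index) and byte-identical
under a fixed seed (gzip members carry zero mtime and no filename).

What the simulator does *not* emulate: realistic vascular/respiratory fMRI
noise spectra, spatial heterogeneity of the HRF, susceptibility artifacts,
imperfect registration, or non-spherical anatomy.  Passing validation shows
the pipeline's statistics behave correctly under its own assumptions — it
does not show the assumptions hold in any particular dataset.

## Validation design and problem sizes

The validation suite (tests/test_acceptance.py, recomputed independently by
scripts/acceptance.py) uses these study sizes, chosen to preserve the
statistical structure at desk scale:

* parameter recovery: 10 replicates of the default cohort — 20 subjects,
  24³ grid, 750 scans; blob-sign recovery requires the negative-direction
  map to intersect the negative blob and not the positive one (and vice
  versa) in ≥ 95 % of replicates;
* type-I error: 200 null cohorts (zero HR coupling) of 10 subjects on a
  16³ grid with a shortened 3-phase × 2-block paradigm.  The uncorrected
  p < 0.05 rate is measured on *unsmoothed* fits: smoothing leaves the
  per-voxel test exactly calibrated (a precise 300-replicate run gave
  0.051 ± 0.010) but correlates the small grid's voxels so strongly that
  one replicate's rate scatters with sd ≈ 0.18, making a 200-replicate
  band check uninformative; without smoothing the estimator's standard
  error is ≈ 0.002.  The Bonferroni FWE arm keeps the full smoothed chain,
  since robustness to exactly that dependence is Bonferroni's guarantee;
* physio QC: 88 subjects, the last 5 rendered at −20 dB SNR;
* calibration: 100 subjects for the pooled HR↔HF-HRV correlation; five
  83-subject cohorts (median) for the upswing↔arousal recovery;
* GLM oracle: 50 random 20×5 designs against statsmodels OLS.

## Known limitations

* OLS without prewhitening understates first-level standard errors under
  AR(1) noise; only group-level inference is calibrated.  A Cochrane–Orcutt
  hook would slot into `fit_glm` if first-level inference were needed.
* Bonferroni is conservative for smooth maps; real studies using
  random-field theory will report lower voxel thresholds.
* The Nyholt m_eff caveat above.
* The quality surrogate is tuned to this simulator's artifact modes
  (noise, dropouts); real PPG pathologies (motion artifacts, perfusion
  loss) may need different thresholds.
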