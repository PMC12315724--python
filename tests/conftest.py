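import numpy as np
import pytest

import stressglm as sg


@pytest.fixture(scope="session")
def design():
    """The default 3-phase x 5-block paradigm (750 retained scans, TR 2 s)."""
    return sg.default_design()


@pytest.fixture(scope="session")
def short_design():
    """A scaled-down paradigm for fast end-to-end runs (150 scans)."""
    return sg.default_design(blocks_per_phase=2, active_s=30.0, rest_s=20.0,
                             n_dummy=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def truth():
    return sg.GroundTruth()


@pytest.fixture(scope="session")
def simulated_subject(design, truth):
    """One default-scale subject: HR process, PPG, and its IBI chain."""
    import stressglm.physio as ph
    rng = np.random.default_rng(42)
    proc = sg.simulate_hr_process(design, truth, rng)
    rec = sg.render_ppg(proc.beat_times, seed_or_rng=rng,
                        duration=design.duration)
    beats, quality = sg.detect_beats(rec)
    ibis = sg.filter_ibis(beats)
    return {"proc": proc, "rec": rec, "beats": beats, "quality": quality,
            "ibis": ibis}
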