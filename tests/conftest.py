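import pytest
from hypothesis import settings

from hoofbeat import analyze_trial, make_template, simulate_trial

settings.register_profile("det", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def wb_trot_trial():
    """Noiseless Warmblood trot, published defaults, 5 strides."""
    return simulate_trial(make_template("trot", "warmblood",
                                        n_strides=5, seed=0))


@pytest.fixture(scope="session")
def wb_trot_table(wb_trot_trial):
    return analyze_trial(wb_trot_trial)


@pytest.fixture(scope="session")
def ideal_walk_trial():
    """Lateral-sequence walk with equally spaced footfalls (0/25/50/75)."""
    tpl = make_template("walk", "warmblood",
                        {"lateral_dissociation_pct": 25.0,
                         "diagonal_dissociation_pct": -25.0,
                         "stride_duration_s": 1.1,
                         "stance_duration_fl_s": 0.72,
                         "stance_duration_hl_s": 0.63,
                         "n_strides": 5, "seed": 0})
    return simulate_trial(tpl)


@pytest.fixture(scope="session")
def ideal_walk_table(ideal_walk_trial):
    return analyze_trial(ideal_walk_trial)
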