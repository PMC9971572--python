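import pytest

import canophot as cp

#: generating truth on the measurement scale of the fitting protocol
TRUTH = cp.LeafPhotoParams(Vcmax25=140.4, Jmax25=214.7, TPU25=12.3,
                           Rd25=1.0, gm25=0.25)


@pytest.fixture(scope="session")
def truth_leaf():
    return TRUTH


@pytest.fixture(scope="session")
def clean_cfg():
    return cp.SyntheticConfig(truth=TRUTH, seed=12345)


@pytest.fixture(scope="session")
def aci_records(clean_cfg):
    return cp.synth_aci_curve(clean_cfg)


@pytest.fixture(scope="session")
def low_o2_records(clean_cfg):
    return cp.synth_low_o2_light_response(clean_cfg)


@pytest.fixture(scope="session")
def trial_fixture():
    return cp.synth_trial_fixture()


@pytest.fixture(scope="session")
def tillering_weather():
    return cp.stage_weather("tillering")


@pytest.fixture(scope="session")
def tillering_states(trial_fixture):
    return {cv: trial_fixture[(cv, "tillering")].canopy
            for cv in cp.synthetic.CULTIVARS}
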