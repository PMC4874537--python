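import pytest

from spinevolt import cable, synth


@pytest.fixture(scope="session")
def cfg():
    return synth.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def tree_model():
    """Default synthetic L5-like tree at the fine spatial grid."""
    return cable.discretize(cable.synthetic_l5_tree(), cable.PassiveParams(),
                            max_fraction_of_lambda=0.02)


@pytest.fixture(scope="session")
def attenuation_curves(tree_model):
    """Per-R_neck attenuation curves reused across cable/pipeline tests."""
    spine = cable.SpineSynapse(g_syn_ns=0.5)
    curves, _ = cable.scan_locations(
        tree_model, spine, (1.0, 100.0, 200.0, 350.0, 500.0, 700.0), n_sites=31)
    return curves
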