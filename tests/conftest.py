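import pytest

from cytopipe.gating import default_gate_tree
from cytopipe.panel import default_panel
from cytopipe.synthetic import SampleMeta, TruthConfig, make_truth


@pytest.fixture(scope="session")
def truth():
    """Default study-shaped truth: 3 groups x 8 animals, fixed seed."""
    return make_truth(TruthConfig(), seed=1)


@pytest.fixture(scope="session")
def small_truth():
    """Smaller experiment (3 groups x 3 animals) for faster module tests."""
    cfg = TruthConfig()
    cfg.groups = {g: 3 for g in cfg.groups}
    return make_truth(cfg, seed=7)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def tree():
    return default_gate_tree()


@pytest.fixture
def meta():
    return SampleMeta(animal_id="mock01", group="mock", tissue="PBMC",
                      stim="UNSTIM", barcode_code=(1, 1, 0, 1, 0, 0))
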