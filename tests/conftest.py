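import pytest

from qmdial import ExperimentConfig


@pytest.fixture
def std_config():
    """Standard HPLC system: 80 µM protein, ligand equilibrating to 50 µM,
    100/300 µL chambers, perfectly equilibrating compound."""
    return ExperimentConfig(red_volume=100, white_volume=300, l0=50, t0=80, pc=1.0)


@pytest.fixture
def fig_config():
    """The simulated system behind the printed partition-ratio examples
    (ligand equilibrating to 25 µM)."""
    return ExperimentConfig(red_volume=100, white_volume=300, l0=25, t0=80, pc=1.0)
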