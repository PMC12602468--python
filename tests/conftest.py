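import numpy as np
import pytest

from tpdcflow import TimeSeriesSet, make_template, simulate_subject


@pytest.fixture
def diag_template():
    """Seven independent AR(1) channels, self-coupling 0.5."""
    return make_template("custom", 0.0, 0.5, edges=())


@pytest.fixture
def coupled_template():
    """Older-control template at coupling 0.4 (five directed edges)."""
    return make_template("old_hc", 0.4, 0.5)


@pytest.fixture
def short_series(coupled_template):
    """One simulated subject, T=300, seeded."""
    return simulate_subject(coupled_template, 300, seed=42, subject_id="s300")


@pytest.fixture
def white_series():
    """Pure white-noise series (no dynamics at all), T=400."""
    rng = np.random.default_rng(7)
    return TimeSeriesSet(
        subject_id="white",
        data=rng.normal(size=(400, 7)),
        channels=("VIS", "SMN", "DAN", "VAN", "LIN", "FPN", "DMN"),
        tr=2.0,
    )
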