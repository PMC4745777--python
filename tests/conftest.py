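import numpy as np
import pytest

from synscreen.dose_response import DoseSeries, FourPLFit
from synscreen.synthetic_data import (
    TrueCurve,
    default_combo_grid,
    default_single_agent_grid,
    simulate_single_agent,
)


@pytest.fixture
def unit_curve() -> TrueCurve:
    """Clean reference curve: top=100, bottom=0, ic50=1 μM, hill=1."""
    return TrueCurve(top=100.0, bottom=0.0, ic50=1.0, hill=1.0)


@pytest.fixture
def unit_fit() -> FourPLFit:
    """Exact 4PL parameters matching unit_curve, as a converged fit."""
    return FourPLFit(top=100.0, bottom=0.0, ic50=1.0, hill=1.0,
                     dose_range=(0.01, 100.0), converged=True, rss=0.0)


@pytest.fixture
def sa_grid() -> tuple[float, ...]:
    return default_single_agent_grid()


@pytest.fixture
def combo_grid() -> tuple[float, ...]:
    return default_combo_grid()


@pytest.fixture
def clean_series(unit_curve, sa_grid) -> DoseSeries:
    """Noise-free series generated from unit_curve on the default grid."""
    return simulate_single_agent(unit_curve, sa_grid, 0.0, 1, 0, "clean")


def random_curve(rng: np.random.Generator,
                 ic50_log10=(-1.0, 1.0), hill=(0.8, 1.5),
                 bottom=(0.0, 0.0)) -> TrueCurve:
    """Draw a random true curve (top fixed at 100)."""
    return TrueCurve(
        top=100.0,
        bottom=float(rng.uniform(*bottom)),
        ic50=float(10.0 ** rng.uniform(*ic50_log10)),
        hill=float(rng.uniform(*hill)),
    )
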