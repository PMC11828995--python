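import warnings

import numpy as np
import pytest

from bonechem import synthetic as syn
from bonechem.spectra import Spectrum

warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", category=FutureWarning)


def gaussian_spectrum(center, sigma, amplitude=1.0, grid=(400.0, 4000.0, 2.0), baseline=0.0):
    """Single-Gaussian test spectrum on a uniform grid."""
    lo, hi, step = grid
    wn = np.arange(lo, hi + 0.5 * step, step)
    y = amplitude * np.exp(-0.5 * ((wn - center) / sigma) ** 2) + baseline
    return Spectrum(wn, y)


@pytest.fixture(scope="session")
def unit_profiles():
    """Shipped, pre-calibrated per-unit generating profiles."""
    return {p.unit: p for p in syn.default_unit_profiles()}


@pytest.fixture(scope="session")
def cohort():
    """Default 150-sample feature cohort (30 per fossil unit), seed 0."""
    return syn.generate_cohort_features(syn.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def giia_spectra(unit_profiles):
    """Seeded 30-spectrum batch for the basal subunit."""
    return syn.generate_spectra(unit_profiles["GIIa"], syn.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def giia_panel(giia_spectra):
    """Full index panel over the GIIa batch (shared: the pipeline is slow)."""
    from bonechem.chemometrics import INDEX_COLUMNS, compute_profile

    panel = {c: [] for c in INDEX_COLUMNS.values()}
    for s in giia_spectra:
        p = compute_profile(s)
        for attr, col in INDEX_COLUMNS.items():
            panel[col].append(getattr(p, attr))
    return {c: np.asarray(v) for c, v in panel.items()}
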