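"""Shared fixtures: synthetic carpets at the reference study conditions.

The expensive Brownian-dynamics simulations are session-scoped and shared
between the unit, property and acceptance tests.  All seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

import pcfscan as p
from pcfscan import workflows as wf


@pytest.fixture(scope="session")
def small_free_sim() -> p.SimResult:
    """Short uniform free-diffusion carpet for estimator-level tests."""
    cfg = p.paper_scan_config(n_lines=4096, burn_in_s=0.2, seed=7)
    return p.simulate_carpet(cfg)


@pytest.fixture(scope="session")
def nuclear_sim() -> tuple[p.DiffusionFit, p.SimResult]:
    """Nuclear-compartment analog: uniform D = 12.5 µm²/s, 6e4 lines."""
    return wf.compartment_d_experiment(12.5, n_lines=60_000, seed=1)


@pytest.fixture(scope="session")
def cyto_sim() -> tuple[p.DiffusionFit, p.SimResult]:
    """Cytoplasmic-compartment analog: uniform D = 5.5 µm²/s, 6e4 lines."""
    return wf.compartment_d_experiment(5.5, n_lines=60_000, seed=2)


@pytest.fixture(scope="session")
def passive_barrier_exp() -> wf.BarrierExperiment:
    """Two-compartment records with the barrier calibrated to a 250 ms mean
    first-crossing time; cell-pooled nucleus-to-cytoplasm pCF(14)."""
    return wf.passive_barrier_experiment(target_crossing_s=0.25, seed=3)


@pytest.fixture(scope="session")
def active_exp() -> tuple[wf.BarrierExperiment, p.PeakDetection | None]:
    """Directional-import analog (capture probability 0.5, 5 ms mean
    translocation dwell) plus the backward-direction peak."""
    return wf.active_import_experiment(target_crossing_s=0.25, seed=4)


@pytest.fixture(scope="session")
def depleted_exp(passive_barrier_exp) -> wf.BarrierExperiment:
    """Energy-depletion analog: the passive-only record read in the
    cytoplasm-to-nucleus sense at the active-experiment separation.
    Passive exchange is direction-symmetric, so the passive carpet is
    re-analyzed rather than re-simulated."""
    exp = passive_barrier_exp
    peak = wf.cross_barrier_pcf_delay(
        exp.results, delta_pixels=14, direction="cyto_to_nuc"
    )
    return wf.BarrierExperiment(
        peak=peak,
        p_cross=exp.p_cross,
        achieved_crossing_s=exp.achieved_crossing_s,
        results=exp.results,
        direction="cyto_to_nuc",
        delta_pixels=14,
    )


@pytest.fixture(scope="session")
def gap_exp() -> tuple[p.SimResult, list]:
    """Impenetrable-gap control (p_cross = 0) and its cross-gap peaks."""
    return wf.gap_experiment(n_lines=40_000, delta_pixels=7, seed=5)


@pytest.fixture(scope="session")
def dye_calibration() -> tuple[p.DiffusionFit, p.SimResult]:
    """Fast-dye instrument calibration analog (D = 300 µm²/s, point scan)."""
    return wf.dye_calibration_experiment(seed=6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def poisson_carpet(
    rng: np.random.Generator,
    n_lines: int = 2048,
    n_pixels: int = 8,
    mean: float = 5.0,
) -> p.LineScanCarpet:
    """I.i.d. Poisson carpet (no dynamics) for null-distribution tests."""
    return p.LineScanCarpet(
        counts=rng.poisson(mean, size=(n_lines, n_pixels)),
        pixel_size_um=0.1,
        pixel_dwell_s=6.3e-6,
        line_period_s=4.73e-4,
    )
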