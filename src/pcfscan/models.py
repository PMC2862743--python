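"""Closed-form diffusion models for a Gaussian focal volume, and fitting.

For free 3D diffusion through the Gaussian observation profile the
autocorrelation is

    G(tau) = (gamma / N) (1 + 4 D tau / w0^2)^-1 (1 + 4 D tau / wz^2)^-1/2

and the two-focus (pair) correlation at a displacement ``delta`` along the
scan axis multiplies this by ``exp(-delta^2 / (w0^2 + 4 D tau))``.  The
shape-factor convention is gamma = 1: the amplitude is absorbed into the
apparent occupancy N, which leaves D and the pair-correlation peak time —
the readouts this package actually uses — unaffected.

The mean-field pair-correlation model is non-negative everywhere.  The
*measured* estimator can go negative at short lags for separations beyond
the waist: with a fixed total number of molecules, occupancy fluctuations
at two disjoint spots anti-correlate (one molecule cannot be in two places
at once).  That single-molecule dip is real signal in the data and simply
absent from this mean-concentration model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .correlate import CorrelationCurve
from .errors import FitInfeasibleError, ValidationError
from .psf import DEFAULT_KAPPA, PSFModel

_MODEL_IDS = ("3d_1comp", "3d_2comp")


def model_acf_3d(tau, n_molecules: float, d: float, psf: PSFModel):
    """3D free-diffusion ACF; ``tau`` may be a scalar or array (seconds)."""
    if n_molecules <= 0 or d <= 0:
        raise ValidationError("n_molecules and d must be positive")
    tau = np.asarray(tau, dtype=np.float64)
    t = 4.0 * d * tau
    return (1.0 / n_molecules) / (1.0 + t / psf.w0_um**2) / np.sqrt(1.0 + t / psf.wz_um**2)


def model_pcf_3d(tau, n_molecules: float, d: float, psf: PSFModel, delta_um: float):
    """Two-focus correlation for foci ``delta_um`` apart along the scan axis."""
    if delta_um < 0:
        raise ValidationError("delta_um must be >= 0")
    tau = np.asarray(tau, dtype=np.float64)
    return model_acf_3d(tau, n_molecules, d, psf) * np.exp(
        -(delta_um**2) / (psf.w0_um**2 + 4.0 * d * tau)
    )


class PeakTime(NamedTuple):
    """Analytic pair-correlation peak time.

    ``tau_peak_s`` maximizes the full 3D model numerically;
    ``tau_peak_2d_s`` is the 2D-limit closed form (delta^2 - w0^2)/(4 D),
    returned alongside as a reference.
    """

    tau_peak_s: float
    tau_peak_2d_s: float


def peak_time_theory(d: float, delta_um: float, psf: PSFModel) -> PeakTime:
    """Lag of the pair-correlation maximum for free diffusion.

    Defined for separations beyond the waist (closer pairs peak at
    tau -> 0 because the two observation volumes overlap).
    """
    if d <= 0:
        raise ValidationError("d must be positive")
    if delta_um <= psf.w0_um:
        raise ValidationError(
            f"peak time requires delta_um > w0 ({delta_um} <= {psf.w0_um})"
        )
    tau_2d = (delta_um**2 - psf.w0_um**2) / (4.0 * d)

    def neg(log_tau: float) -> float:
        return -float(model_pcf_3d(np.exp(log_tau), 1.0, d, psf, delta_um))

    res = minimize_scalar(
        neg,
        bounds=(np.log(tau_2d) - 6.0, np.log(tau_2d) + 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return PeakTime(float(np.exp(res.x)), float(tau_2d))


@dataclass
class DiffusionFit:
    """Result of fitting a correlation curve to a diffusion model.

    ``d`` is the (fast) diffusion coefficient in µm²/s; for the
    two-component model ``d_slow`` and ``fraction_slow`` describe the
    second species.  ``g0 = 1/n_molecules`` under the gamma = 1 convention.
    """

    model_id: str
    n_molecules: float
    d: float
    g0: float
    d_slow: float | None = None
    fraction_slow: float = 0.0
    baseline: float = 0.0
    stderr: dict = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = False
    n_points: int = 0
    fit_range_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.d <= 0:
            raise ValidationError("fitted N and D must be positive")
        if not 0.0 <= self.fraction_slow <= 1.0:
            raise ValidationError("fraction_slow must lie in [0, 1]")


def _initial_guess(lags: np.ndarray, vals: np.ndarray, psf: PSFModel) -> tuple[float, float]:
    g0 = max(vals[0], 1e-6)
    n0 = 1.0 / g0
    half = np.nonzero(vals < 0.5 * g0)[0]
    tau_half = lags[half[0]] if half.size else lags[-1]
    d0 = psf.w0_um**2 / (4.0 * tau_half)
    return n0, d0


def fit_acf(
    curve: CorrelationCurve,
    psf: PSFModel,
    model_id: str = "3d_1comp",
    fit_range: tuple[float, float] | None = None,
    fit_baseline: bool = False,
    max_nfev: int = 2000,
) -> DiffusionFit:
    """Weighted least-squares fit of an ACF to the 3D diffusion model.

    Weights are the inverse variance across contributing columns when the
    curve carries one (set by :func:`~pcfscan.correlate.average_curves`),
    else uniform.  Initialization: N from the first in-range amplitude, D
    from the half-decay lag.  Parameters are optimized in log space to
    enforce positivity; convergence is to relative tolerance 1e-8 and a
    non-converged solver is flagged on the result, never silent.

    The default fit range runs from the first lag to a quarter of the
    longest lag — the longest lags are dominated by drift and statistical
    noise.

    ``fit_baseline`` adds a free additive constant.  A record from a closed
    reservoir holding a *fixed* number of molecules carries a constant
    negative term of order -1/N_total (occupancy anti-correlation); the
    baseline absorbs it.  For cell data with a vast reservoir it is
    negligible and the option stays off.
    """
    if model_id not in _MODEL_IDS:
        raise ValidationError(f"unknown model_id {model_id!r}")
    lags = curve.lags_s
    vals = curve.values
    if fit_range is None:
        fit_range = (lags[0], lags[-1] / 4.0)
    mask = (lags >= fit_range[0]) & (lags <= fit_range[1])
    if mask.sum() < 8:
        raise ValidationError("fit range must contain at least 8 lags")
    lags_f = lags[mask]
    vals_f = vals[mask]
    if not np.any(vals_f > 0):
        raise FitInfeasibleError("curve is nowhere positive in the fit range")
    if curve.values_sem is not None:
        sem = curve.values_sem[mask]
        w = 1.0 / np.where(sem > 0, sem, np.max(sem[sem > 0]) if np.any(sem > 0) else 1.0)
    else:
        w = np.ones_like(vals_f)

    n0, d0 = _initial_guess(lags_f, vals_f, psf)

    if model_id == "3d_1comp":
        def shape(p: np.ndarray) -> np.ndarray:
            n, d = np.exp(p[:2])
            return model_acf_3d(lags_f, n, d, psf)

        p0 = [np.log(n0), np.log(d0)]
        names = ["n_molecules", "d"]
    else:
        def shape(p: np.ndarray) -> np.ndarray:
            n, d_fast, d_slow = np.exp(p[:3])
            frac = 1.0 / (1.0 + np.exp(-p[3]))
            return (
                (1.0 - frac) * model_acf_3d(lags_f, 1.0, d_fast, psf)
                + frac * model_acf_3d(lags_f, 1.0, d_slow, psf)
            ) / n

        p0 = [np.log(n0), np.log(d0), np.log(d0 / 20.0), 0.0]
        names = ["n_molecules", "d", "d_slow", "logit_fraction_slow"]

    n_shape = len(p0)
    if fit_baseline:
        p0.append(0.0)
        names.append("baseline")

        def resid(p: np.ndarray) -> np.ndarray:
            return (shape(p) + p[n_shape] - vals_f) * w
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            return (shape(p) - vals_f) * w

    res = least_squares(
        resid, np.asarray(p0), xtol=1e-8, ftol=1e-8, gtol=1e-10, max_nfev=max_nfev
    )
    converged = bool(res.status > 0)
    baseline = float(res.x[n_shape]) if fit_baseline else 0.0

    # standard errors via the Jacobian at the solution
    stderr: dict = {}
    try:
        jtj = res.jac.T @ res.jac
        dof = max(lags_f.size - res.x.size, 1)
        cov = np.linalg.inv(jtj) * 2.0 * res.cost / dof
        perr = np.sqrt(np.diag(cov))
        # delta method back from log space for the positive parameters
        for i, name in enumerate(names):
            if name.startswith("logit") or name == "baseline":
                stderr[name] = float(perr[i])
            else:
                stderr[name] = float(np.exp(res.x[i]) * perr[i])
    except np.linalg.LinAlgError:
        pass

    if model_id == "3d_1comp":
        n, d = np.exp(res.x[:2])
        return DiffusionFit(
            model_id=model_id,
            n_molecules=float(n),
            d=float(d),
            g0=float(1.0 / n),
            baseline=baseline,
            stderr=stderr,
            residual_norm=float(np.sqrt(2.0 * res.cost)),
            converged=converged,
            n_points=int(lags_f.size),
            fit_range_s=(float(fit_range[0]), float(fit_range[1])),
        )
    n, d_fast, d_slow = np.exp(res.x[:3])
    frac = float(1.0 / (1.0 + np.exp(-res.x[3])))
    if d_slow > d_fast:  # keep "slow" the slower component
        d_fast, d_slow = d_slow, d_fast
        frac = 1.0 - frac
    return DiffusionFit(
        model_id=model_id,
        n_molecules=float(n),
        d=float(d_fast),
        g0=float(1.0 / n),
        d_slow=float(d_slow),
        fraction_slow=frac,
        baseline=baseline,
        stderr=stderr,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
        n_points=int(lags_f.size),
        fit_range_s=(float(fit_range[0]), float(fit_range[1])),
    )


def calibrate_psf(
    curve: CorrelationCurve,
    d_known: float,
    kappa: float = DEFAULT_KAPPA,
    fit_kappa: bool = False,
    fit_range: tuple[float, float] | None = None,
) -> PSFModel:
    """Recover the beam waist from a calibration ACF with known D.

    The standard instrument calibration: record the autocorrelation of a
    dye of known diffusion coefficient (e.g. fluorescein) and fit w0 with D
    held fixed.  ``fit_kappa`` additionally frees the axial aspect ratio.
    """
    if d_known <= 0:
        raise ValidationError("d_known must be positive")
    lags = curve.lags_s
    vals = curve.values
    if fit_range is None:
        fit_range = (lags[0], lags[-1] / 4.0)
    mask = (lags >= fit_range[0]) & (lags <= fit_range[1])
    lags_f = lags[mask]
    vals_f = vals[mask]
    if not np.any(vals_f > 0):
        raise FitInfeasibleError("calibration curve is nowhere positive")

    g0 = max(vals_f[0], 1e-6)
    half = np.nonzero(vals_f < 0.5 * g0)[0]
    tau_half = lags_f[half[0]] if half.size else lags_f[-1]
    w0_0 = float(np.sqrt(4.0 * d_known * tau_half))

    def resid(p: np.ndarray) -> np.ndarray:
        n, w0 = np.exp(p[:2])
        kap = np.exp(p[2]) if fit_kappa else kappa
        psf = PSFModel(w0, max(kap, 1.0) * w0)
        return model_acf_3d(lags_f, n, d_known, psf) - vals_f

    p0 = [np.log(1.0 / g0), np.log(w0_0)]
    if fit_kappa:
        p0.append(np.log(kappa))
    res = least_squares(resid, np.array(p0), xtol=1e-10, ftol=1e-10, max_nfev=2000)
    w0 = float(np.exp(res.x[1]))
    kap = float(np.exp(res.x[2])) if fit_kappa else kappa
    return PSFModel(w0, max(kap, 1.0) * w0)
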