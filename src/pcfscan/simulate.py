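"""Brownian-dynamics line-scan simulator with a semi-permeable barrier.

The simulated experiment emulates a confocal line scan across the nuclear
envelope: fluorescent molecules diffuse in a closed box split into a left
("nucleus", by the convention that the scan runs nucleus to cytoplasm) and
a right ("cytoplasm") compartment by a semi-permeable plane.  Molecules
can cross the plane passively in both directions with a per-attempt
transmission probability, and optionally through a directional active
channel (capture with probability ``p_active`` on barrier contact,
exponential translocation dwell, release on the far side) — a minimal
mechanism for carrier-mediated import, not a mechanistic pore model.

Photon counts are Poisson with expectation
``background + brightness * sum_i W(r_i - beam)`` where W is the Gaussian
beam profile, evaluated once per pixel dwell.  The PSF is truncated beyond
3 w0 radially and 3 wz axially (relative error < 1e-7, large speedup).

A single integer seed expands into independent streams for the particle
trajectories (including translocation dwells), the photon shot noise and
the initial positions, so re-sampling photons never perturbs trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import _kernels
from .carpet import LineScanCarpet
from .errors import InfeasibleTargetError, ValidationError
from .psf import PSFModel

#: PSF truncation radii in units of the respective waist
_TRUNC_WAISTS = 3.0

_DIRECTIONS = ("left_to_right", "right_to_left")


def _dir_sign(direction: str) -> int:
    if direction not in _DIRECTIONS:
        raise ValidationError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return 1 if direction == "left_to_right" else -1


@dataclass(frozen=True)
class ScanGeometry:
    """Line-scan acquisition geometry (defaults: the 32-pixel, 6.3 µs dwell,
    0.473 ms line-period raster typical of fast confocal line scanning)."""

    n_pixels: int = 32
    pixel_size_um: float = 0.1
    pixel_dwell_s: float = 6.3e-6
    line_period_s: float = 4.73e-4
    direction: str = "left_to_right"

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValidationError("n_pixels must be >= 1")
        for name in ("pixel_size_um", "pixel_dwell_s", "line_period_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.line_period_s + 1e-12 < self.n_pixels * self.pixel_dwell_s:
            raise ValidationError("line_period_s < n_pixels * pixel_dwell_s")
        _dir_sign(self.direction)

    @property
    def retrace_s(self) -> float:
        return max(self.line_period_s - self.n_pixels * self.pixel_dwell_s, 0.0)

    @property
    def scan_length_um(self) -> float:
        return (self.n_pixels - 1) * self.pixel_size_um


@dataclass(frozen=True)
class ActiveTransport:
    """Directional capture-and-release channel across the barrier."""

    enabled: bool = False
    direction: str = "right_to_left"
    p_active: float = 0.5
    translocation_mean_s: float = 0.005

    def __post_init__(self) -> None:
        _dir_sign(self.direction)
        if not 0.0 <= self.p_active <= 1.0:
            raise ValidationError("p_active must lie in [0, 1]")
        if self.translocation_mean_s <= 0:
            raise ValidationError("translocation_mean_s must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full physical specification of a synthetic line-scan experiment.

    The box extends ``box_pad_um`` beyond both ends of the scanned line in
    x and ``box_ly_um`` / ``box_lz_um`` across/along the optical axis,
    centered on the line.  ``d_left`` / ``d_right`` are the diffusion
    coefficients on either side of ``barrier_x_um`` (µm²/s); without a
    barrier ``d_left`` applies everywhere.  ``brightness`` is the expected
    photon count per molecule per pixel dwell at the beam center and
    ``background`` the expected count per dwell from everything else.
    """

    scan: ScanGeometry = field(default_factory=ScanGeometry)
    psf: PSFModel = field(default_factory=lambda: PSFModel(0.25))
    box_pad_um: float = 0.75
    box_ly_um: float = 2.0
    box_lz_um: float = 5.0
    barrier_x_um: float | None = None
    gap_half_width_um: float = 0.0
    d_left: float = 12.5
    d_right: float = 12.5
    n_particles: int = 100
    brightness: float = 0.5
    background: float = 0.05
    p_cross: float = 1.0
    active: ActiveTransport = field(default_factory=ActiveTransport)
    n_lines: int = 60000
    burn_in_s: float = 5.0
    seed: int = 0
    init: str = "uniform"
    slow_fraction: float = 0.0
    d_slow: float | None = None

    def __post_init__(self) -> None:
        for name in ("box_pad_um", "box_ly_um", "box_lz_um", "d_left", "d_right"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if min(self.box_ly_um, self.box_lz_um) < 6.0 * self.psf.w0_um:
            raise ValidationError(
                "box_ly_um and box_lz_um must be >= 6 w0 (guard against wall artifacts)"
            )
        if not 0.0 <= self.p_cross <= 1.0:
            raise ValidationError("p_cross must lie in [0, 1]")
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.brightness < 0 or self.background < 0:
            raise ValidationError("brightness and background must be >= 0")
        if self.n_lines < 1:
            raise ValidationError("n_lines must be >= 1")
        if self.burn_in_s < 0:
            raise ValidationError("burn_in_s must be >= 0")
        if self.init not in ("uniform", "left", "right"):
            raise ValidationError("init must be 'uniform', 'left' or 'right'")
        if not 0.0 <= self.slow_fraction <= 1.0:
            raise ValidationError("slow_fraction must lie in [0, 1]")
        if self.slow_fraction > 0 and (self.d_slow is None or self.d_slow <= 0):
            raise ValidationError("slow_fraction > 0 requires a positive d_slow")
        if self.barrier_x_um is not None:
            lo, hi = self.x_bounds
            if not lo < self.barrier_x_um < hi:
                raise ValidationError("barrier_x_um must lie strictly inside the box")
        if self.init != "uniform" and self.barrier_x_um is None:
            raise ValidationError("one-sided init requires a barrier")
        if self.active.enabled and self.barrier_x_um is None:
            raise ValidationError("active transport requires a barrier")
        if self.gap_half_width_um < 0:
            raise ValidationError("gap_half_width_um must be >= 0")
        if self.gap_half_width_um > 0:
            if self.barrier_x_um is None:
                raise ValidationError("a gap (void slab) requires barrier_x_um")
            if self.p_cross != 0.0 or self.active.enabled:
                raise ValidationError(
                    "a void gap is impenetrable: requires p_cross=0 and no active transport"
                )

    @property
    def x_bounds(self) -> tuple[float, float]:
        return (-self.box_pad_um, self.scan.scan_length_um + self.box_pad_um)

    @property
    def volume_um3(self) -> float:
        lo, hi = self.x_bounds
        return (hi - lo) * self.box_ly_um * self.box_lz_um

    def compartment_volumes(self) -> tuple[float, float]:
        if self.barrier_x_um is None:
            raise ValidationError("no barrier: compartment volumes undefined")
        lo, hi = self.x_bounds
        a = self.box_ly_um * self.box_lz_um
        hw = self.gap_half_width_um
        return (
            (self.barrier_x_um - hw - lo) * a,
            (hi - self.barrier_x_um - hw) * a,
        )


def paper_scan_config(**overrides) -> SimConfig:
    """The reference acquisition: 32 pixels of 100 nm at 6.3 µs dwell and
    0.473 ms line period, w0 = 0.25 µm, roughly one molecule per focal
    volume.  Keyword overrides replace any SimConfig field."""
    cfg = SimConfig()
    cfg = replace(cfg, n_particles=max(1, round(cfg.volume_um3 / cfg.psf.focal_volume_um3)))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


class CrossingTimes(NamedTuple):
    """First-passage summary; ``mean_s`` is None when nothing crossed."""

    mean_s: float | None
    sd_s: float | None
    n_crossed: int
    n_censored: int
    times_s: np.ndarray


@dataclass
class SimResult:
    """Carpet plus ground truth of a simulated experiment."""

    carpet: LineScanCarpet
    events: pd.DataFrame  # time_s (from recording start), direction, kind
    occupancy: pd.DataFrame  # per line: left, right, translocating
    realized_keq: float | None
    mean_expected_intensity: float
    initial_positions: np.ndarray
    final_positions: np.ndarray
    config: SimConfig
    seed: int


def _streams(seed: int) -> tuple[int, int, int]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(int(c.generate_state(1)[0] % (2**31 - 1)) for c in children)


def _sigmas(cfg: SimConfig, dt: float) -> tuple[float, float, float]:
    s_l = math.sqrt(2.0 * cfg.d_left * dt)
    s_r = math.sqrt(2.0 * cfg.d_right * dt)
    s_slow = math.sqrt(2.0 * (cfg.d_slow or cfg.d_left) * dt)
    return s_l, s_r, s_slow


def simulate_carpet(config: SimConfig, max_events: int = 2_000_000) -> SimResult:
    """Run the Brownian-dynamics scan and return carpet plus ground truth.

    Deterministic given ``config.seed``.  Counts follow
    Poisson(background + brightness * sum W) with positions advanced once
    per pixel dwell and once over the retrace dead time.
    """
    cfg = config
    traj_seed, photon_seed, init_seed = _streams(cfg.seed)
    scan = cfg.scan
    xmin, xmax = cfg.x_bounds
    ymin, ymax = -cfg.box_ly_um / 2.0, cfg.box_ly_um / 2.0
    zmin, zmax = -cfg.box_lz_um / 2.0, cfg.box_lz_um / 2.0

    rng = np.random.default_rng(init_seed)
    n = cfg.n_particles
    if cfg.init == "uniform":
        x = rng.uniform(xmin, xmax, n)
    elif cfg.init == "left":
        x = rng.uniform(xmin, cfg.barrier_x_um, n)
    else:
        x = rng.uniform(cfg.barrier_x_um, xmax, n)
    if cfg.gap_half_width_um > 0:
        lo = cfg.barrier_x_um - cfg.gap_half_width_um
        hi = cfg.barrier_x_um + cfg.gap_half_width_um
        inside = (x > lo) & (x < hi)
        while inside.any():  # resample the few that landed in the void
            x[inside] = rng.uniform(xmin, xmax, int(inside.sum()))
            inside = (x > lo) & (x < hi)
    y = rng.uniform(ymin, ymax, n)
    z = rng.uniform(zmin, zmax, n)
    slow = np.zeros(n, dtype=np.bool_)
    slow[: int(round(cfg.slow_fraction * n))] = True
    state = np.zeros(n, dtype=np.int64)
    release_t = np.zeros(n)
    pos0 = np.column_stack([x, y, z]).copy()

    beam_x = np.arange(scan.n_pixels) * scan.pixel_size_um
    if scan.direction == "right_to_left":
        beam_x = beam_x[::-1].copy()

    s_dw = _sigmas(cfg, scan.pixel_dwell_s)
    s_rt = _sigmas(cfg, scan.retrace_s) if scan.retrace_s > 0 else (0.0, 0.0, 0.0)
    # reference sigma for the detailed-balance scaling of barrier acceptance
    sig_ref = min(s_dw[0], s_dw[1], s_dw[2] if cfg.slow_fraction > 0 else s_dw[0])

    n_burn = int(math.ceil(cfg.burn_in_s / scan.line_period_s))
    intensity = np.zeros((cfg.n_lines, scan.n_pixels))
    occ_l = np.zeros(cfg.n_lines, dtype=np.int64)
    occ_r = np.zeros(cfg.n_lines, dtype=np.int64)
    occ_t = np.zeros(cfg.n_lines, dtype=np.int64)
    ev_t = np.empty(max_events)
    ev_dir = np.empty(max_events, dtype=np.int64)
    ev_kind = np.empty(max_events, dtype=np.int64)

    has_barrier = cfg.barrier_x_um is not None
    bx = cfg.barrier_x_um if has_barrier else 0.0
    act = cfg.active

    nev = _kernels.run_scan(
        traj_seed,
        x, y, z, slow, state, release_t,
        n_burn, cfg.n_lines, scan.n_pixels,
        scan.pixel_dwell_s, scan.retrace_s,
        beam_x,
        s_dw[0], s_dw[1], s_dw[2], sig_ref,
        s_rt[0], s_rt[1], s_rt[2],
        xmin, xmax, ymin, ymax, zmin, zmax,
        has_barrier, bx, cfg.gap_half_width_um, cfg.p_cross,
        act.enabled and has_barrier, _dir_sign(act.direction),
        act.p_active, act.translocation_mean_s,
        2.0 / cfg.psf.w0_um**2, 2.0 / cfg.psf.wz_um**2,
        _TRUNC_WAISTS * cfg.psf.w0_um, _TRUNC_WAISTS * cfg.psf.wz_um,
        cfg.brightness, cfg.background, cfg.brightness > 0 or cfg.background > 0,
        intensity, occ_l, occ_r, occ_t,
        ev_t, ev_dir, ev_kind,
    )
    if nev > max_events:
        raise ValidationError(
            f"event buffer overflow ({nev} > {max_events}); raise max_events"
        )

    counts = np.random.default_rng(photon_seed).poisson(intensity).astype(np.int64)

    t0 = n_burn * scan.line_period_s
    keep = ev_t[:nev] >= t0
    events = pd.DataFrame(
        {
            "time_s": ev_t[:nev][keep] - t0,
            "direction": ev_dir[:nev][keep],
            "kind": np.where(ev_kind[:nev][keep] == _kernels.ACTIVE, "active", "passive"),
        }
    )
    occupancy = pd.DataFrame({"left": occ_l, "right": occ_r, "translocating": occ_t})

    realized_keq = None
    labels = None
    if has_barrier:
        v_l, v_r = cfg.compartment_volumes()
        mean_r = occ_r.mean()
        if mean_r > 0:
            realized_keq = float((occ_l.mean() / v_l) / (mean_r / v_r))
        labels = tuple(
            "nucleus" if bxc < bx else "cytoplasm"
            for bxc in np.arange(scan.n_pixels) * scan.pixel_size_um
        )

    carpet = LineScanCarpet(
        counts=counts,
        pixel_size_um=scan.pixel_size_um,
        pixel_dwell_s=scan.pixel_dwell_s,
        line_period_s=scan.line_period_s,
        labels=labels,
    )
    return SimResult(
        carpet=carpet,
        events=events,
        occupancy=occupancy,
        realized_keq=realized_keq,
        mean_expected_intensity=float(intensity.mean()),
        initial_positions=pos0,
        final_positions=np.column_stack([x, y, z]),
        config=cfg,
        seed=cfg.seed,
    )


def mean_crossing_time(
    config: SimConfig,
    start_offset_um: float,
    n_rep: int = 200,
    horizon_s: float = 3.0,
    seed: int | None = None,
) -> CrossingTimes:
    """Brute-force first-passage oracle across the barrier (no PSF/photons).

    Walkers start ``start_offset_um`` to the left of the barrier (negative
    offsets start on the right) and use the same step schedule as the scan
    kernel, so a permeability calibrated here transfers directly to
    :func:`simulate_carpet`.  Replicates that do not cross within
    ``horizon_s`` are reported as censored, never silently averaged.
    """
    cfg = config
    if cfg.barrier_x_um is None:
        raise ValidationError("mean_crossing_time requires a barrier")
    if cfg.gap_half_width_um > 0:
        raise ValidationError("a void gap has no crossing time")
    if n_rep < 100:
        raise ValidationError("n_rep must be >= 100")
    if start_offset_um == 0:
        raise ValidationError("start_offset_um must be nonzero")
    if seed is None:
        seed = _streams(cfg.seed)[0]
    xmin, xmax = cfg.x_bounds
    x0 = cfg.barrier_x_um - start_offset_um
    if not xmin < x0 < xmax:
        raise ValidationError("start position falls outside the box")
    s_dw = _sigmas(cfg, cfg.scan.pixel_dwell_s)
    s_rt = _sigmas(cfg, cfg.scan.retrace_s) if cfg.scan.retrace_s > 0 else (0.0, 0.0, 0.0)
    sig_ref = min(s_dw[0], s_dw[1])
    act = cfg.active
    times = _kernels.first_passage_1d(
        seed,
        n_rep,
        x0,
        cfg.barrier_x_um,
        xmin, xmax,
        cfg.scan.n_pixels,
        cfg.scan.pixel_dwell_s, cfg.scan.retrace_s,
        s_dw[0], s_dw[1], s_rt[0], s_rt[1], sig_ref,
        cfg.p_cross,
        act.enabled, _dir_sign(act.direction), act.p_active, act.translocation_mean_s,
        horizon_s,
    )
    crossed = times[~np.isnan(times)]
    n_cens = int(np.isnan(times).sum())
    if crossed.size == 0:
        return CrossingTimes(None, None, 0, n_cens, times)
    sd = float(crossed.std(ddof=1)) if crossed.size > 1 else None
    return CrossingTimes(float(crossed.mean()), sd, int(crossed.size), n_cens, times)


def calibrate_permeability(
    target_mean_s: float,
    config: SimConfig,
    start_offset_um: float = 0.5,
    n_rep: int = 200,
    rel_tol: float = 0.1,
    max_iter: int = 30,
    seed: int | None = None,
) -> tuple[float, float]:
    """Find the per-attempt transmission probability giving a target mean
    first-crossing time; returns ``(p_cross, achieved_mean_s)``.

    Bisection on log p_cross against the :func:`mean_crossing_time` oracle
    (common random numbers per evaluation keep the response monotone).
    Raises :class:`InfeasibleTargetError` when the target is shorter than
    the free-diffusion (p_cross = 1) passage time.
    """
    if target_mean_s <= 0:
        raise ValidationError("target_mean_s must be positive")
    if seed is None:
        seed = _streams(config.seed)[0]
    horizon = max(20.0 * target_mean_s, 1.0)

    def mean_at(p: float) -> float:
        cfg = replace(config, p_cross=p)
        res = mean_crossing_time(
            cfg, start_offset_um, n_rep=n_rep, horizon_s=horizon, seed=seed
        )
        if res.mean_s is None or res.n_censored > 0.5 * n_rep:
            return math.inf
        return res.mean_s

    m_free = mean_at(1.0)
    if m_free > target_mean_s * (1.0 + rel_tol):
        raise InfeasibleTargetError(
            f"target {target_mean_s:.4g}s is below the free-diffusion passage "
            f"time {m_free:.4g}s from {start_offset_um} µm"
        )
    if abs(m_free - target_mean_s) <= rel_tol * target_mean_s:
        return 1.0, m_free

    lo = 1e-4  # slow end (long crossing times)
    while mean_at(lo) < target_mean_s:
        lo /= 10.0
        if lo < 1e-8:
            raise InfeasibleTargetError("could not bracket the target permeability")
    hi = 1.0
    p = lo
    achieved = math.inf
    for _ in range(max_iter):
        p = math.sqrt(lo * hi)
        achieved = mean_at(p)
        if achieved is not math.inf and abs(achieved - target_mean_s) <= rel_tol * target_mean_s:
            return p, achieved
        if achieved > target_mean_s:
            lo = p
        else:
            hi = p
    return p, achieved


def steady_state_keq(
    config: SimConfig, horizon_s: float, seed: int | None = None
) -> float:
    """Time-averaged left/right concentration ratio after burn-in.

    Runs the trajectory kernel without photon detection for ``horizon_s``
    of recorded time and normalizes occupancies by compartment volume, so
    an equal-volume passive system returns ~1 (detailed balance) and a
    leftward active channel returns > 1.
    """
    cfg = config
    if cfg.barrier_x_um is None:
        raise ValidationError("steady_state_keq requires a barrier")
    n_lines = max(1, int(round(horizon_s / cfg.scan.line_period_s)))
    cfg2 = replace(cfg, n_lines=n_lines, brightness=0.0, background=0.0)
    if seed is not None:
        cfg2 = replace(cfg2, seed=seed)
    res = simulate_carpet(cfg2)
    v_l, v_r = cfg.compartment_volumes()
    occ = res.occupancy
    mean_r = occ["right"].mean()
    if mean_r == 0:
        raise ValidationError("right compartment never occupied; Keq undefined")
    return float((occ["left"].mean() / v_l) / (mean_r / v_r))
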