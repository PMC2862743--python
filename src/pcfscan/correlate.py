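"""Auto- and pair-correlation of carpet columns on a multi-tau lag grid.

The fluctuation estimator used throughout is

    G(tau) = <dF_a(t) dF_b(t + tau)> / (<F_a>_head <F_b>_tail) ,

with the *symmetric* normalization: for an inter-line lag of ``k`` lines the
head segment is lines ``[0, n-k)`` of the origin column and the tail segment
lines ``[k, n)`` of the target column, and each segment is normalized by its
own mean.  This halves the bias a slow drift of the mean intensity induces
compared to normalizing both segments by the global mean.  Negative values
are preserved — the short-lag anti-correlation dip of the pair correlation
is the single-molecule signature of the method and must never be clipped.

Lags live on a multi-tau grid in units of the line period: 16 linear lags
at full resolution, then 8 lags per further octave with the two series
co-binned by successive factors of 2.  The ``direct`` scheme evaluates the
identical estimator (same grid, same binning) by exhaustive compensated
summation and serves as the oracle for the cascaded implementation.

Because the intensity is sampled pixel-by-pixel within each line, two
columns separated by ``delta`` pixels are visited ``delta * pixel_dwell``
apart *within* a line.  This constant intra-line offset is added to the
reported lag values (it is far below the line period, but keeping it makes
the lags physically exact); the lag *grid* itself remains inter-line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .carpet import LineScanCarpet
from .errors import NormalizationError, ValidationError

#: minimum record length for a meaningful correlation estimate
MIN_LINES = 1024

#: linear lags in the first multi-tau stage
_LAGS_STAGE0 = 16


@dataclass
class CorrelationCurve:
    """A correlation curve G(tau) for one column pair.

    ``delta_pixels`` is the signed column separation (0 for an ACF; the
    sign follows the scan direction sense).  ``values_sem`` is populated by
    :func:`average_curves` with the standard error across the averaged
    members and is used as inverse-variance weights when fitting.
    """

    lags_s: np.ndarray
    values: np.ndarray
    delta_pixels: int
    delta_um: float
    source_columns: tuple[int, int] | None
    n_lines_used: int
    values_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.lags_s.ndim != 1 or self.lags_s.shape != self.values.shape:
            raise ValidationError("lags and values must be 1-D arrays of equal length")
        if self.lags_s.size and (
            self.lags_s[0] <= 0 or np.any(np.diff(self.lags_s) <= 0)
        ):
            raise ValidationError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("correlation values must be finite")

    def __len__(self) -> int:
        return self.lags_s.size


@dataclass
class CorrelationCarpet:
    """One CorrelationCurve per origin column at a fixed pixel separation."""

    curves: list[CorrelationCurve]
    delta_pixels: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValidationError("a correlation carpet needs at least one curve")
        lags = self.curves[0].lags_s
        for c in self.curves:
            if c.delta_pixels != self.delta_pixels:
                raise ValidationError("member curves disagree on delta_pixels")
            if c.lags_s.shape != lags.shape or not np.array_equal(c.lags_s, lags):
                raise ValidationError("member curves must share the lag grid")

    @property
    def lags_s(self) -> np.ndarray:
        return self.curves[0].lags_s

    @property
    def origins(self) -> list[int]:
        return [c.source_columns[0] for c in self.curves]


# -- estimator core --------------------------------------------------------


def multitau_grid(n_lines: int, max_lag_lines: int) -> list[tuple[int, int]]:
    """Multi-tau lag grid as ``(lag_in_binned_units, bin_width)`` pairs.

    Stage 0 holds lags 1..16 at bin width 1; stage ``j >= 1`` holds binned
    lags 9..16 at width ``2**j`` (actual lag ``k * 2**j`` lines).
    """
    grid: list[tuple[int, int]] = []
    for k in range(1, _LAGS_STAGE0 + 1):
        if k <= max_lag_lines and k < n_lines:
            grid.append((k, 1))
    j = 1
    while True:
        width = 2**j
        if width > max_lag_lines:
            break
        m = n_lines // width
        added = False
        for k in range(_LAGS_STAGE0 // 2 + 1, _LAGS_STAGE0 + 1):
            if k * width <= max_lag_lines and k < m:
                grid.append((k, width))
                added = True
        if not added:
            break
        j += 1
    return grid


def _check_mean(series: np.ndarray, what: str) -> None:
    if series.mean() <= 0:
        raise NormalizationError(f"{what} has non-positive mean; estimator undefined")


def _bin2(a: np.ndarray) -> np.ndarray:
    m = a.size // 2
    return (a[: 2 * m : 2] + a[1 : 2 * m : 2]) / 2.0


def _bin(a: np.ndarray, width: int) -> np.ndarray:
    m = a.size // width
    return a[: m * width].reshape(m, width).mean(axis=1)


def _estimate(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Symmetric-normalization fluctuation estimator at integer lag k."""
    head = a[: a.size - k]
    tail = b[k:]
    mh = head.mean()
    mt = tail.mean()
    return float(np.dot(head, tail) / head.size / (mh * mt) - 1.0)


def _correlate_multitau(
    x: np.ndarray, y: np.ndarray, max_lag_lines: int
) -> tuple[np.ndarray, np.ndarray]:
    grid = multitau_grid(x.size, max_lag_lines)
    xa, ya = x, y
    width = 1
    lags = np.empty(len(grid), dtype=np.int64)
    vals = np.empty(len(grid))
    for i, (k, w) in enumerate(grid):
        while width < w:
            xa = _bin2(xa)
            ya = _bin2(ya)
            width *= 2
        lags[i] = k * w
        vals[i] = _estimate(xa, ya, k)
    return lags, vals


def _correlate_direct(
    x: np.ndarray, y: np.ndarray, max_lag_lines: int
) -> tuple[np.ndarray, np.ndarray]:
    """Same estimator on the same grid, by fresh binning and fsum.

    Deliberately shares no accumulation code with the cascaded correlator so
    it can act as an independent oracle.
    """
    grid = multitau_grid(x.size, max_lag_lines)
    lags = np.empty(len(grid), dtype=np.int64)
    vals = np.empty(len(grid))
    for i, (k, w) in enumerate(grid):
        xa = _bin(x, w)
        ya = _bin(y, w)
        head = xa[: xa.size - k]
        tail = ya[k:]
        m = head.size
        mh = math.fsum(head) / m
        mt = math.fsum(tail) / m
        vals[i] = math.fsum(head * tail) / m / (mh * mt) - 1.0
        lags[i] = k * w
    return lags, vals


# -- public operations ------------------------------------------------------


def compute_pcf(
    carpet: LineScanCarpet,
    origin_column: int,
    target_column: int,
    scheme: str = "multitau",
    max_lag_lines: int | None = None,
    detrend_window: int | None = None,
) -> CorrelationCurve:
    """Pair correlation of columns ``origin`` and ``target``.

    The curve cross-correlates ``F(origin, t)`` with ``F(target, t + tau)``.
    Reported lags are ``k * line_period + (target - origin) * pixel_dwell``
    for integer line lags ``k >= 1``; the signed second term accounts for
    the intra-line sampling offset between the two columns.

    ``detrend_window`` optionally divides each column by its moving average
    before correlating (off by default; prefer selecting stationary
    segments).
    """
    if scheme not in {"multitau", "direct"}:
        raise ValidationError(f"unknown correlator scheme {scheme!r}")
    if carpet.n_lines < MIN_LINES:
        raise ValidationError(
            f"correlation needs >= {MIN_LINES} lines, carpet has {carpet.n_lines}"
        )
    x = carpet.column(origin_column)
    y = carpet.column(target_column)
    _check_mean(x, f"column {origin_column}")
    _check_mean(y, f"column {target_column}")
    if detrend_window is not None:
        x = detrend_column(x, detrend_window)
        y = detrend_column(y, detrend_window)
    if max_lag_lines is None:
        max_lag_lines = carpet.n_lines // 4
    corr = _correlate_multitau if scheme == "multitau" else _correlate_direct
    lag_lines, values = corr(x, y, max_lag_lines)
    delta = target_column - origin_column
    lags_s = lag_lines * carpet.line_period_s + delta * carpet.pixel_dwell_s
    return CorrelationCurve(
        lags_s=lags_s,
        values=values,
        delta_pixels=delta,
        delta_um=delta * carpet.pixel_size_um,
        source_columns=(origin_column, target_column),
        n_lines_used=carpet.n_lines,
    )


def compute_acf(
    carpet: LineScanCarpet,
    column: int,
    scheme: str = "multitau",
    max_lag_lines: int | None = None,
    detrend_window: int | None = None,
) -> CorrelationCurve:
    """Autocorrelation of one column: the ``delta = 0`` pair correlation."""
    return compute_pcf(
        carpet,
        column,
        column,
        scheme=scheme,
        max_lag_lines=max_lag_lines,
        detrend_window=detrend_window,
    )


def pcf_carpet(
    carpet: LineScanCarpet,
    delta_pixels: int,
    columns: list[int] | None = None,
    scheme: str = "multitau",
    max_lag_lines: int | None = None,
    detrend_window: int | None = None,
) -> CorrelationCarpet:
    """One pair-correlation curve per origin column at fixed separation.

    ``columns`` restricts the origin columns; by default every origin whose
    partner ``origin + delta_pixels`` lies inside the carpet is used.
    """
    if columns is None:
        columns = [
            c
            for c in range(carpet.n_pixels)
            if 0 <= c + delta_pixels < carpet.n_pixels
        ]
    else:
        for c in columns:
            if not (0 <= c < carpet.n_pixels and 0 <= c + delta_pixels < carpet.n_pixels):
                raise ValidationError(
                    f"origin {c} with delta {delta_pixels} leaves the carpet"
                )
    if not columns:
        raise ValidationError("no valid origin columns for this delta")
    curves = [
        compute_pcf(
            carpet,
            c,
            c + delta_pixels,
            scheme=scheme,
            max_lag_lines=max_lag_lines,
            detrend_window=detrend_window,
        )
        for c in columns
    ]
    return CorrelationCarpet(
        curves=curves,
        delta_pixels=delta_pixels,
        provenance={
            "scheme": scheme,
            "detrend_window": detrend_window,
            "n_lines": carpet.n_lines,
        },
    )


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Arithmetic mean of curves sharing a lag grid.

    Column-block averaging trades spatial resolution for statistical
    precision of the peak position.  The standard error of the mean across
    members is stored on the result (``values_sem``) for use as fit
    weights.  ``n_lines_used`` is the minimum over members.
    """
    if not curves:
        raise ValidationError("cannot average an empty list of curves")
    lags = curves[0].lags_s
    delta = curves[0].delta_pixels
    for c in curves[1:]:
        if c.lags_s.shape != lags.shape or not np.array_equal(c.lags_s, lags):
            raise ValidationError("curves must share the lag grid")
        if c.delta_pixels != delta:
            raise ValidationError("curves must share delta_pixels")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    # a spread estimated from fewer than 3 members is too unstable to use
    # as inverse-variance weights (near-zero sems get enormous weight)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(len(curves)) if len(curves) >= 3 else None
    return CorrelationCurve(
        lags_s=lags.copy(),
        values=mean,
        delta_pixels=delta,
        delta_um=curves[0].delta_um,
        source_columns=None,
        n_lines_used=min(c.n_lines_used for c in curves),
        values_sem=sem,
    )


def block_average(cc: CorrelationCarpet, block: int = 3) -> CorrelationCarpet:
    """Sliding block average of a correlation carpet along the column axis.

    Each output curve averages the ``block`` curves centered on one origin
    (attributed to the central column pair), trading spatial resolution for
    statistical precision of the peak position — the column-block averaging
    used when reading transit delays off a carpet.  Requires consecutive
    origin columns.
    """
    if block < 1 or block % 2 == 0:
        raise ValidationError("block must be a positive odd number")
    origins = cc.origins
    if any(b - a != 1 for a, b in zip(origins, origins[1:])):
        raise ValidationError("block averaging requires consecutive origin columns")
    if len(cc.curves) < block:
        raise ValidationError(f"need at least {block} curves for block={block}")
    half = block // 2
    out = []
    for i in range(half, len(cc.curves) - half):
        avg = average_curves(cc.curves[i - half : i + half + 1])
        avg.source_columns = cc.curves[i].source_columns
        out.append(avg)
    return CorrelationCarpet(
        curves=out,
        delta_pixels=cc.delta_pixels,
        provenance={**cc.provenance, "block": block},
    )


def detrend_column(series: np.ndarray, window_lines: int) -> np.ndarray:
    """Divide a series by its moving average, rescaled to the original mean.

    Removes slow multiplicative drifts (bleaching-like decays) while
    preserving fast fluctuations.  Off by default in the correlation
    pipeline: segment selection after stationarity QC is preferred.
    """
    if window_lines < 16:
        raise ValidationError("detrend window must be >= 16 lines")
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValidationError("detrend_column expects a 1-D series")
    mean = series.mean()
    if mean <= 0:
        raise NormalizationError("cannot detrend a series with non-positive mean")
    moving = uniform_filter1d(series, size=window_lines, mode="nearest")
    if np.any(moving <= 0):
        raise NormalizationError("moving average reaches zero; cannot detrend")
    ratio = series / moving
    return ratio * (mean / ratio.mean())
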