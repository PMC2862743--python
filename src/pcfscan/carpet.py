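"""Line-scan carpet data model, I/O and stationarity quality control.

A *carpet* is the standard rendering of a line-scan FCS acquisition: a
photon-count matrix whose rows are successive scan lines (time) and whose
columns are pixel positions along the scanned line.  Column ``i`` sits at
physical position ``i * pixel_size_um`` (0-based, left edge of the scan).

Carpets are persisted as single-page 16-bit grayscale TIFF, header-less
integer CSV, or raw little-endian uint32, always accompanied by a JSON
metadata sidecar (same basename, ``.json`` extension) carrying the scan
geometry.  Metadata is deliberately kept out of TIFF tags so that counts
round-trip bit-exactly regardless of TIFF dialect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ConfigurationError,
    FormatError,
    RatioUndefinedError,
    ValidationError,
)

VALID_LABELS = frozenset({"nucleus", "cytoplasm", "barrier", "unknown"})

_SIDECAR_REQUIRED = ("pixel_size_um", "pixel_dwell_s", "line_period_s")

#: float slack when checking line_period >= n_pixels * pixel_dwell
_TIME_EPS = 1e-12


@dataclass(frozen=True)
class SegmentSelection:
    """Half-open range of scan lines ``[start_line, end_line)``."""

    start_line: int
    end_line: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_line < self.end_line):
            raise ValidationError(
                f"invalid segment [{self.start_line}, {self.end_line})"
            )


@dataclass
class LineScanCarpet:
    """Photon-count matrix (lines x pixels) plus scan geometry.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_lines, n_pixels)``.
    pixel_size_um
        Distance between adjacent pixel centers along the line (µm).
    pixel_dwell_s
        Time the beam dwells on one pixel (s).
    line_period_s
        Time between the starts of successive lines (s); must be at least
        ``n_pixels * pixel_dwell_s`` — the difference is the retrace dead
        time.
    labels
        Optional per-column compartment tag, each one of
        ``nucleus | cytoplasm | barrier | unknown``.
    acquisition_start_s
        Time of the first line relative to the start of the recording
        (0 for simulated data).
    """

    counts: np.ndarray
    pixel_size_um: float
    pixel_dwell_s: float
    line_period_s: float
    labels: tuple[str, ...] | None = None
    acquisition_start_s: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(
                f"counts must be 2-D (lines x pixels), got ndim={counts.ndim}"
            )
        if counts.dtype.kind == "f":
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        elif counts.dtype.kind in "ui":
            counts = counts.astype(np.int64)
        else:
            raise ValidationError(f"counts dtype {counts.dtype} is not numeric")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if counts.shape[1] < 2:
            raise ValidationError("a carpet needs at least 2 pixels per line")
        self.counts = counts

        for name in ("pixel_size_um", "pixel_dwell_s", "line_period_s"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"{name} must be positive, got {value!r}")
        if self.line_period_s + _TIME_EPS < self.n_pixels * self.pixel_dwell_s:
            raise ValidationError(
                "line_period_s must be >= n_pixels * pixel_dwell_s "
                f"({self.line_period_s} < {self.n_pixels * self.pixel_dwell_s})"
            )
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.n_pixels:
                raise ValidationError(
                    f"labels length {len(labels)} != n_pixels {self.n_pixels}"
                )
            bad = set(labels) - VALID_LABELS
            if bad:
                raise ValidationError(f"unknown column labels: {sorted(bad)}")
            self.labels = labels

    # -- derived geometry -------------------------------------------------

    @property
    def n_lines(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_pixels(self) -> int:
        return int(self.counts.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_lines * self.line_period_s

    @property
    def positions_um(self) -> np.ndarray:
        """Physical position of each column center (µm)."""
        return np.arange(self.n_pixels) * self.pixel_size_um

    def column(self, i: int) -> np.ndarray:
        """Intensity record of column ``i`` as float64."""
        if not 0 <= i < self.n_pixels:
            raise ValidationError(f"column {i} out of range [0, {self.n_pixels})")
        return self.counts[:, i].astype(np.float64)


# -- I/O -------------------------------------------------------------------

_EXT_FORMAT = {".tif": "tiff", ".tiff": "tiff", ".csv": "csv", ".raw": "raw", ".bin": "raw"}


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in {"tiff", "csv", "raw"}:
            raise FormatError(f"unknown carpet format {format!r}")
        return format
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise FormatError(
            f"cannot infer carpet format from extension {path.suffix!r}; "
            "pass format='tiff'|'csv'|'raw'"
        ) from None


def _read_sidecar(path: Path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise ConfigurationError(f"metadata sidecar {sc} not found")
    try:
        meta = json.loads(sc.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {sc} is not valid JSON: {exc}") from exc
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise ConfigurationError(f"sidecar {sc} is missing required field {key!r}")
    return meta


def load_carpet(path: str | Path, format: str | None = None) -> LineScanCarpet:
    """Load a carpet and its JSON metadata sidecar.

    ``format`` is inferred from the file extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"carpet file {path} does not exist")
    fmt = _infer_format(path, format)
    meta = _read_sidecar(path)

    if fmt == "tiff":
        try:
            counts = tifffile.imread(path)
        except Exception as exc:  # tifffile raises a zoo of types
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if counts.ndim != 2:
            raise FormatError(
                f"TIFF {path} must be a single-page grayscale image, got shape {counts.shape}"
            )
    elif fmt == "csv":
        try:
            counts = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    else:  # raw
        for key in ("n_lines", "n_pixels"):
            if key not in meta:
                raise ConfigurationError(
                    f"raw format requires field {key!r} in the sidecar"
                )
        counts = np.fromfile(path, dtype="<u4")
        expected = int(meta["n_lines"]) * int(meta["n_pixels"])
        if counts.size != expected:
            raise FormatError(
                f"raw file {path} has {counts.size} values, expected {expected}"
            )
        counts = counts.reshape(int(meta["n_lines"]), int(meta["n_pixels"]))

    labels = meta.get("labels")
    return LineScanCarpet(
        counts=counts,
        pixel_size_um=float(meta["pixel_size_um"]),
        pixel_dwell_s=float(meta["pixel_dwell_s"]),
        line_period_s=float(meta["line_period_s"]),
        labels=tuple(labels) if labels is not None else None,
        acquisition_start_s=float(meta.get("acquisition_start_s", 0.0)),
    )


def save_carpet(carpet: LineScanCarpet, path: str | Path, format: str | None = None) -> Path:
    """Persist a carpet bit-exactly, writing the JSON sidecar alongside."""
    path = Path(path)
    fmt = _infer_format(path, format)

    if fmt == "tiff":
        if carpet.counts.size and carpet.counts.max() > np.iinfo(np.uint16).max:
            raise FormatError(
                "counts exceed the 16-bit TIFF range (65535); save as format='raw'"
            )
        tifffile.imwrite(path, carpet.counts.astype(np.uint16), photometric="minisblack")
    elif fmt == "csv":
        np.savetxt(path, carpet.counts, fmt="%d", delimiter=",")
    else:
        if carpet.counts.size and carpet.counts.max() > np.iinfo(np.uint32).max:
            raise FormatError("counts exceed the uint32 range")
        carpet.counts.astype("<u4").tofile(path)

    meta = {
        "pixel_size_um": carpet.pixel_size_um,
        "pixel_dwell_s": carpet.pixel_dwell_s,
        "line_period_s": carpet.line_period_s,
        "acquisition_start_s": carpet.acquisition_start_s,
        "n_lines": carpet.n_lines,
        "n_pixels": carpet.n_pixels,
    }
    if carpet.labels is not None:
        meta["labels"] = list(carpet.labels)
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


# -- segment selection and QC ---------------------------------------------


def select_segment(carpet: LineScanCarpet, selection: SegmentSelection) -> LineScanCarpet:
    """Return the sub-carpet of lines ``[start_line, end_line)``.

    Metadata is unchanged except that ``acquisition_start_s`` advances to
    the start of the selected segment.  Selecting the full range is the
    identity; selections compose: ``[a,b)`` then ``[c,d)`` equals
    ``[a+c, a+d)`` on the original carpet.
    """
    if selection.end_line > carpet.n_lines:
        raise ValidationError(
            f"segment end {selection.end_line} exceeds n_lines {carpet.n_lines}"
        )
    return dataclasses.replace(
        carpet,
        counts=carpet.counts[selection.start_line : selection.end_line].copy(),
        acquisition_start_s=carpet.acquisition_start_s
        + selection.start_line * carpet.line_period_s,
    )


def stationarity_report(
    carpet: LineScanCarpet,
    window_lines: int,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-column drift metric for stationarity QC.

    The record is cut into consecutive non-overlapping windows of
    ``window_lines`` lines; the metric is
    ``(max windowed mean - min windowed mean) / grand mean``.  A column
    passes iff its metric is below ``threshold``.  Slow drifts of the mean
    intensity (photobleaching, movement of the nuclear-envelope position)
    inflate the metric, while a stationary shot-noise-limited record keeps
    it near zero.  The metric is invariant to global rescaling of a column.

    All-zero columns get metric 0 and are flagged ``empty`` rather than
    producing NaN.

    Returns a DataFrame indexed by column with ``metric``, ``passed`` and
    ``empty``; the window and threshold used are recorded in ``df.attrs``.
    """
    if not (2 <= window_lines <= carpet.n_lines // 4):
        raise ValidationError(
            f"window_lines must be in [2, n_lines/4] = [2, {carpet.n_lines // 4}]"
        )
    n_win = carpet.n_lines // window_lines
    trimmed = carpet.counts[: n_win * window_lines].astype(np.float64)
    windowed = trimmed.reshape(n_win, window_lines, carpet.n_pixels).mean(axis=1)
    grand = carpet.counts.mean(axis=0)
    span = windowed.max(axis=0) - windowed.min(axis=0)
    empty = grand == 0
    metric = np.where(empty, 0.0, span / np.where(empty, 1.0, grand))
    df = pd.DataFrame(
        {
            "metric": metric,
            "passed": metric < threshold,
            "empty": empty,
        },
        index=pd.RangeIndex(carpet.n_pixels, name="column"),
    )
    df.attrs["window_lines"] = window_lines
    df.attrs["threshold"] = threshold
    return df


def concentration_ratio(
    carpet: LineScanCarpet, labels: tuple[str, ...] | None = None
) -> float:
    """Nuclear/cytoplasmic mean-intensity ratio Keq.

    Uses the per-column compartment labels (argument overrides the ones
    stored on the carpet).  With fluorescence proportional to
    concentration this estimates the steady-state partition coefficient.
    """
    labels = tuple(labels) if labels is not None else carpet.labels
    if labels is None:
        raise ConfigurationError("concentration_ratio requires column labels")
    if len(labels) != carpet.n_pixels:
        raise ValidationError("labels length does not match n_pixels")
    labels_arr = np.asarray(labels)
    nuc = carpet.counts[:, labels_arr == "nucleus"]
    cyt = carpet.counts[:, labels_arr == "cytoplasm"]
    if nuc.size == 0 or cyt.size == 0:
        raise ValidationError("both nucleus and cytoplasm label groups must be non-empty")
    cyt_mean = cyt.mean()
    if cyt_mean == 0:
        raise RatioUndefinedError("cytoplasm mean intensity is zero; Keq undefined")
    return float(nuc.mean() / cyt_mean)
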