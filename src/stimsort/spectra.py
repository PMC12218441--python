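"""Single-cell Raman spectra: parsing, band integration, and activity scoring.

A cell's deuterium-substitution score (%CD) is the C-D band area as a
percentage of the combined C-D + C-H band area, both integrated with a local
linear baseline.  The activity threshold is calibrated from control cells as
mean + 3 standard deviations of their %CD values; cells strictly above the
threshold are called labeled.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    SpectrumParseError,
    ValidationError,
    WindowRangeError,
)

__all__ = [
    "BandWindow",
    "RamanSpectrum",
    "CdScore",
    "ActivityThreshold",
    "CD_WINDOW",
    "CH_WINDOW",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "integrate_band",
    "percent_cd",
    "calibrate_threshold",
    "classify_cells",
    "compare_groups",
]

#: Width (cm^-1) of the shoulder regions used to anchor the local linear
#: baseline just outside an integration window.
SHOULDER_WIDTH = 5.0


@dataclass(frozen=True)
class BandWindow:
    """A closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValidationError("band window bounds must be finite")
        if not self.lo < self.hi:
            raise ValidationError(
                f"band window requires lo < hi, got [{self.lo}, {self.hi}]"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo


CD_WINDOW = BandWindow(2040.0, 2300.0)
CH_WINDOW = BandWindow(2800.0, 3100.0)


@dataclass
class RamanSpectrum:
    """One cell's wavenumber/intensity trace plus identity metadata.

    Wavenumbers must be strictly increasing, finite, and aligned with the
    intensity array; both need at least two points.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    cell_id: str = ""
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if w.size != y.size:
            raise ValidationError(
                f"length mismatch: {w.size} wavenumbers vs {y.size} intensities"
            )
        if w.size < 2:
            raise ValidationError("spectrum needs at least 2 points")
        if not (np.isfinite(w).all() and np.isfinite(y).all()):
            raise ValidationError("spectrum contains non-finite values")
        if not (np.diff(w) > 0).all():
            raise ValidationError("wavenumbers must be strictly increasing")
        self.wavenumbers = w
        self.intensities = y

    def covers(self, window: BandWindow) -> bool:
        return self.wavenumbers[0] <= window.lo and self.wavenumbers[-1] >= window.hi

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class CdScore:
    """Per-cell %CD value; `labeled` stays None until classified."""

    cell_id: str
    percent_cd: float
    labeled: bool | None = None
    sample_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_cd <= 100.0:
            raise ValidationError(
                f"percent_cd must lie in [0, 100], got {self.percent_cd}"
            )


@dataclass(frozen=True)
class ActivityThreshold:
    """Control-derived labeling cutoff: mean + 3 SD of control %CD values."""

    value: float
    control_mean: float
    control_sd: float
    n_control: int

    def __post_init__(self) -> None:
        if self.n_control < 2:
            raise ValidationError("threshold calibration needs >= 2 controls")
        expected = self.control_mean + 3.0 * self.control_sd
        if not np.isclose(self.value, expected, rtol=1e-12, atol=1e-12):
            raise ValidationError("threshold value must equal mean + 3*SD")


_DELIMS = re.compile(r"[,\t]|\s+")


def read_spectrum(path: str | Path, cell_id: str | None = None) -> RamanSpectrum:
    """Read a two-column delimited text spectrum (whitespace, comma, or tab).

    Lines starting with '#' and blank lines are skipped.  Rows are sorted by
    wavenumber on load.  Malformed rows, non-numeric fields, and duplicate
    wavenumbers raise :class:`SpectrumParseError` naming the line number.
    """
    path = Path(path)
    wavenumbers: list[float] = []
    intensities: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _DELIMS.split(line) if f]
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                w, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric field in {fields!r}"
                ) from exc
            wavenumbers.append(w)
            intensities.append(y)
    w = np.asarray(wavenumbers)
    y = np.asarray(intensities)
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    dup = np.flatnonzero(np.diff(w) == 0)
    if dup.size:
        raise SpectrumParseError(
            f"{path}: duplicate wavenumber {w[dup[0]]} in data rows"
        )
    return RamanSpectrum(w, y, cell_id=cell_id or path.stem)


def write_spectrum(spec: RamanSpectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text at full float precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cell_id: {spec.cell_id}\n")
        fh.write("# wavenumber_cm-1 intensity\n")
        for w, y in zip(spec.wavenumbers, spec.intensities):
            fh.write(f"{float(w)!r} {float(y)!r}\n")


def resample(spec: RamanSpectrum, grid: np.ndarray) -> RamanSpectrum:
    """Linearly resample a spectrum onto a new strictly-increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spec.wavenumbers[0] or grid[-1] > spec.wavenumbers[-1]:
        raise WindowRangeError("resampling grid extends beyond spectrum span")
    y = np.interp(grid, spec.wavenumbers, spec.intensities)
    return RamanSpectrum(grid, y, cell_id=spec.cell_id, sample_meta=dict(spec.sample_meta))


def _window_arrays(
    spec: RamanSpectrum, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grid points within [lo, hi] with interpolated values at the edges."""
    w, y = spec.wavenumbers, spec.intensities
    inside = (w >= lo) & (w <= hi)
    ws = list(w[inside])
    ys = list(y[inside])
    if not ws or ws[0] > lo:
        ws.insert(0, lo)
        ys.insert(0, float(np.interp(lo, w, y)))
    if ws[-1] < hi:
        ws.append(hi)
        ys.append(float(np.interp(hi, w, y)))
    return np.asarray(ws), np.asarray(ys)


def integrate_band(
    spec: RamanSpectrum,
    window: BandWindow,
    baseline_mode: Literal["raw", "local_linear"] = "raw",
) -> float:
    """Trapezoidal band integral, optionally above a local linear baseline.

    In ``local_linear`` mode the baseline is the straight line joining the
    median intensities of the 5 cm^-1 shoulders just outside the window
    (anchored at the shoulder midpoints); the corrected integral may be
    negative and is NOT clamped here.
    """
    if not spec.covers(window):
        raise WindowRangeError(
            f"window [{window.lo}, {window.hi}] outside spectrum span "
            f"[{spec.wavenumbers[0]}, {spec.wavenumbers[-1]}]"
        )
    ws, ys = _window_arrays(spec, window.lo, window.hi)
    area = float(np.trapezoid(ys, ws))
    if baseline_mode == "raw":
        return area
    if baseline_mode != "local_linear":
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")

    w, y = spec.wavenumbers, spec.intensities
    left = (w >= window.lo - SHOULDER_WIDTH) & (w < window.lo)
    right = (w > window.hi) & (w <= window.hi + SHOULDER_WIDTH)
    if not left.any() or not right.any():
        raise WindowRangeError(
            f"local_linear baseline needs {SHOULDER_WIDTH} cm^-1 shoulders "
            f"outside [{window.lo}, {window.hi}]"
        )
    x_l = window.lo - SHOULDER_WIDTH / 2.0
    x_r = window.hi + SHOULDER_WIDTH / 2.0
    y_l = float(np.median(y[left]))
    y_r = float(np.median(y[right]))
    # integral of the baseline line over [lo, hi] = mean of its endpoint
    # values times the window width
    slope = (y_r - y_l) / (x_r - x_l)
    b_lo = y_l + slope * (window.lo - x_l)
    b_hi = y_l + slope * (window.hi - x_l)
    baseline_area = 0.5 * (b_lo + b_hi) * window.width
    return area - baseline_area


def percent_cd(
    spec: RamanSpectrum,
    cd_window: BandWindow = CD_WINDOW,
    ch_window: BandWindow = CH_WINDOW,
    baseline_mode: Literal["raw", "local_linear"] = "local_linear",
) -> CdScore:
    """%CD = 100 * A_CD / (A_CD + A_CH), baseline-corrected areas clamped at 0.

    If both clamped areas are zero the score is 0.
    """
    a_cd = max(integrate_band(spec, cd_window, baseline_mode), 0.0)
    a_ch = max(integrate_band(spec, ch_window, baseline_mode), 0.0)
    total = a_cd + a_ch
    value = 0.0 if total == 0.0 else 100.0 * a_cd / total
    return CdScore(
        cell_id=spec.cell_id,
        percent_cd=float(np.clip(value, 0.0, 100.0)),
        sample_meta=dict(spec.sample_meta),
    )


def calibrate_threshold(control_scores: Sequence[float]) -> ActivityThreshold:
    """Labeling cutoff = mean + 3 * sample SD (n-1) of control %CD values."""
    values = np.asarray(list(control_scores), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"threshold calibration needs >= 2 control scores, got {values.size}"
        )
    if not np.isfinite(values).all():
        raise ValidationError("control scores contain non-finite values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ActivityThreshold(
        value=mean + 3.0 * sd, control_mean=mean, control_sd=sd, n_control=values.size
    )


def classify_cells(
    scores: Iterable[CdScore], thr: ActivityThreshold
) -> list[CdScore]:
    """Set ``labeled = percent_cd > threshold`` (ties classified unlabeled)."""
    return [
        dataclasses.replace(s, labeled=bool(s.percent_cd > thr.value))
        for s in scores
    ]


def compare_groups(
    groups: Mapping[str, Sequence[float]]
) -> dict[str, float | int]:
    """One-way fixed-effects ANOVA across %CD groups.

    Returns ``{"F": ..., "p": ..., "n": total observations}``.
    """
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    arrays = []
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise InsufficientDataError(
                f"group {label!r} has {arr.size} values; >= 2 required"
            )
        arrays.append(arr)
    f_stat, p = stats.f_oneway(*arrays)
    n = int(sum(a.size for a in arrays))
    if not np.isfinite(f_stat):  # all-identical degenerate input
        raise InsufficientDataError("ANOVA undefined: zero within-group variance")
    return {"F": float(f_stat), "p": float(p), "n": n}
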