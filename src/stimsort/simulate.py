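"""Synthetic-data generators with recorded ground truth.

Every generator is deterministic given (spec, seed).  Spectra are built on a
400-3200 cm^-1 grid at 1 cm^-1 spacing with Gaussian bands, a linear
baseline, and i.i.d. Gaussian noise; community count tables follow a
Dirichlet-multinomial with log-normal donor effects and planted responder
genera; growth curves are shifted logistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError, ValidationError
from .community import CountTable
from .phenotype import GrowthCurve
from .spectra import RamanSpectrum

__all__ = [
    "DEFAULT_GRID",
    "SpectrumSpec",
    "CellTruth",
    "CommunitySpec",
    "CommunityTruth",
    "generate_spectrum",
    "generate_cell_population",
    "generate_fluid_background",
    "generate_sort_stream",
    "generate_count_table",
    "generate_growth_curves",
    "logistic_od",
    "logistic_auc",
]

DEFAULT_GRID = np.arange(400.0, 3200.0 + 1.0, 1.0)

CD_CENTER = 2170.0
CH_CENTER = 2950.0


def _gaussian_band(grid: np.ndarray, area: float, center: float, sigma: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2.0 * math.pi)) * np.exp(
        -0.5 * ((grid - center) / sigma) ** 2
    )


@dataclass(frozen=True)
class SpectrumSpec:
    """Parameters of one synthetic cell spectrum.

    The C-D band area is chosen so that the clamped-area ratio equals
    ``percent_cd_true`` given ``ch_area``.
    """

    percent_cd_true: float = 0.0
    ch_area: float = 100.0
    peak_width_cd: float = 25.0
    peak_width_ch: float = 40.0
    baseline_offset: float = 5.0
    baseline_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_cd_true <= 100.0:
            raise SpecError("percent_cd_true must lie in [0, 100]")
        if self.percent_cd_true >= 100.0 and self.ch_area > 0:
            raise SpecError(
                "percent_cd_true = 100 is infeasible with a non-zero C-H area"
            )
        if self.ch_area < 0 or self.noise_sd < 0:
            raise SpecError("areas and noise_sd must be non-negative")
        if self.peak_width_cd <= 0 or self.peak_width_ch <= 0:
            raise SpecError("peak widths must be positive")


@dataclass(frozen=True)
class CellTruth:
    cell_id: str
    labeled: bool
    percent_cd_true: float


def generate_spectrum(
    spec: SpectrumSpec,
    seed: int | None = None,
    cell_id: str = "cell",
    grid: np.ndarray | None = None,
    sample_meta: dict | None = None,
) -> RamanSpectrum:
    """Baseline + C-D band + C-H band + Gaussian noise on the standard grid."""
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    p = spec.percent_cd_true
    if p >= 100.0:
        cd_area = 100.0  # ch_area is 0 here; any positive area yields 100%
    else:
        cd_area = p / (100.0 - p) * spec.ch_area
    y = spec.baseline_offset + spec.baseline_slope * (g - g[0])
    if cd_area > 0:
        y = y + _gaussian_band(g, cd_area, CD_CENTER, spec.peak_width_cd)
    if spec.ch_area > 0:
        y = y + _gaussian_band(g, spec.ch_area, CH_CENTER, spec.peak_width_ch)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=g.size)
    return RamanSpectrum(g, y, cell_id=cell_id, sample_meta=dict(sample_meta or {}))


def generate_cell_population(
    n_cells: int,
    labeled_fraction: float,
    cd_active_mean: float,
    cd_active_sd: float,
    cd_null_mean: float,
    cd_null_sd: float,
    seed: int | None = None,
    base_spec: SpectrumSpec = SpectrumSpec(noise_sd=0.05),
    sample_meta: dict | None = None,
    id_prefix: str = "cell",
) -> list[tuple[RamanSpectrum, CellTruth]]:
    """Mixed population: labeled cells draw %CD from the active distribution,
    unlabeled from the null; both truncated to [0, 99]."""
    if not 0.0 <= labeled_fraction <= 1.0:
        raise SpecError("labeled_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[tuple[RamanSpectrum, CellTruth]] = []
    for i in range(n_cells):
        labeled = bool(rng.random() < labeled_fraction)
        mu, sd = (cd_active_mean, cd_active_sd) if labeled else (cd_null_mean, cd_null_sd)
        p = float(np.clip(rng.normal(mu, sd), 0.0, 99.0))
        spec = SpectrumSpec(
            percent_cd_true=p,
            ch_area=base_spec.ch_area,
            peak_width_cd=base_spec.peak_width_cd,
            peak_width_ch=base_spec.peak_width_ch,
            baseline_offset=base_spec.baseline_offset,
            baseline_slope=base_spec.baseline_slope,
            noise_sd=base_spec.noise_sd,
        )
        cell_id = f"{id_prefix}{i:04d}"
        spectrum = generate_spectrum(
            spec,
            seed=int(rng.integers(0, 2**31 - 1)),
            cell_id=cell_id,
            sample_meta=sample_meta,
        )
        out.append((spectrum, CellTruth(cell_id, labeled, p)))
    return out


def generate_fluid_background(
    grid: np.ndarray | None = None,
    offset: float = 10.0,
    slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RamanSpectrum:
    """Smooth low-intensity carrier-fluid spectrum for Pc denominators."""
    if offset <= 0:
        raise ValidationError("fluid offset must be positive")
    g = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    y = offset + slope * (g - g[0])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=g.size)
    return RamanSpectrum(g, y, cell_id="fluid")


#: flat-spectrum PL implied by the window-width ratio 260/50
FLAT_PL = 5.2


def generate_sort_stream(
    n_cells: int,
    labeled_fraction: float,
    pl_labeled_mean: float = 9.0,
    pl_labeled_sd: float = 1.0,
    pl_unlabeled_mean: float = FLAT_PL,
    pl_unlabeled_sd: float = 0.2,
    pc_mean: float = 2.0,
    pc_sd: float = 0.1,
    offset: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[list[tuple[RamanSpectrum, bool]], RamanSpectrum]:
    """Cells with target Pc/PL index values plus the matching fluid spectrum.

    Each cell is a flat spectrum at ``offset`` with a 1645 cm^-1 protein band
    sized to hit the drawn Pc and a C-D band (possibly a dip, for PL below
    the flat value) sized to hit the drawn PL.
    """
    rng = np.random.default_rng(seed)
    fluid = generate_fluid_background(offset=offset)
    den_width = 50.0  # widths of the PL reference and Pc windows
    stream: list[tuple[RamanSpectrum, bool]] = []
    for i in range(n_cells):
        labeled = bool(rng.random() < labeled_fraction)
        pl = rng.normal(
            pl_labeled_mean if labeled else pl_unlabeled_mean,
            pl_labeled_sd if labeled else pl_unlabeled_sd,
        )
        pc = max(rng.normal(pc_mean, pc_sd), 0.1)
        g = DEFAULT_GRID
        y = np.full(g.size, offset)
        y = y + _gaussian_band(g, (pc - 1.0) * den_width * offset, 1645.0, 8.0)
        y = y + _gaussian_band(g, (pl - FLAT_PL) * den_width * offset, CD_CENTER, 25.0)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=g.size)
        stream.append(
            (RamanSpectrum(g, y, cell_id=f"evt{i:04d}"), labeled)
        )
    return stream, fluid


# ---------------------------------------------------------------------------
# Community count tables

@dataclass(frozen=True)
class CommunitySpec:
    """Six-donor paired-fraction community design with planted responders."""

    n_donors: int = 6
    n_genera: int = 50
    reads_per_sample: int = 20000
    donor_effect_sd: float = 2.0
    base_log_sd: float = 1.0
    responders: dict = field(default_factory=dict)  # genus label -> log effect
    #: added to responder genera's base log-abundance so planted effects land
    #: on reliably observable genera (EF analysis targets abundant genera)
    responder_base_boost: float = 0.0
    dispersion: float = 200.0
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise SpecError("reads_per_sample must be positive")
        if self.dispersion <= 0:
            raise SpecError("dispersion must be positive")
        if self.n_donors < 1 or self.n_genera < 1 or self.n_replicates < 1:
            raise SpecError("design dimensions must be positive")
        for effect in self.responders.values():
            if not np.isfinite(effect):
                raise SpecError("responder effects must be finite")


@dataclass(frozen=True)
class CommunityTruth:
    responders: dict  # genus label -> planted log effect
    genus_labels: tuple


#: (treatment, fraction, timepoint_h) per condition in each donor block
_CONDITIONS = (
    ("none", "bulk", 0),
    ("none", "dapi_neg", 6),
    ("lactulose", "boncat_pos", 6),
)


def genus_labels(n_genera: int) -> list[str]:
    return [f"g{i:03d}" for i in range(n_genera)]


def generate_count_table(
    spec: CommunitySpec, seed: int | None = None
) -> tuple[CountTable, CommunityTruth]:
    """Dirichlet-multinomial genus table over a paired per-donor design.

    Per donor a log-composition is drawn once (base + donor effect); samples
    from the treated fraction multiply responder genera by exp(effect) before
    renormalization; counts are multinomial over a Dirichlet draw with
    concentration ``dispersion``; column sums equal ``reads_per_sample``.
    """
    labels = genus_labels(spec.n_genera)
    unknown = [g for g in spec.responders if g not in labels]
    if unknown:
        raise SpecError(f"responder genera not in table: {unknown}")
    rng = np.random.default_rng(seed)
    base_log = rng.normal(0.0, spec.base_log_sd, size=spec.n_genera)
    effect = np.zeros(spec.n_genera)
    for g, e in spec.responders.items():
        effect[labels.index(g)] = e
        base_log[labels.index(g)] += spec.responder_base_boost

    samples: list[str] = []
    sample_meta: dict[str, dict] = {}
    columns: list[np.ndarray] = []
    for d in range(1, spec.n_donors + 1):
        donor_log = base_log + rng.normal(0.0, spec.donor_effect_sd, size=spec.n_genera)
        comp = np.exp(donor_log - donor_log.max())
        comp /= comp.sum()
        treated = comp * np.exp(effect)
        treated /= treated.sum()
        for treatment, fraction, tp in _CONDITIONS:
            target = treated if fraction == "boncat_pos" else comp
            for rep in range(1, spec.n_replicates + 1):
                sid = f"D{d}_{treatment}_{fraction}_t{tp}_r{rep}"
                p = rng.dirichlet(spec.dispersion * target + 1e-9)
                counts = rng.multinomial(spec.reads_per_sample, p)
                samples.append(sid)
                sample_meta[sid] = {
                    "donor": f"D{d}",
                    "treatment": treatment,
                    "fraction": fraction,
                    "timepoint_h": tp,
                    "replicate": rep,
                }
                columns.append(counts)
    table = CountTable(
        taxa=labels,
        samples=samples,
        counts=np.column_stack(columns),
        sample_meta=sample_meta,
    )
    truth = CommunityTruth(responders=dict(spec.responders), genus_labels=tuple(labels))
    return table, truth


# ---------------------------------------------------------------------------
# Growth curves

def logistic_od(t: np.ndarray, k: float, r: float, t_mid: float) -> np.ndarray:
    """Shifted logistic K / (1 + exp(-r (t - t_mid)))."""
    return k / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t_mid)))


def logistic_auc(k: float, r: float, t_mid: float, t0: float, t1: float) -> float:
    """Closed-form integral of the shifted logistic over [t0, t1]."""
    def antideriv(t: float) -> float:
        return (k / r) * float(np.logaddexp(0.0, r * (t - t_mid)))

    return antideriv(t1) - antideriv(t0)


def generate_growth_curves(
    k: float = 1.0,
    r: float = 0.5,
    t_mid: float = 10.0,
    noise_sd: float = 0.0,
    horizon: float = 48.0,
    step: float = 0.5,
    seed: int | None = None,
    boost: float = 1.0,
    n_replicates: int = 3,
    strain: str = "isolate",
) -> tuple[list[GrowthCurve], list[GrowthCurve]]:
    """Paired (treatment, control) logistic OD600 curves read every ``step`` h.

    The treatment carrying capacity is ``k * boost`` so the noiseless AUC
    ratio equals ``boost`` exactly.  Noise is additive Gaussian, clamped at 0.
    """
    if k <= 0 or r <= 0 or step <= 0:
        raise SpecError("k, r, and step must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, horizon + step / 2.0, step)
    treatment, control = [], []
    for rep in range(1, n_replicates + 1):
        for curves, cap, medium in (
            (treatment, k * boost, "treatment"),
            (control, k, "control"),
        ):
            od = logistic_od(t, cap, r, t_mid)
            if noise_sd > 0:
                od = od + rng.normal(0.0, noise_sd, size=t.size)
            curves.append(
                GrowthCurve(
                    times=t,
                    od600=np.maximum(od, 0.0),
                    strain=strain,
                    medium=medium,
                    replicate=rep,
                )
            )
    return treatment, control
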