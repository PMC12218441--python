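"""End-to-end orchestration of the synthetic demo experiment.

Stages: simulate -> cd_score -> sort_sim -> enrich -> ordinate -> growth.
A single global seed is expanded into per-stage sub-seeds by hashing
"<seed>:<stage>", so any stage can be re-run in isolation.  Every run emits
a manifest with the config snapshot and per-output SHA-256 checksums;
deterministic stages reproduce identical checksums for identical
config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    bray_curtis,
    ef_permutation_test,
    parse_selector,
    pcoa,
    permanova,
    read_counts,
    relative_abundance,
    results_to_frame,
)
from .errors import StimsortError
from .phenotype import GrowthCurve, growth_boost
from .simulate import (
    CommunitySpec,
    SpectrumSpec,
    generate_cell_population,
    generate_count_table,
    generate_fluid_background,
    generate_growth_curves,
    generate_sort_stream,
)
from .sorting import GateConfig, simulate_sort
from .spectra import (
    calibrate_threshold,
    classify_cells,
    percent_cd,
    read_spectrum,
    write_spectrum,
)

logger = logging.getLogger("stimsort.pipeline")

ALL_STAGES = ("simulate", "cd_score", "sort_sim", "enrich", "ordinate", "growth")


@dataclass
class PipelineConfig:
    outdir: str = "stimsort_run"
    seed: int = 1
    stages: tuple = ALL_STAGES
    # spectra / scoring
    n_control_cells: int = 35
    n_cells_per_sample: int = 35
    labeled_fraction: float = 0.6
    cd_active_mean: float = 25.0
    cd_active_sd: float = 6.0
    cd_null_mean: float = 1.0
    cd_null_sd: float = 0.5
    spectrum_noise_sd: float = 0.05
    baseline_mode: str = "local_linear"
    # gate
    pc_threshold: float = 1.2
    pl_threshold: float = 5.7
    n_sort_events: int = 200
    # community
    n_donors: int = 6
    n_genera: int = 40
    reads_per_sample: int = 20000
    donor_effect_sd: float = 2.0
    dispersion: float = 200.0
    n_replicates: int = 2
    responders: dict = field(default_factory=lambda: {"g005": 2.0, "g017": 1.5})
    responder_base_boost: float = 1.0
    n_perm: int = 999
    treat_selector: str = "fraction=boncat_pos,treatment=lactulose"
    ref_selector: str = "fraction=dapi_neg,treatment=none"
    # growth
    growth_boost_true: float = 2.0
    growth_noise_sd: float = 0.0
    # optional pre-existing inputs (used when the simulate stage is disabled)
    spectra_dir: str | None = None
    control_dir: str | None = None
    fluid_path: str | None = None
    counts_path: str | None = None
    meta_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StimsortError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**32)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the run manifest (also written
    to ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in config.stages:
        if name not in ALL_STAGES:
            raise StimsortError(f"unknown stage {name!r}")

    # validate declared external inputs before any stage runs
    if "simulate" not in config.stages:
        for attr in ("spectra_dir", "control_dir", "fluid_path", "counts_path", "meta_path"):
            value = getattr(config, attr)
            if value is not None and not Path(value).exists():
                raise StimsortError(f"input path for {attr} does not exist: {value}")

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": {},
        "checksums": {},
    }
    paths = {
        "spectra_dir": Path(config.spectra_dir) if config.spectra_dir else out / "spectra",
        "control_dir": Path(config.control_dir) if config.control_dir else out / "controls",
        "fluid_path": Path(config.fluid_path) if config.fluid_path else out / "fluid.txt",
        "counts_path": Path(config.counts_path) if config.counts_path else out / "counts.tsv",
        "meta_path": Path(config.meta_path) if config.meta_path else out / "metadata.tsv",
    }

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        seed = stage_seed(config.seed, stage)
        logger.info("stage=%s seed=%d start", stage, seed)
        outputs = _STAGE_FUNCS[stage](config, paths, out, seed)
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {
            "seed": seed,
            "wall_clock_s": round(elapsed, 3),
            "outputs": [str(p) for p in outputs],
        }
        for p in outputs:
            if p.is_file():
                manifest["checksums"][str(p.relative_to(out))] = _sha256(p)
        logger.info("stage=%s done in %.2fs (%d outputs)", stage, elapsed, len(outputs))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations

def _stage_simulate(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    rng = np.random.default_rng(seed)
    base = SpectrumSpec(noise_sd=config.spectrum_noise_sd)
    outputs: list[Path] = []

    controls = generate_cell_population(
        config.n_control_cells,
        labeled_fraction=0.0,
        cd_active_mean=config.cd_active_mean,
        cd_active_sd=config.cd_active_sd,
        cd_null_mean=config.cd_null_mean,
        cd_null_sd=config.cd_null_sd,
        seed=int(rng.integers(2**31)),
        base_spec=base,
        id_prefix="ctrl",
    )
    cells = generate_cell_population(
        config.n_cells_per_sample,
        labeled_fraction=config.labeled_fraction,
        cd_active_mean=config.cd_active_mean,
        cd_active_sd=config.cd_active_sd,
        cd_null_mean=config.cd_null_mean,
        cd_null_sd=config.cd_null_sd,
        seed=int(rng.integers(2**31)),
        base_spec=base,
        id_prefix="cell",
    )
    paths["control_dir"].mkdir(parents=True, exist_ok=True)
    paths["spectra_dir"].mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for population, directory in ((controls, paths["control_dir"]), (cells, paths["spectra_dir"])):
        for spectrum, truth in population:
            write_spectrum(spectrum, directory / f"{spectrum.cell_id}.txt")
            truth_rows.append(
                {
                    "cell_id": truth.cell_id,
                    "labeled": truth.labeled,
                    "percent_cd_true": truth.percent_cd_true,
                }
            )
    truth_path = out / "cell_truth.tsv"
    _write_tsv(pd.DataFrame(truth_rows), truth_path)
    outputs += [truth_path]

    fluid = generate_fluid_background(offset=10.0)
    write_spectrum(fluid, paths["fluid_path"])
    outputs.append(paths["fluid_path"])

    spec = CommunitySpec(
        n_donors=config.n_donors,
        n_genera=config.n_genera,
        reads_per_sample=config.reads_per_sample,
        donor_effect_sd=config.donor_effect_sd,
        dispersion=config.dispersion,
        n_replicates=config.n_replicates,
        responders=dict(config.responders),
        responder_base_boost=config.responder_base_boost,
    )
    table, truth = generate_count_table(spec, seed=int(rng.integers(2**31)))
    counts_df = table.to_frame()
    counts_df.index.name = "genus"
    counts_df.to_csv(paths["counts_path"], sep="\t")
    meta_df = pd.DataFrame(
        [{"sample_id": s, **table.sample_meta[s]} for s in table.samples]
    )
    _write_tsv(meta_df, paths["meta_path"])
    planted = pd.DataFrame(
        [{"genus": g, "log_effect": e} for g, e in truth.responders.items()]
    )
    planted_path = out / "community_truth.tsv"
    _write_tsv(planted, planted_path)
    outputs += [paths["counts_path"], paths["meta_path"], planted_path]

    logger.info(
        "stage=simulate cells=%d controls=%d samples=%d",
        len(cells), len(controls), len(table.samples),
    )
    return outputs


def _read_dir_scores(directory: Path, baseline_mode: str) -> list:
    scores = []
    for path in sorted(directory.glob("*.txt")):
        spectrum = read_spectrum(path)
        scores.append(percent_cd(spectrum))
    return scores


def _stage_cd_score(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    control_scores = _read_dir_scores(paths["control_dir"], config.baseline_mode)
    threshold = calibrate_threshold([s.percent_cd for s in control_scores])
    scores = _read_dir_scores(paths["spectra_dir"], config.baseline_mode)
    classified = classify_cells(scores, threshold)
    df = pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "donor": s.sample_meta.get("donor", ""),
                "treatment": s.sample_meta.get("treatment", ""),
                "percent_cd": s.percent_cd,
                "labeled": s.labeled,
            }
            for s in classified
        ]
    )
    scores_path = out / "cd_scores.tsv"
    _write_tsv(df, scores_path)
    thr_path = out / "threshold.json"
    with open(thr_path, "w") as fh:
        json.dump(
            {
                "value": threshold.value,
                "control_mean": threshold.control_mean,
                "control_sd": threshold.control_sd,
                "n_control": threshold.n_control,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    logger.info(
        "stage=cd_score cells=%d labeled=%d threshold=%.3f",
        len(classified), sum(bool(s.labeled) for s in classified), threshold.value,
    )
    return [scores_path, thr_path]


def _stage_sort_sim(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    stream, fluid = generate_sort_stream(
        config.n_sort_events, labeled_fraction=0.5, seed=seed
    )
    cfg = GateConfig(
        pc_threshold=config.pc_threshold, pl_threshold=config.pl_threshold
    )
    summary, events = simulate_sort(stream, fluid, cfg)
    events_df = pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "pc": e.pc,
                "pl": e.pl,
                "decision": e.decision,
                "truth_labeled": e.truth_labeled,
            }
            for e in events
        ]
    )
    events_path = out / "sort_events.tsv"
    _write_tsv(events_df, events_path)
    summary_path = out / "sort_summary.json"
    with open(summary_path, "w") as fh:
        json.dump(dataclasses.asdict(summary), fh, indent=2, sort_keys=True)
    logger.info(
        "stage=sort_sim events=%d collected=%d sensitivity=%s",
        summary.n_events, summary.n_collected, summary.sensitivity,
    )
    return [events_path, summary_path]


def _stage_enrich(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    table = read_counts(paths["counts_path"], paths["meta_path"])
    results = ef_permutation_test(
        table,
        parse_selector(config.treat_selector),
        parse_selector(config.ref_selector),
        n_perm=config.n_perm,
        seed=seed,
    )
    df = results_to_frame(results)
    ef_path = out / "enrichment.tsv"
    _write_tsv(df, ef_path)
    n_sig = int(((df["p_adj"] < 0.05) & (df["ef"] > 0)).sum())
    logger.info("stage=enrich genera=%d significant=%d", len(df), n_sig)
    return [ef_path]


def _stage_ordinate(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    table = read_counts(paths["counts_path"], paths["meta_path"])
    ra = relative_abundance(table)
    dist = bray_curtis(ra)
    ordination = pcoa(dist, sample_ids=table.samples)
    n_axes = min(3, ordination.coordinates.shape[1])
    coords = pd.DataFrame(
        ordination.coordinates[:, :n_axes],
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    coords.insert(0, "sample_id", table.samples)
    coords_path = out / "pcoa_coordinates.tsv"
    _write_tsv(coords, coords_path)

    donors = [table.meta_value(s, "donor") for s in table.samples]
    result = permanova(dist, donors, n_perm=config.n_perm, seed=seed)
    perma_path = out / "permanova.json"
    with open(perma_path, "w") as fh:
        json.dump(dataclasses.asdict(result), fh, indent=2, sort_keys=True)
    logger.info(
        "stage=ordinate samples=%d donor_R2=%.3f p=%.4f",
        len(table.samples), result.r2, result.p,
    )
    return [coords_path, perma_path]


def _stage_growth(config: PipelineConfig, paths: dict, out: Path, seed: int) -> list[Path]:
    treatment, control = generate_growth_curves(
        boost=config.growth_boost_true,
        noise_sd=config.growth_noise_sd,
        seed=seed,
    )
    rows = []
    for tr, ct in zip(treatment, control):
        gb = growth_boost(tr, ct, blank=0.0)
        rows.append(
            {
                "strain": tr.strain,
                "replicate": tr.replicate,
                "auc_treatment": gb.auc_treatment,
                "auc_control": gb.auc_control,
                "boost": gb.boost,
            }
        )
    growth_path = out / "growth_boost.tsv"
    _write_tsv(pd.DataFrame(rows), growth_path)
    logger.info("stage=growth replicates=%d", len(rows))
    return [growth_path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cd_score": _stage_cd_score,
    "sort_sim": _stage_sort_sim,
    "enrich": _stage_enrich,
    "ordinate": _stage_ordinate,
    "growth": _stage_growth,
}
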