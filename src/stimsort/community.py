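"""Sorted-fraction community statistics.

Implements, from their distance/partitioning definitions rather than by
delegating to an ecology package: relative abundance, the signed bounded
enrichment factor EF = (a - b)/(a + b), a within-donor permutation test on
cohort EF with Benjamini-Hochberg correction, Bray-Curtis dissimilarity,
classical-scaling PCoA, and one-way PERMANOVA with permutation (or exact
enumeration) p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContrastError,
    DegenerateDesignError,
    DomainError,
    EmptySampleError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "CountTable",
    "EnrichmentResult",
    "OrdinationResult",
    "PermanovaResult",
    "read_counts",
    "read_metadata",
    "parse_selector",
    "relative_abundance",
    "enrichment_factor",
    "ef_table",
    "ef_permutation_test",
    "results_to_frame",
    "bh_adjust",
    "bray_curtis",
    "pcoa",
    "permanova",
]

REQUIRED_META = ("donor",)


@dataclass
class CountTable:
    """Genus-by-sample integer counts with per-sample metadata.

    ``counts`` has shape (len(taxa), len(samples)).  Metadata maps each
    sample id to a dict; ``donor`` is mandatory, the remaining keys
    (treatment, fraction, timepoint_h, replicate) are free-form and consumed
    by selectors.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray
    sample_meta: dict[str, dict]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError(
                f"counts shape {counts.shape} != (taxa={len(self.taxa)}, "
                f"samples={len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        for s in self.samples:
            meta = self.sample_meta.get(s)
            if meta is None:
                raise ValidationError(f"sample {s!r} has no metadata")
            for key in REQUIRED_META:
                if key not in meta:
                    raise ValidationError(f"sample {s!r} missing metadata {key!r}")
        self.counts = counts

    def meta_value(self, sample: str, key: str):
        return self.sample_meta[sample].get(key)

    def select(self, selector: Mapping[str, str]) -> list[int]:
        """Indices of samples whose metadata matches every key=value pair."""
        out = []
        for j, s in enumerate(self.samples):
            meta = self.sample_meta[s]
            if all(str(meta.get(k)) == str(v) for k, v in selector.items()):
                out.append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)


@dataclass
class EnrichmentResult:
    genus: str
    ef: float
    baseline_ra: float
    p: float | None = None
    p_adj: float | None = None
    n_samples: int = 0
    donor_efs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.ef <= 1.0:
            raise ValidationError(f"EF must lie in [-1, 1], got {self.ef}")
        for name, v in (("p", self.p), ("p_adj", self.p_adj)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class OrdinationResult:
    """Classical-scaling coordinates; eigenvalues sorted non-increasing.

    ``coordinates`` keeps only axes with positive eigenvalues; the full
    (possibly negative) spectrum is retained in ``eigenvalues`` for
    inspection, and ``variance_explained`` is over the positive part.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    sample_ids: list[str] | None = None


@dataclass
class PermanovaResult:
    r2: float
    f: float
    p: float
    n_permutations: int
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError(f"R^2 must lie in [0, 1], got {self.r2}")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"p must lie in (0, 1], got {self.p}")


# ---------------------------------------------------------------------------
# I/O

def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountTable:
    """Read a TSV count table (first column genus) and a sample metadata TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    sample_meta = {s: meta.loc[s].to_dict() for s in df.columns}
    return CountTable(
        taxa=list(df.index),
        samples=list(df.columns),
        counts=df.to_numpy(),
        sample_meta=sample_meta,
    )


def read_metadata(meta_path: str | Path) -> dict[str, dict]:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return {s: meta.loc[s].to_dict() for s in meta.index}


def parse_selector(text: str) -> dict[str, str]:
    """Parse ``"fraction=boncat_pos,treatment=lactulose"`` into a dict."""
    out: dict[str, str] = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"selector clause {part!r} is not key=value")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    if not out:
        raise ValueError(f"empty selector {text!r}")
    return out


# ---------------------------------------------------------------------------
# Core statistics

def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample fractions (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise EmptySampleError(
            f"sample {table.samples[zero[0]]!r} has zero total count"
        )
    return table.counts / totals.astype(float)


def enrichment_factor(ra_treat: float, ra_ref: float) -> float:
    """EF = (a - b)/(a + b); bounded in [-1, 1]; defined as 0 when both are 0."""
    if ra_treat < 0 or ra_ref < 0:
        raise DomainError("relative abundances must be non-negative")
    total = ra_treat + ra_ref
    if total == 0:
        return 0.0
    return (ra_treat - ra_ref) / total


def _ef_vector(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized EF with the 0/0 -> 0 convention."""
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ef = np.where(total > 0, (a - b) / np.where(total > 0, total, 1.0), 0.0)
    return ef


def _donor_groups(
    table: CountTable,
    treat_selector: Mapping[str, str],
    ref_selector: Mapping[str, str],
    pairing: str = "donor",
) -> dict[str, tuple[list[int], list[int]]]:
    treat_idx = table.select(treat_selector)
    ref_idx = table.select(ref_selector)
    if not treat_idx:
        raise ContrastError(f"treat selector {dict(treat_selector)} matched no samples")
    if not ref_idx:
        raise ContrastError(f"ref selector {dict(ref_selector)} matched no samples")
    groups: dict[str, tuple[list[int], list[int]]] = {}
    donors = sorted(
        {str(table.meta_value(table.samples[j], pairing)) for j in treat_idx + ref_idx}
    )
    for donor in donors:
        t = [j for j in treat_idx if str(table.meta_value(table.samples[j], pairing)) == donor]
        r = [j for j in ref_idx if str(table.meta_value(table.samples[j], pairing)) == donor]
        if not t or not r:
            raise ContrastError(
                f"{pairing} {donor!r} lacks samples on one side of the contrast"
            )
        groups[donor] = (t, r)
    return groups


def ef_table(
    table: CountTable,
    treat_selector: Mapping[str, str],
    ref_selector: Mapping[str, str],
    pairing: str = "donor",
) -> list[EnrichmentResult]:
    """Per-genus cohort EF: mean over donors of EF(mean RA treat, mean RA ref).

    ``baseline_ra`` is the mean relative abundance across the reference
    samples.  No p-values here; see :func:`ef_permutation_test`.
    """
    ra = relative_abundance(table)
    groups = _donor_groups(table, treat_selector, ref_selector, pairing)
    donor_ef = {
        donor: _ef_vector(ra[:, t].mean(axis=1), ra[:, r].mean(axis=1))
        for donor, (t, r) in groups.items()
    }
    cohort = np.mean(list(donor_ef.values()), axis=0)
    all_ref = sorted({j for _, r in groups.values() for j in r})
    baseline = ra[:, all_ref].mean(axis=1)
    n_samples = len({j for t, r in groups.values() for j in t + r})
    return [
        EnrichmentResult(
            genus=g,
            ef=float(cohort[i]),
            baseline_ra=float(baseline[i]),
            n_samples=n_samples,
            donor_efs={d: float(donor_ef[d][i]) for d in donor_ef},
        )
        for i, g in enumerate(table.taxa)
    ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def ef_permutation_test(
    table: CountTable,
    treat_selector: Mapping[str, str],
    ref_selector: Mapping[str, str],
    pairing: str = "donor",
    n_perm: int = 999,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Two-sided permutation test on the cohort EF, stratified within donors.

    The null is built by reassigning which of each donor's contrast samples
    carry the treatment label (group sizes preserved per donor).  When the
    number of distinct within-donor relabelings is <= n_perm the null is
    enumerated exhaustively and p = #{|EF_perm| >= |EF_obs|}/N (the identity
    relabeling is one of the N); otherwise relabelings are sampled and
    p = (1 + #{|EF_perm| >= |EF_obs|})/(1 + n_perm).  BH correction across
    genera.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ra = relative_abundance(table)
    groups = _donor_groups(table, treat_selector, ref_selector, pairing)
    donors = list(groups)

    # Per donor: pooled columns, number of treat slots, all slot-combinations,
    # and the per-combination EF vector over genera.
    pooled: list[np.ndarray] = []
    combos_per_donor: list[list[tuple[int, ...]]] = []
    ef_per_combo: list[np.ndarray] = []  # each (n_combos, n_genera)
    identity_combo: list[int] = []
    for donor in donors:
        t, r = groups[donor]
        cols = np.asarray(t + r)
        n_d, t_d = len(cols), len(t)
        combos = list(itertools.combinations(range(n_d), t_d))
        efs = np.empty((len(combos), len(table.taxa)))
        for ci, combo in enumerate(combos):
            mask = np.zeros(n_d, dtype=bool)
            mask[list(combo)] = True
            efs[ci] = _ef_vector(
                ra[:, cols[mask]].mean(axis=1), ra[:, cols[~mask]].mean(axis=1)
            )
        pooled.append(cols)
        combos_per_donor.append(combos)
        ef_per_combo.append(efs)
        identity_combo.append(combos.index(tuple(range(t_d))))

    n_distinct = math.prod(len(c) for c in combos_per_donor)
    if n_distinct < 2:
        raise DegenerateDesignError(
            "fewer than 2 distinct within-donor relabelings; cannot permute"
        )

    obs = np.mean(
        [ef_per_combo[d][identity_combo[d]] for d in range(len(donors))], axis=0
    )
    tol = 1e-12

    if n_distinct <= n_perm:
        exceed = np.zeros(len(table.taxa), dtype=np.int64)
        for assignment in itertools.product(
            *[range(len(c)) for c in combos_per_donor]
        ):
            ef_perm = np.mean(
                [ef_per_combo[d][ci] for d, ci in enumerate(assignment)], axis=0
            )
            exceed += np.abs(ef_perm) >= np.abs(obs) - tol
        p = exceed / n_distinct
        n_used = n_distinct
        exact = True
    else:
        rng = np.random.default_rng(seed)
        choices = np.column_stack(
            [
                rng.integers(0, len(combos_per_donor[d]), size=n_perm)
                for d in range(len(donors))
            ]
        )
        ef_perms = np.mean(
            [ef_per_combo[d][choices[:, d]] for d in range(len(donors))], axis=0
        )  # (n_perm, n_genera)
        exceed = (np.abs(ef_perms) >= np.abs(obs)[None, :] - tol).sum(axis=0)
        p = (1 + exceed) / (1 + n_perm)
        n_used = n_perm
        exact = False

    p_adj = bh_adjust(p)
    results = ef_table(table, treat_selector, ref_selector, pairing)
    for i, res in enumerate(results):
        res.p = float(p[i])
        res.p_adj = float(p_adj[i])
    _ = exact, n_used  # recorded by callers that need provenance
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten EnrichmentResults into a table with per-donor EF columns."""
    donors = sorted({d for r in results for d in r.donor_efs})
    rows = []
    for r in results:
        row: dict = {
            "genus": r.genus,
            "ef": r.ef,
            "baseline_ra": r.baseline_ra,
            "p": r.p,
            "p_adj": r.p_adj,
            "n_samples": r.n_samples,
        }
        for d in donors:
            row[f"ef_donor_{d}"] = r.donor_efs.get(d)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distances, ordination, PERMANOVA

def bray_curtis(profiles: np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity between sample columns.

    ``profiles`` is taxa x samples (counts or fractions).
    d(x, y) = 1 - 2 * sum(min(x_i, y_i)) / sum(x_i + y_i).
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InsufficientDataError("need a 2-D taxa x samples array with >= 2 samples")
    if (x < 0).any():
        raise DomainError("abundances must be non-negative")
    totals = x.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise EmptySampleError(f"sample column {zero[0]} is all zero")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[:, i : i + 1], x[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1 :])
    d = d + d.T
    return np.clip(d, 0.0, 1.0)


def pcoa(dist: np.ndarray, sample_ids: Sequence[str] | None = None) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    eigenvector * sqrt(eigenvalue) for the positive eigenvalues.  Negative
    eigenvalues are dropped from the coordinates but reported.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    var_exp = (
        eigvals[positive] / pos_sum if pos_sum > 0 else np.zeros(positive.sum())
    )
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained=var_exp,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_total, ss_within


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: np.ndarray,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    method: Literal["auto", "exact", "sample"] = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within analogously per group;
    pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)); R^2 =
    SS_between/SS_total.  The p-value permutes group labels: exhaustively
    over all distinct label arrangements when their number is <= n_perm (or
    method="exact"), otherwise by sampling n_perm label permutations with
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    labels = np.asarray([str(g) for g in grouping])
    n = d.shape[0]
    if labels.size != n:
        raise ValidationError("grouping length must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    k = uniq.size
    if k < 2:
        raise DegenerateDesignError("PERMANOVA needs >= 2 groups")
    if n - k < 1:
        raise DegenerateDesignError("all groups are singletons; residual df is 0")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = d**2
    f_obs = _pseudo_f(d2, labels, uniq, k)
    ss_total, ss_within = _permanova_ss(d2, labels, uniq)
    r2 = 0.0 if ss_total == 0 else (ss_total - ss_within) / ss_total
    tol = 1e-12

    n_distinct = math.factorial(n) // math.prod(math.factorial(c) for c in counts)
    use_exact = method == "exact" or (method == "auto" and n_distinct <= n_perm)

    if use_exact:
        exceed = 0
        for arrangement in _distinct_arrangements(uniq, counts, n):
            f_perm = _pseudo_f(d2, arrangement, uniq, k)
            if f_perm >= f_obs - tol:
                exceed += 1
        p = exceed / n_distinct
        n_used = n_distinct
        exact = True
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if _pseudo_f(d2, perm, uniq, k) >= f_obs - tol:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        n_used = n_perm
        exact = False

    return PermanovaResult(
        r2=float(min(max(r2, 0.0), 1.0)),
        f=float(f_obs),
        p=float(p),
        n_permutations=n_used,
        exact=exact,
    )


def _distinct_arrangements(uniq: np.ndarray, counts: np.ndarray, n: int):
    """Yield every distinct assignment of the label multiset to n positions."""
    def rec(positions: tuple[int, ...], gi: int, current: np.ndarray):
        if gi == uniq.size - 1:
            out = current.copy()
            out[list(positions)] = uniq[gi]
            yield out
            return
        for chosen in itertools.combinations(positions, counts[gi]):
            nxt = current.copy()
            nxt[list(chosen)] = uniq[gi]
            remaining = tuple(p for p in positions if p not in set(chosen))
            yield from rec(remaining, gi + 1, nxt)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=uniq.dtype))
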