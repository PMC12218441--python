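import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from stimsort.community import (
    CountTable,
    bh_adjust,
    bray_curtis,
    ef_permutation_test,
    ef_table,
    enrichment_factor,
    parse_selector,
    pcoa,
    permanova,
    read_counts,
    relative_abundance,
    results_to_frame,
)
from stimsort.errors import (
    ContrastError,
    DegenerateDesignError,
    DomainError,
    EmptySampleError,
    ValidationError,
)


def make_table(counts, donors, fractions, taxa=None):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    taxa = taxa or [f"g{i:03d}" for i in range(counts.shape[0])]
    meta = {
        s: {"donor": d, "fraction": f, "treatment": "none", "timepoint_h": 6}
        for s, d, f in zip(samples, donors, fractions)
    }
    return CountTable(taxa=taxa, samples=samples, counts=counts, sample_meta=meta)


class TestCountTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            make_table([[-1, 2]], ["D1", "D1"], ["a", "b"])

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            make_table([[1.5, 2.0]], ["D1", "D1"], ["a", "b"])

    def test_duplicate_samples_rejected(self):
        with pytest.raises(ValidationError):
            CountTable(
                taxa=["g"],
                samples=["s", "s"],
                counts=np.array([[1, 2]]),
                sample_meta={"s": {"donor": "D1"}},
            )

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValidationError):
            CountTable(
                taxa=["g"], samples=["s"], counts=np.array([[1]]), sample_meta={}
            )

    def test_selector(self):
        t = make_table([[1, 2, 3]], ["D1", "D1", "D2"], ["a", "b", "a"])
        assert t.select({"fraction": "a"}) == [0, 2]
        assert t.select({"fraction": "a", "donor": "D2"}) == [2]

    def test_roundtrip_tsv(self, tmp_path):
        t = make_table([[1, 2], [3, 4]], ["D1", "D2"], ["a", "b"])
        df = t.to_frame()
        df.index.name = "genus"
        df.to_csv(tmp_path / "counts.tsv", sep="\t")
        import pandas as pd

        pd.DataFrame(
            [{"sample_id": s, **t.sample_meta[s]} for s in t.samples]
        ).to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        back = read_counts(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
        np.testing.assert_array_equal(back.counts, t.counts)
        assert back.samples == t.samples


class TestRelativeAbundance:
    def test_simple(self):
        t = make_table([[2], [2]], ["D1"], ["a"])
        np.testing.assert_allclose(relative_abundance(t)[:, 0], [0.5, 0.5])

    def test_zero_genus(self):
        t = make_table([[0], [5]], ["D1"], ["a"])
        np.testing.assert_allclose(relative_abundance(t)[:, 0], [0.0, 1.0])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 100, size=(20, 8))
        counts[0] += 1  # no all-zero column
        t = make_table(counts, ["D1"] * 8, ["a"] * 8)
        np.testing.assert_allclose(
            relative_abundance(t).sum(axis=0), np.ones(8), atol=1e-12
        )

    def test_zero_total_sample_named(self):
        t = make_table([[1, 0], [1, 0]], ["D1", "D1"], ["a", "b"])
        with pytest.raises(EmptySampleError, match="s1"):
            relative_abundance(t)


class TestEnrichmentFactor:
    def test_symmetry_zero(self):
        assert enrichment_factor(0.05, 0.05) == 0.0

    def test_absent_in_reference(self):
        assert enrichment_factor(0.08, 0.0) == 1.0

    def test_direct_arithmetic(self):
        assert enrichment_factor(0.06, 0.02) == pytest.approx(0.5)

    def test_zero_zero(self):
        assert enrichment_factor(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            enrichment_factor(-0.1, 0.2)

    @settings(max_examples=50, deadline=None)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_antisymmetry_and_bounds(self, a, b):
        ef = enrichment_factor(a, b)
        assert -1.0 <= ef <= 1.0
        assert ef == pytest.approx(-enrichment_factor(b, a), abs=1e-12)


TREAT = {"fraction": "pos"}
REF = {"fraction": "neg"}


def paired_table(counts_by_donor, taxa=None):
    """counts_by_donor: {donor: (pos_rows, neg_rows)}, each a list of
    per-sample taxa vectors."""
    blocks, donors, fractions = [], [], []
    for donor, (pos, neg) in counts_by_donor.items():
        for col in np.atleast_2d(np.asarray(pos)):
            blocks.append(col)
            donors.append(donor)
            fractions.append("pos")
        for col in np.atleast_2d(np.asarray(neg)):
            blocks.append(col)
            donors.append(donor)
            fractions.append("neg")
    return make_table(np.column_stack(blocks), donors, fractions, taxa=taxa)


class TestEfTable:
    def test_identical_groups_zero_ef(self):
        col = [10, 20, 30]
        t = paired_table({"D1": ([col], [col]), "D2": ([col], [col])})
        for r in ef_table(t, TREAT, REF):
            assert r.ef == 0.0

    def test_single_donor_cohort_equals_donor(self):
        t = paired_table({"D1": ([[10, 20, 30]], [[30, 20, 10]])})
        results = ef_table(t, TREAT, REF)
        for r in results:
            assert r.ef == pytest.approx(r.donor_efs["D1"])

    def test_doubled_genus_has_largest_ef(self):
        rng = np.random.default_rng(4)
        by_donor = {}
        for d in range(3):
            base = rng.integers(50, 150, size=6)
            pos = base.copy()
            pos[0] *= 4
            by_donor[f"D{d}"] = ([pos], [base])
        t = paired_table(by_donor)
        results = ef_table(t, TREAT, REF)
        best = max(results, key=lambda r: r.ef)
        assert best.genus == "g000"
        assert best.ef > 0

    def test_no_match_raises(self):
        t = paired_table({"D1": ([[1, 2]], [[2, 1]])})
        with pytest.raises(ContrastError):
            ef_table(t, {"fraction": "nope"}, REF)

    def test_one_sided_donor_raises(self):
        t = make_table([[1, 2]], ["D1", "D2"], ["pos", "neg"])
        with pytest.raises(ContrastError):
            ef_table(t, TREAT, REF)


class TestEfPermutationTest:
    def test_all_identical_p_one(self):
        col = [10, 20, 30]
        t = paired_table(
            {
                "D1": ([col, col], [col, col]),
                "D2": ([col, col], [col, col]),
            }
        )
        results = ef_permutation_test(t, TREAT, REF, n_perm=99, seed=0)
        for r in results:
            assert r.p == 1.0

    def test_sampled_matches_exhaustive_on_tiny_design(self):
        # 2 donors x (1 pos + 1 neg) -> 4 distinct relabelings
        t = paired_table(
            {
                "D1": ([[10, 5, 1]], [[1, 5, 10]]),
                "D2": ([[12, 6, 2]], [[2, 4, 11]]),
            }
        )
        exact = ef_permutation_test(t, TREAT, REF, n_perm=4, seed=0)
        sampled = ef_permutation_test(t, TREAT, REF, n_perm=40_000, seed=1)
        for re, rs in zip(exact, sampled):
            # sampled add-one estimator converges to the enumeration value
            assert rs.p == pytest.approx(re.p, abs=0.02)

    def test_degenerate_design(self):
        t = paired_table({"D1": ([[1, 2]], [[2, 1]])})
        # 1 donor with 1+1 samples -> C(2,1) = 2 relabelings; shrink further
        t2 = make_table([[1, 2]], ["D1", "D1"], ["pos", "pos"])
        with pytest.raises(ContrastError):
            ef_permutation_test(t2, TREAT, REF, n_perm=9)
        # the 2-relabeling design is allowed (>= 2), check it runs
        results = ef_permutation_test(t, TREAT, REF, n_perm=9)
        assert all(r.p in (0.5, 1.0) for r in results)

    def test_p_adj_ge_p_and_results_frame(self):
        rng = np.random.default_rng(8)
        t = paired_table(
            {
                f"D{d}": (
                    rng.integers(1, 100, size=(2, 5)),
                    rng.integers(1, 100, size=(2, 5)),
                )
                for d in range(3)
            }
        )
        results = ef_permutation_test(t, TREAT, REF, n_perm=199, seed=2)
        df = results_to_frame(results)
        assert (df["p_adj"] >= df["p"] - 1e-12).all()
        assert set(c for c in df.columns if c.startswith("ef_donor_")) == {
            "ef_donor_D0", "ef_donor_D1", "ef_donor_D2",
        }


class TestBhAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_step_up(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestBrayCurtis:
    def test_identical_samples(self):
        x = np.array([[1, 1], [2, 2], [3, 3]], dtype=float)
        assert bray_curtis(x)[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        x = np.array([[5, 0], [0, 3]], dtype=float)
        assert bray_curtis(x)[0, 1] == pytest.approx(1.0)

    def test_hand_computed_third(self):
        x = np.array([[2, 1], [0, 1], [1, 1]], dtype=float)
        assert bray_curtis(x)[0, 1] == pytest.approx(1.0 / 3.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=(12, 6))
        d = bray_curtis(x)
        from scipy.spatial.distance import braycurtis

        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(braycurtis(x[:, i], x[:, j]))

    def test_properties(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 5, size=(10, 5)) + 0.01
        d = bray_curtis(x)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_all_zero_sample(self):
        with pytest.raises(EmptySampleError):
            bray_curtis(np.array([[1.0, 0.0], [1.0, 0.0]]))


class TestPcoa:
    def test_two_points(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        res = pcoa(d)
        coords = np.sort(res.coordinates[:, 0])
        np.testing.assert_allclose(coords, [-2.0, 2.0], atol=1e-10)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        d = squareform(pdist(pts))
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_eigenvalues_sorted_and_variance(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(7, 3))
        res = pcoa(squareform(pdist(pts)))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 5, size=(15, 7)) + 0.01
        d = bray_curtis(x)
        mine = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        n_pos = mine.coordinates.shape[1]
        np.testing.assert_allclose(
            mine.eigenvalues[:n_pos], theirs.eigvals.values[:n_pos], atol=1e-8
        )

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            pcoa(d)


def two_cluster_distances(n_per=3, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(2 * n_per, 2))
    pts[n_per:] += sep
    return squareform(pdist(pts)), ["a"] * n_per + ["b"] * n_per


class TestPermanova:
    def test_exhaustive_matches_sampled(self):
        d, labels = two_cluster_distances(n_per=3, sep=3.0)
        exact = permanova(d, labels, method="exact")
        sampled = permanova(d, labels, n_perm=20_000, seed=3, method="sample")
        assert exact.exact and not sampled.exact
        assert sampled.p == pytest.approx(exact.p, abs=0.02)
        assert sampled.f == pytest.approx(exact.f)

    def test_separated_clusters(self):
        d, labels = two_cluster_distances(n_per=4, sep=50.0)
        res = permanova(d, labels, method="exact")
        # minimal attainable enumeration p: only the 2 arrangements
        # equivalent to the observed split reach F_obs
        assert res.p == pytest.approx(2.0 / 70.0)
        assert res.r2 > 0.9

    def test_matches_skbio_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(12)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 1.0
        d = squareform(pdist(pts))
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, labels, n_perm=99, seed=0)
        theirs = sk_permanova(skbio.DistanceMatrix(d), grouping=labels, permutations=99)
        assert mine.f == pytest.approx(float(theirs["test statistic"]))

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(100):
            pts = rng.normal(size=(10, 3))
            d = squareform(pdist(pts))
            res = permanova(d, ["a"] * 5 + ["b"] * 5, method="exact")
            ps.append(res.p)
        rate = np.mean(np.asarray(ps) <= 0.05)
        # attainable level is 12/252 ~ 0.048; binomial 3*SE ~ 0.064 at n=100
        assert abs(rate - 12.0 / 252.0) < 0.07

    def test_degenerate_designs(self):
        d = np.zeros((3, 3))
        with pytest.raises(DegenerateDesignError):
            permanova(d, ["a", "a", "a"])
        with pytest.raises(DegenerateDesignError):
            permanova(d, ["a", "b", "c"])


class TestParseSelector:
    def test_parse(self):
        sel = parse_selector("fraction=boncat_pos, treatment=lactulose")
        assert sel == {"fraction": "boncat_pos", "treatment": "lactulose"}

    def test_bad_clause(self):
        with pytest.raises(ValueError):
            parse_selector("fraction")
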