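import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from viability_bench import (
    AbundanceTable,
    DistanceMatrix,
    bray_curtis,
    group_distance_summary,
    pcoa,
    permanova,
    permanova_by_factor,
)
from viability_bench.tables_io import SampleMetadata


def _rel_table(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows[0]))]
    return AbundanceTable(
        [f"s{i}" for i in range(len(rows))], taxa, np.array(rows, dtype=float), "relative"
    )


class TestBrayCurtis:
    def test_identical_rows_give_zero(self):
        dm = bray_curtis(_rel_table([[0.5, 0.5], [0.5, 0.5]]))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_give_one(self):
        dm = bray_curtis(_rel_table([[1.0, 0.0], [0.0, 1.0]]))
        assert dm.values[0, 1] == 1.0

    def test_hand_computed_half(self):
        # x=(0.5,0.5,0), y=(1,0,0): 1 − 2·0.5/2 = 0.5
        dm = bray_curtis(_rel_table([[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]]))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_counts_are_converted_first(self):
        counts = AbundanceTable(
            ["a", "b"], ["t1", "t2"], np.array([[50.0, 50.0], [100.0, 0.0]]), "counts"
        )
        dm = bray_curtis(counts)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_empty_pair_defined_as_zero_with_warning(self):
        t = _rel_table([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="empty samples"):
            dm = bray_curtis(t)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0  # empty vs non-empty is maximal

    def test_symmetric_bounded_zero_diag(self):
        rng = np.random.default_rng(3)
        rows = rng.dirichlet(np.ones(6), size=8)
        dm = bray_curtis(_rel_table(rows.tolist()))
        assert np.allclose(dm.values, dm.values.T)
        assert dm.values.min() >= 0 and dm.values.max() <= 1
        assert np.all(np.diag(dm.values) == 0)


class TestGroupDistanceSummary:
    def _meta(self, n_free, n_treated, sample_type="screen"):
        meta = []
        for r in range(1, n_free + 1):
            meta.append(SampleMetadata(f"f{r}", sample_type, False, False, r))
        for r in range(1, n_treated + 1):
            meta.append(SampleMetadata(f"p{r}", sample_type, True, False, r))
        return meta

    def _dm(self, meta, fill=0.3):
        ids = [m.sample_id for m in meta]
        v = np.full((len(ids), len(ids)), fill)
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(ids, v)

    def test_pair_counts_four_plus_four(self):
        meta = self._meta(4, 4)
        s = group_distance_summary(self._dm(meta), meta, "screen")
        assert len(s.within_free) == 6      # C(4,2)
        assert len(s.within_treated) == 6
        assert len(s.between_paired) == 4   # replicate-matched only

    def test_single_replicate_per_arm(self):
        meta = self._meta(1, 1)
        s = group_distance_summary(self._dm(meta), meta, "screen")
        assert len(s.within_free) == 0 and len(s.within_treated) == 0
        assert len(s.between_paired) == 1

    def test_identical_arms_between_zero(self):
        meta = self._meta(2, 2)
        ids = [m.sample_id for m in meta]
        v = np.zeros((4, 4))
        s = group_distance_summary(DistanceMatrix(ids, v), meta, "screen")
        assert np.all(s.between_paired == 0)

    def test_missing_arm_errors(self):
        meta = self._meta(3, 0)
        with pytest.raises(ValueError, match="arms"):
            group_distance_summary(self._dm(meta), meta, "screen")


class TestPcoa:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        v = np.full((3, 3), 0.8)
        np.fill_diagonal(v, 0.0)
        ordn = pcoa(DistanceMatrix(["a", "b", "c"], v))
        assert len(ordn.eigenvalues) == 2
        assert ordn.eigenvalues[0] == pytest.approx(ordn.eigenvalues[1], rel=1e-9)
        assert ordn.proportion_explained.sum() == pytest.approx(1.0)

    def test_duplicated_sample_coincident_coordinates(self):
        rows = [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.2, 0.8]]
        ordn = pcoa(bray_curtis(_rel_table(rows)))
        assert np.allclose(ordn.coordinates[0], ordn.coordinates[1], atol=1e-9)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 0.3, size=(6, 3))  # pairwise distances stay < 1
        d = squareform(pdist(pts))
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        d_back = squareform(pdist(ordn.coordinates))
        assert np.allclose(d_back, d, atol=1e-9)

    def test_axes_ordered_and_truncated(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.ones(5), size=7)
        ordn = pcoa(bray_curtis(_rel_table(rows.tolist())), n_axes=2)
        assert ordn.coordinates.shape == (7, 2)
        assert np.all(np.diff(ordn.eigenvalues) <= 1e-12)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(5)
        rows = rng.dirichlet(np.ones(6), size=8)
        dm = bray_curtis(_rel_table(rows.tolist()))
        ours = pcoa(dm)
        ref = skbio_pcoa(skbio.DistanceMatrix(dm.values, dm.ids))
        k = len(ours.eigenvalues)
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1], ref.eigvals.values[:k], atol=1e-9
        )
        # coordinates agree up to per-axis sign
        for j in range(min(3, k)):
            ref_axis = ref.samples.values[:, j]
            assert np.allclose(ours.coordinates[:, j], ref_axis, atol=1e-8) or np.allclose(
                ours.coordinates[:, j], -ref_axis, atol=1e-8
            )


def _two_group_dm(n_per=3, within=0.1, between=0.9):
    n = 2 * n_per
    v = np.full((n, n), between)
    for block in (slice(0, n_per), slice(n_per, n)):
        v[block, block] = within
    np.fill_diagonal(v, 0.0)
    ids = [f"s{i}" for i in range(n)]
    labels = ["g1"] * n_per + ["g2"] * n_per
    return DistanceMatrix(ids, v), labels


def _brute_force_exact_p(dm, labels):
    """Independent oracle: enumerate every assignment of group labels to
    positions and count pseudo-F values at least as extreme, computing F
    from first principles each time."""
    d2 = dm.values ** 2
    n = len(labels)

    def f_stat(lbls):
        ss_total = sum(d2[i, j] for i, j in itertools.combinations(range(n), 2)) / n
        ss_within = 0.0
        groups = set(lbls)
        for g in groups:
            idx = [i for i, l in enumerate(lbls) if l == g]
            ss_within += sum(
                d2[i, j] for i, j in itertools.combinations(idx, 2)
            ) / len(idx)
        a = len(groups)
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    assignments = {p for p in itertools.permutations(labels)}
    hits = sum(f_stat(list(p)) >= f_obs - 1e-12 for p in assignments)
    return hits / len(assignments)


class TestPermanova:
    def test_maximal_separation(self):
        dm, labels = _two_group_dm(within=0.0, between=1.0)
        res = permanova(dm, labels, method="exact")
        assert res.r_squared == pytest.approx(1.0)
        # only the two label-swapped assignments reach F = inf
        assert res.p_value == pytest.approx(2 / 20)

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        rows = rng.dirichlet(np.ones(4), size=6)
        dm = bray_curtis(_rel_table(rows.tolist()))
        labels = ["g1", "g1", "g1", "g2", "g2", "g2"]
        res = permanova(dm, labels, method="exact")
        assert res.p_value == pytest.approx(_brute_force_exact_p(dm, labels))

    def test_seeded_p_value_reproducible(self):
        dm, labels = _two_group_dm(n_per=4, within=0.2, between=0.6)
        r1 = permanova(dm, labels, n_permutations=999, seed=5)
        r2 = permanova(dm, labels, n_permutations=999, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.pseudo_f == r2.pseudo_f

    def test_r_squared_invariant_to_label_renaming(self):
        dm, labels = _two_group_dm(n_per=4, within=0.2, between=0.6)
        renamed = ["x" if l == "g1" else "y" for l in labels]
        r1 = permanova(dm, labels, n_permutations=99, seed=0)
        r2 = permanova(dm, renamed, n_permutations=99, seed=0)
        assert r1.r_squared == pytest.approx(r2.r_squared)

    def test_pseudo_f_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(21)
        rows = rng.dirichlet(np.ones(5), size=10)
        dm = bray_curtis(_rel_table(rows.tolist()))
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dm, labels, n_permutations=99, seed=1)
        ref = skbio_permanova(skbio.DistanceMatrix(dm.values, dm.ids), labels,
                              permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_degenerate_groups_rejected(self):
        dm, labels = _two_group_dm()
        with pytest.raises(ValueError, match="≥ 2 groups"):
            permanova(dm, ["g"] * dm.n)
        with pytest.raises(ValueError, match="≥ 2 samples"):
            permanova(dm, ["a"] + ["b"] * (dm.n - 1))

    def test_by_factor_bh_adjustment(self):
        dm, labels = _two_group_dm(n_per=4, within=0.1, between=0.9)
        meta = [
            SampleMetadata(sid, labels[i], i % 2 == 0, False, i + 1)
            for i, sid in enumerate(dm.ids)
        ]
        out = permanova_by_factor(
            dm, meta, factors=("sample_type", "pma_treated"),
            n_permutations=99, seed=3,
        )
        assert set(out) == {"sample_type", "pma_treated"}
        for r in out.values():
            assert r.p_adjusted is not None and r.p_adjusted >= r.p_value
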