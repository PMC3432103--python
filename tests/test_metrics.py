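"""Trait distances, ordination and the community-composition metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from conftest import random_traits
from traitscape.metrics import (
    Community,
    MetricConfig,
    TraitDistanceMatrix,
    choose_hull_axes,
    community_metrics,
    cwm_categorical,
    cwm_continuous,
    frich_hull,
    frich_single,
    gower_distance,
    hull_volume_bruteforce,
    numbers_equivalent,
    pcoa,
    per_trait_distances,
    rao_q,
)


class TestGowerDistance:
    def test_identical_species_distance_zero(self):
        rng = np.random.default_rng(0)
        tr = random_traits(rng, 4)
        tr.iloc[1] = tr.iloc[0]
        d = gower_distance(tr)
        assert d.d[0, 1] == 0.0

    def test_maximally_different_pair_distance_one(self):
        tr = pd.DataFrame(
            {
                "log_mass": [0.0, 5.0],
                "log_genlength": [0.0, 2.0],
                "migratory_class": ["non-migrant", "nomad"],
                "diet_class": ["fruit", "nectar"],
            },
            index=["a", "b"],
        )
        assert gower_distance(tr).d[0, 1] == 1.0

    def test_matches_per_trait_formula(self):
        """Element-wise recomputation of the Gower definition: mean over
        traits of range-scaled |differences| and class mismatches."""
        rng = np.random.default_rng(7)
        tr = random_traits(rng, 5)
        d = gower_distance(tr).d
        for i in range(5):
            for j in range(5):
                parts = []
                for name in ("log_mass", "log_genlength"):
                    rng_ = tr[name].max() - tr[name].min()
                    parts.append(abs(tr[name].iloc[i] - tr[name].iloc[j]) / rng_)
                for name in ("migratory_class", "diet_class"):
                    parts.append(float(tr[name].iloc[i] != tr[name].iloc[j]))
                assert np.isclose(d[i, j], np.mean(parts), atol=1e-12)

    def test_invariant_to_species_order_and_affine_rescaling(self):
        rng = np.random.default_rng(3)
        tr = random_traits(rng, 8)
        d = gower_distance(tr)
        perm = list(tr.index[::-1])
        d_perm = gower_distance(tr, species=perm)
        idx = [perm.index(s) for s in tr.index]
        np.testing.assert_allclose(d_perm.d[np.ix_(idx, idx)], d.d, atol=1e-12)
        tr2 = tr.copy()
        tr2["log_mass"] = 3.0 * tr2["log_mass"] - 10.0  # range-normalisation absorbs this
        np.testing.assert_allclose(gower_distance(tr2).d, d.d, atol=1e-12)

    def test_zero_range_trait_contributes_nothing(self):
        rng = np.random.default_rng(4)
        tr = random_traits(rng, 4)
        tr["log_genlength"] = 1.5
        d = gower_distance(tr).d
        assert np.all(np.isfinite(d))

    def test_rejects_missing_trait_values(self):
        rng = np.random.default_rng(5)
        tr = random_traits(rng, 4)
        tr.loc[tr.index[0], "log_mass"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            gower_distance(tr)


class TestPcoa:
    def test_equilateral_triangle(self):
        d = TraitDistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3))
        coords = pcoa(d).coords
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec, d.d, atol=1e-8)

    def test_points_on_a_line_need_one_axis(self):
        x = np.array([0.0, 0.3, 0.9])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(TraitDistanceMatrix(["a", "b", "c"], d))
        assert res.coords.shape[1] == 1
        np.testing.assert_allclose(squareform(pdist(res.coords)), d, atol=1e-8)

    def test_round_trip_of_euclidean_configuration(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 3))
        d = squareform(pdist(pts))
        d /= d.max()
        res = pcoa(TraitDistanceMatrix([f"s{i}" for i in range(12)], d))
        np.testing.assert_allclose(squareform(pdist(res.coords)), d, atol=1e-6)

    def test_all_zero_distances_zero_dimensional(self):
        res = pcoa(TraitDistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert res.coords.shape == (2, 0)

    def test_agrees_with_skbio(self):
        """Cross-check eigenvalues against an independent implementation."""
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        d = gower_distance(random_traits(rng, 10)).d
        ours = pcoa(TraitDistanceMatrix([f"s{i}" for i in range(10)], d))
        theirs = skbio_pcoa(d, dimensions=ours.coords.shape[1])
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues)[::-1],
            np.sort(theirs.eigvals.to_numpy())[::-1][: ours.eigenvalues.size],
            atol=1e-8,
        )


class TestCwm:
    def test_equal_abundance_is_arithmetic_mean(self):
        vals = pd.Series([1.0, 3.0, 8.0], index=["a", "b", "c"])
        comm = Community(["a", "b", "c"], np.ones(3))
        assert np.isclose(cwm_continuous(comm, vals), 4.0)

    def test_single_species_identity(self):
        vals = pd.Series([2.5], index=["a"])
        assert cwm_continuous(Community(["a"], [1.0]), vals) == 2.5

    def test_weighted_example(self):
        vals = pd.Series([2.0, 4.0], index=["a", "b"])
        assert cwm_continuous(Community(["a", "b"], [1.0, 3.0]), vals) == 3.5

    def test_bounded_by_trait_range(self):
        rng = np.random.default_rng(13)
        vals = pd.Series(rng.normal(size=6), index=list("abcdef"))
        comm = Community(list("abcdef"), rng.uniform(0.1, 5, 6))
        x = cwm_continuous(comm, vals)
        assert vals.min() <= x <= vals.max()

    def test_categorical_all_in_class(self):
        labs = pd.Series(["k", "k"], index=["a", "b"])
        assert cwm_categorical(Community(["a", "b"], [1, 2]), labs, "k") == 1.0

    def test_categorical_proportions_sum_to_one(self):
        labs = pd.Series(["k", "j", "k"], index=["a", "b", "c"])
        comm = Community(["a", "b", "c"], [1.0, 1.0, 2.0])
        props = [cwm_categorical(comm, labs, c) for c in ("k", "j")]
        assert np.isclose(sum(props), 1.0)
        assert props[0] == 0.75

    def test_categorical_unknown_class_rejected(self):
        labs = pd.Series(["k"], index=["a"])
        with pytest.raises(ValueError):
            cwm_categorical(Community(["a"], [1.0]), labs, "zz")


class TestFrich:
    def test_single_species_continuous_zero(self):
        vals = pd.Series([2.0], index=["a"])
        assert frich_single(["a"], vals, categorical=False) == 0.0

    def test_class_count(self):
        labs = pd.Series(["fruit", "fruit", "nectar"], index=["a", "b", "c"])
        assert frich_single(["a", "b", "c"], labs, categorical=True) == 2.0

    def test_continuous_range(self):
        vals = pd.Series([1.0, 2.5, 2.0], index=["a", "b", "c"])
        assert frich_single(["a", "b", "c"], vals, categorical=False) == 1.5

    def test_hull_triangle_area(self):
        vol, degenerate = frich_hull(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))
        assert not degenerate and np.isclose(vol, 0.5)

    def test_hull_collinear_degenerate(self):
        vol, degenerate = frich_hull(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))
        assert degenerate and vol == 0.0

    def test_hull_matches_bruteforce(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(size=(10, 2))
        vol, _ = frich_hull(pts)
        assert np.isclose(vol, hull_volume_bruteforce(pts), atol=1e-9)

    def test_hull_monotone_under_added_species(self):
        rng = np.random.default_rng(19)
        pts = rng.normal(size=(8, 2))
        vol_small, _ = frich_hull(pts[:5])
        vol_big, _ = frich_hull(pts)
        assert vol_big >= vol_small - 1e-12


class TestRao:
    def test_single_species_zero(self):
        d = TraitDistanceMatrix(["a"], np.zeros((1, 1)))
        assert rao_q(Community(["a"], [3.0]), d) == 0.0

    def test_two_maximally_distinct_equal_species(self):
        d = TraitDistanceMatrix(["a", "b"], 1.0 - np.eye(2))
        assert np.isclose(rao_q(Community(["a", "b"], [1.0, 1.0]), d), 0.5)

    def test_matches_nested_loop(self):
        rng = np.random.default_rng(23)
        n = 6
        m = rng.uniform(0, 1, (n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(n)]
        dm = TraitDistanceMatrix(ids, d)
        a = rng.uniform(0.5, 4.0, n)
        comm = Community(ids, a)
        q = rao_q(comm, dm)
        total = a.sum()
        expected = sum(
            d[i, j] * (a[i] / total) * (a[j] / total) for i in range(n) for j in range(n)
        )
        assert np.isclose(q, expected, atol=1e-12)

    def test_numbers_equivalent_examples(self):
        assert numbers_equivalent(0.0) == 1.0
        assert numbers_equivalent(0.5) == 2.0
        with pytest.raises(ValueError):
            numbers_equivalent(1.0)

    def test_numbers_equivalent_strictly_increasing(self):
        qs = np.linspace(0, 0.95, 40)
        vals = [numbers_equivalent(q) for q in qs]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("s", range(2, 11))
    def test_equal_abundance_maximal_distinctness_recovers_s(self, s):
        """S equally abundant, maximally distinct species have Q = (S-1)/S
        and an effective species number of exactly S."""
        ids = [f"s{i}" for i in range(s)]
        d = TraitDistanceMatrix(ids, 1.0 - np.eye(s))
        q = rao_q(Community(ids, np.ones(s)), d)
        assert np.isclose(q, (s - 1) / s, atol=1e-12)
        assert np.isclose(numbers_equivalent(q), s, atol=1e-9)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(29)
    tr = random_traits(rng, 9)
    distances = per_trait_distances(tr)
    coords = pcoa(distances["all"])
    comm = Community(list(tr.index[:5]), rng.uniform(0.5, 3.0, 5))
    return tr, distances, coords, comm


class TestCommunityMetrics:
    def test_each_value_matches_standalone_operation(self, setup):
        tr, distances, coords, comm = setup
        cfg = MetricConfig()
        vals = {
            (m.metric, m.trait_scope): m.value
            for m in community_metrics(comm, tr, distances, coords, cfg)
        }
        assert vals[("CWM", "log_mass")] == cwm_continuous(comm, tr["log_mass"])
        cls = tr["diet_class"].iloc[0]
        assert vals[("CWM", f"diet_class={cls}")] == cwm_categorical(
            comm, tr["diet_class"], cls
        )
        assert vals[("FRICH", "log_mass")] == frich_single(
            comm.species_ids, tr["log_mass"], False
        )
        n_axes = choose_hull_axes(coords, cfg.hull_mass_frac, cfg.hull_max_axes)
        assert vals[("FRICH", "all")] == frich_hull(coords.subset(comm.species_ids, n_axes))[0]
        assert vals[("FDIV", "all")] == numbers_equivalent(rao_q(comm, distances["all"]))

    def test_class_proportions_sum_to_one(self, setup):
        tr, distances, coords, comm = setup
        vals = community_metrics(comm, tr, distances, coords)
        for trait in ("migratory_class", "diet_class"):
            props = [
                m.value for m in vals
                if m.metric == "CWM" and m.trait_scope.startswith(f"{trait}=")
            ]
            assert np.isclose(sum(props), 1.0)

    def test_uniform_abundance_equals_presence_only_fdiv(self, setup):
        tr, distances, coords, comm = setup
        uniform = Community(comm.species_ids, np.ones(comm.n_species))
        scaled = Community(comm.species_ids, np.full(comm.n_species, 4.0))
        assert np.isclose(
            rao_q(uniform, distances["all"]), rao_q(scaled, distances["all"]), atol=1e-12
        )

    def test_single_species_cell_flagged_but_cwm_computed(self, setup):
        tr, distances, coords, _ = setup
        comm = Community([tr.index[0]], [2.0])
        vals = community_metrics(comm, tr, distances, coords)
        fdiv = [m for m in vals if m.metric == "FDIV"]
        assert all(m.flag == "too_few_species" and m.value == 1.0 for m in fdiv)
        cwm = [m for m in vals if m.metric == "CWM" and m.trait_scope == "log_mass"]
        assert cwm[0].value == tr["log_mass"].iloc[0]
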