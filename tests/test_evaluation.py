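"""Site splitting, regression diagnostics, SAR refits, screens, detectability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_traits
from traitscape.evaluation import (
    delaunay_weights,
    detectability_glm,
    evaluation_report,
    EvaluationResult,
    jaccard,
    observed_site_communities,
    observed_site_metrics,
    regress_estimate_on_observed,
    sar_error_model,
    split_sites,
    trait_abundance_screen,
)
from traitscape.metrics import Community, pcoa, per_trait_distances, community_metrics


def _sites(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site_id": [f"s{i:03d}" for i in range(n)],
            "row": rng.integers(0, 20, n),
            "col": rng.integers(0, 20, n),
            "quadrant": rng.integers(0, 4, n),
        }
    )


class TestSplitSites:
    def test_disjoint_exhaustive(self):
        train, evaluation = split_sites(_sites(100), n_eval=10, seed=1)
        assert len(train) == 90 and len(evaluation) == 10
        assert not set(train) & set(evaluation)

    def test_deterministic(self):
        a = split_sites(_sites(50), n_eval=7, seed=3)
        b = split_sites(_sites(50), n_eval=7, seed=3)
        assert a == b

    def test_stratified_shares_proportional(self):
        sites = _sites(200, seed=5)
        _, evaluation = split_sites(sites, n_eval=40, stratify_by="quadrant", seed=2)
        ev = sites[sites["site_id"].isin(evaluation)]
        for q, grp in sites.groupby("quadrant"):
            expected = 40 * len(grp) / 200
            got = (ev["quadrant"] == q).sum()
            assert abs(got - expected) <= 1

    def test_rejects_oversized_eval_set(self):
        with pytest.raises(ValueError):
            split_sites(_sites(10), n_eval=10)


class TestRegression:
    def test_perfect_identity_fit(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = regress_estimate_on_observed(x, x)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)
        assert res["t_unity"] == pytest.approx(0.0, abs=1e-8)

    def test_constant_estimate_has_no_precision(self):
        x = np.array([1.0, 2, 3, 4])
        res = regress_estimate_on_observed(x, np.full(4, 2.0))
        assert res["r2"] == 0.0

    def test_zero_variance_in_observed_refused(self):
        res = regress_estimate_on_observed(np.ones(5), np.arange(5.0))
        assert np.isnan(res["slope"])

    def test_unbiased_simulation_recovers_unit_slope(self):
        """y = x + noise at the real evaluation size (n = 68): the mean
        fitted slope across replicates is within 3 SE of 1."""
        rng = np.random.default_rng(77)
        slopes = []
        for _ in range(300):
            x = rng.uniform(0, 1, 68)
            y = x + rng.normal(0, 0.2, 68)
            slopes.append(regress_estimate_on_observed(x, y)["slope"])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.0) < 3 * se

    def test_one_sided_halves_p(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 0.05, 30)
        two = regress_estimate_on_observed(x, y, sided="two")
        one = regress_estimate_on_observed(x, y, sided="one")
        assert one["p_unity"] == pytest.approx(two["p_unity"] / 2)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_half_overlap(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_undefined(self):
        assert np.isnan(jaccard(set(), set()))

    @given(
        a=st.sets(st.integers(0, 20), max_size=10),
        b=st.sets(st.integers(0, 20), max_size=10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_bounded_identity(self, a, b):
        if not a and not b:
            return
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == jaccard(b, a)
        assert (j == 1.0) == (a == b)


class TestSar:
    def test_perfect_identity_slope_one(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (30, 2))
        x = rng.uniform(0, 1, 30)
        res = sar_error_model(x, x, coords)
        assert res["slope"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_ols_without_spatial_structure(self):
        """Spatially independent residuals: SAR and OLS slopes agree
        within twice their joint standard error."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            coords = rng.uniform(0, 10, (60, 2))
            x = rng.uniform(0, 1, 60)
            y = 0.8 * x + rng.normal(0, 0.1, 60)
            sar = sar_error_model(x, y, coords)
            ols = regress_estimate_on_observed(x, y)
            ols_se = (ols["slope"] - 1.0) / ols["t_unity"]
            assert abs(sar["slope"] - ols["slope"]) < 2 * np.hypot(sar["slope_se"], ols_se)

    def test_no_autocorrelation_rarely_significant(self):
        rng = np.random.default_rng(3)
        n_sig = 0
        for _ in range(20):
            coords = rng.uniform(0, 10, (60, 2))
            x = rng.uniform(0, 1, 60)
            y = x + rng.normal(0, 0.2, 60)
            res = sar_error_model(x, y, coords)
            n_sig += res["lr_lambda_p"] < 0.05
        assert 20 - n_sig >= 18  # lambda = 0 accepted in >= 90% of sims

    def test_duplicate_coordinates_jittered(self):
        rng = np.random.default_rng(4)
        coords = np.repeat(rng.uniform(0, 5, (6, 2)), 3, axis=0)
        x = rng.uniform(0, 1, 18)
        y = x + rng.normal(0, 0.1, 18)
        res = sar_error_model(x, y, coords)
        assert np.isfinite(res["slope"])

    def test_weights_row_standardised(self):
        rng = np.random.default_rng(6)
        W = delaunay_weights(rng.uniform(0, 1, (15, 2)))
        np.testing.assert_allclose(W.sum(axis=1), 1.0)


class TestTraitAbundanceScreen:
    def _table(self, rng, n_sites, coupling):
        tr = random_traits(rng, 25)
        rows = []
        for s in range(n_sites):
            chosen = rng.choice(25, size=rng.integers(8, 20), replace=False)
            for i in chosen:
                la = coupling * tr["log_mass"].iloc[i] + rng.normal(0, 1.0)
                rows.append((f"site{s}", tr.index[i], int(np.ceil(np.exp(la)))))
        df = pd.DataFrame(rows, columns=["site_id", "species_id", "abundance"])
        return tr, df[df["abundance"] > 0]

    def test_perfect_mass_abundance_correlation(self):
        tr = random_traits(np.random.default_rng(8), 10)
        df = pd.DataFrame(
            {
                "site_id": "s0",
                "species_id": tr.index,
                "abundance": np.exp(tr["log_mass"]).to_numpy(),
            }
        )
        per_site, _ = trait_abundance_screen(df, tr)
        assert per_site["r_log_mass"].iloc[0] == pytest.approx(1.0)

    def test_identical_abundances_skipped(self):
        tr = random_traits(np.random.default_rng(9), 6)
        df = pd.DataFrame({"site_id": "s0", "species_id": tr.index, "abundance": 2.0})
        per_site, _ = trait_abundance_screen(df, tr)
        assert "r_log_mass" not in per_site.columns

    def test_null_regime_mean_correlation_near_zero(self):
        rng = np.random.default_rng(10)
        tr, df = self._table(rng, 200, coupling=0.0)
        _, summary = trait_abundance_screen(df, tr)
        assert abs(summary["mean_r_log_mass"]) < 0.1

    def test_coupled_regime_detected(self):
        rng = np.random.default_rng(11)
        tr, df = self._table(rng, 100, coupling=1.0)
        _, summary = trait_abundance_screen(df, tr)
        assert summary["mean_r_log_mass"] > 0.3


class TestDetectabilityGlm:
    def _stats(self, rng, n=60):
        tr = random_traits(rng, n)
        df = tr.reset_index(names="species_id")
        df["range_size"] = rng.integers(20, 400, n)
        return df

    def test_equal_recording_gives_null_coefficients(self):
        df = self._stats(np.random.default_rng(12))
        df["n_sites_recorded"] = 25.0
        res = detectability_glm(df)
        for name, coef in res["coefficients"].items():
            if name != "intercept":
                assert abs(coef) < 1e-6
        assert res["pct_deviance_overall"] == 0.0

    def test_range_size_driven_recording(self):
        rng = np.random.default_rng(13)
        df = self._stats(rng)
        df["n_sites_recorded"] = rng.poisson(df["range_size"] / 10.0)
        res = detectability_glm(df)
        assert res["pct_deviance_range_size"] > 0.8 * res["pct_deviance_overall"]
        assert res["pct_deviance_mass"] < 0.1 * res["pct_deviance_overall"]

    def test_requires_enough_species(self):
        df = self._stats(np.random.default_rng(14), n=10)
        df["n_sites_recorded"] = 5.0
        with pytest.raises(ValueError):
            detectability_glm(df)


class TestObservedSiteMetrics:
    def test_shared_code_path_with_map_cells(self):
        """A site community identical to a cell community yields exactly
        the same metric values (one implementation, two callers)."""
        rng = np.random.default_rng(15)
        tr = random_traits(rng, 8)
        distances = per_trait_distances(tr)
        coords = pcoa(distances["all"])
        comm = Community(list(tr.index[:4]), np.array([1.0, 2.0, 1.0, 3.0]))
        site_vals = observed_site_metrics(comm, tr, distances, coords)
        cell_vals = community_metrics(comm, tr, distances, coords, method_tag="uniform")
        for s, c in zip(site_vals, cell_vals):
            assert (s.metric, s.trait_scope) == (c.metric, c.trait_scope)
            assert s.value == c.value

    def test_single_species_site(self):
        rng = np.random.default_rng(16)
        tr = random_traits(rng, 5)
        distances = per_trait_distances(tr)
        comm = Community([tr.index[0]], [4.0])
        vals = {(m.metric, m.trait_scope): m for m in observed_site_metrics(comm, tr, distances)}
        assert vals[("CWM", "log_mass")].value == tr["log_mass"].iloc[0]
        assert vals[("FDIV", "all")].value == 1.0

    def test_sites_without_records_skipped(self):
        rec = pd.DataFrame(
            {
                "site_id": ["a", "b"],
                "species_id": ["x", "y"],
                "year": 2000,
                "count": [3, 0],
                "effort": 1.0,
            }
        )
        comms = observed_site_communities(rec, ["a", "b"])
        assert set(comms) == {"a"}


class TestEvaluationReport:
    def _result(self, **kw):
        base = dict(
            metric="CWM", trait_scope="log_mass", method_tag="uniform",
            r2=0.5, p_corr=0.01, slope=0.8, t_unity=-2.0, p_unity=0.06, n_sites=16,
        )
        base.update(kw)
        return EvaluationResult(**base)

    def test_single_pair_single_row(self):
        df = evaluation_report([self._result()])
        assert len(df) == 1

    def test_best_flags_within_groups(self):
        df = evaluation_report(
            [
                self._result(method_tag="uniform", r2=0.3, slope=0.5),
                self._result(method_tag="env_model", r2=0.6, slope=1.2),
                self._result(method_tag="survey_mean", r2=0.1, slope=0.2),
            ]
        )
        assert df.loc[df["method_tag"] == "env_model", "best_r2"].item()
        assert df.loc[df["method_tag"] == "env_model", "best_slope"].item()
        assert df["best_r2"].sum() == 1
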