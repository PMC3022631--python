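"""Profile construction: aggregation, log fold-change, moderated t, BH, ranks."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import polygamma, psi

from desearch.datamodel import ExpressionExperiment, HomologMap, ValidationError
from desearch.profiles import (
    MappingError,
    aggregate_probes_fixed_effects,
    bh_adjust,
    build_profile,
    enumerate_comparisons,
    fixed_effect_meta,
    logfc_profile,
    map_to_human,
    moderated_t_pvalues,
    rank_profile,
)


def _two_group_experiment(values, n_a, n_b, features=None, log=True):
    values = np.asarray(values, dtype=float)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ExpressionExperiment(
        "e", pd.DataFrame(values, index=features, columns=samples), groups, is_log_scale=log
    )


class TestFixedEffectAggregation:
    def test_hand_example_weighted_mean_and_variance(self):
        # two probes of one gene: values 2 and 4, variances 1 and 3
        values = pd.DataFrame({"s1": [2.0, 4.0]}, index=["p1", "p2"])
        variances = pd.Series([1.0, 3.0], index=["p1", "p2"])
        grouping = pd.Series({"p1": "g", "p2": "g"})
        agg, gvar = fixed_effect_meta(values, variances, grouping)
        assert agg.loc["g", "s1"] == pytest.approx((2 / 1 + 4 / 3) / (1 + 1 / 3))
        assert agg.loc["g", "s1"] == pytest.approx(2.5)
        assert gvar["g"] == pytest.approx(0.75)

    def test_single_probe_gene_passes_through(self):
        exp = _two_group_experiment(np.arange(8.0).reshape(2, 4), 2, 2, ["p1", "p2"])
        out = aggregate_probes_fixed_effects(exp, {"p1": "gX", "p2": "gY"})
        np.testing.assert_allclose(out.values.loc["gX"], exp.values.loc["p1"])
        assert out.feature_variances["gX"] == pytest.approx(exp.values.loc["p1"].var(ddof=1))

    def test_equal_variance_probes_average_plainly(self):
        base = np.array([1.0, 3.0, 5.0, 7.0])
        exp = _two_group_experiment(np.vstack([base, base + 2.0]), 2, 2, ["p1", "p2"])
        out = aggregate_probes_fixed_effects(exp, {"p1": "g", "p2": "g"})
        np.testing.assert_allclose(out.values.loc["g"], base + 1.0)

    def test_unmapped_probes_dropped_and_empty_map_errors(self):
        exp = _two_group_experiment(np.arange(8.0).reshape(2, 4), 2, 2, ["p1", "p2"])
        out = aggregate_probes_fixed_effects(exp, {"p1": "g1"})
        assert out.feature_ids == ["g1"]
        with pytest.raises(ValidationError):
            aggregate_probes_fixed_effects(exp, {"q9": "g"})


class TestLogFC:
    def test_identical_groups_score_zero(self):
        vals = np.tile(np.array([[1.0, 2.0]]).T, (1, 2)).reshape(1, 4)
        exp = _two_group_experiment(np.array([[5.0, 6.0, 5.0, 6.0]]), 2, 2)
        prof = logfc_profile(exp, "A", "B")
        np.testing.assert_allclose(prof.scores, 0.0)

    def test_hand_example(self):
        exp = _two_group_experiment(np.array([[2.0, 4.0, 1.0, 1.0]]), 2, 2)
        prof = logfc_profile(exp, "A", "B")
        assert prof.scores[0] == pytest.approx(2.0)
        assert prof.comparison == ("A", "B")

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        exp = _two_group_experiment(rng.normal(size=(20, 6)), 3, 3)
        ab = logfc_profile(exp, "A", "B")
        ba = logfc_profile(exp, "B", "A")
        np.testing.assert_array_equal(ab.scores, -ba.scores)

    def test_unknown_group_errors(self):
        exp = _two_group_experiment(np.ones((2, 4)), 2, 2)
        with pytest.raises(ValidationError, match="unknown group"):
            logfc_profile(exp, "A", "C")


def _oracle_prior_fit(s2, df):
    """Independent transcription of the variance-prior moment equations.

    Solves trigamma(d0/2) = Var[log s^2] - mean trigamma(df/2) by
    bisection rather than Newton, as a cross-check of the fitted prior.
    """
    z = np.log(s2)
    e = z - psi(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - np.mean(polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = optimize.brentq(lambda x: polygamma(1, x) - evar, 1e-6, 1e8)
    d0 = 2 * half_d0
    s0_2 = float(np.exp(e.mean() + psi(half_d0) - np.log(half_d0)))
    return d0, s0_2


class TestModeratedT:
    def test_zero_difference_gives_p_one(self):
        vals = np.array([[1.0, 2.0, 1.0, 2.0], [0.0, 1.0, 2.0, 4.0]])
        exp = _two_group_experiment(vals, 2, 2)
        res = moderated_t_pvalues(exp, "A", "B")
        assert res.t[0] == pytest.approx(0.0)
        assert res.pvalues_raw[0] == pytest.approx(1.0)

    def test_constant_gene_variances_drive_d0_to_infinity(self):
        rng = np.random.default_rng(7)
        # all genes share the same within-group scatter pattern -> no
        # excess dispersion of log s^2 -> infinite prior df
        row = rng.normal(0, 1, 8)
        vals = np.add.outer(rng.normal(0, 5, 50), row)
        exp = _two_group_experiment(vals, 4, 4)
        res = moderated_t_pvalues(exp, "A", "B")
        assert np.isinf(res.prior_df)

    def test_pooled_ttest_recovered_with_zero_prior_df(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(100, 9))
        exp = _two_group_experiment(vals, 4, 5)
        res = moderated_t_pvalues(exp, "A", "B", prior_df=0)
        _, p_ref = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1)
        np.testing.assert_allclose(res.pvalues_raw, p_ref, atol=1e-10)

    def test_prior_recovery_from_scaled_inv_chisq(self):
        """d0 and s0^2 recovered from data drawn with d0=4, s0^2=1."""
        d0_true, s0_true = 4.0, 1.0
        d0_hat, s0_hat = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sig2 = d0_true * s0_true / stats.chi2.rvs(d0_true, size=200, random_state=rng)
            vals = rng.normal(0, 1, (200, 8)) * np.sqrt(sig2)[:, None]
            exp = _two_group_experiment(vals, 4, 4)
            res = moderated_t_pvalues(exp, "A", "B")
            # cross-check against the independent bisection-based fit
            ok = res.df_residual > 0
            d0_ref, s0_ref = _oracle_prior_fit(res.s2[ok], res.df_residual[ok])
            assert res.prior_df == pytest.approx(d0_ref, rel=1e-4)
            assert res.prior_var == pytest.approx(s0_ref, rel=1e-6)
            d0_hat.append(res.prior_df)
            s0_hat.append(res.prior_var)
        assert 2.0 <= np.median(d0_hat) <= 8.0
        assert all(2.0 <= d <= 8.0 for d in d0_hat)
        assert all(0.7 <= s <= 1.4 for s in s0_hat)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        exp = _two_group_experiment(rng.normal(size=(50, 8)), 4, 4)
        res = moderated_t_pvalues(exp, "A", "B")
        assert np.all(res.pvalues_adjusted >= res.pvalues_raw - 1e-15)
        assert np.all((res.pvalues_adjusted > 0) & (res.pvalues_adjusted <= 1))

    def test_global_null_fdr_is_controlled(self):
        rng = np.random.default_rng(19)
        n = 2000
        exp = _two_group_experiment(rng.normal(size=(n, 10)), 5, 5)
        res = moderated_t_pvalues(exp, "A", "B")
        frac = np.mean(res.pvalues_adjusted < 0.05)
        se = np.sqrt(0.05 * 0.95 / n)
        assert frac <= 0.05 + 2 * se


class TestBHAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(1, 51)
            p = rng.uniform(1e-6, 1.0, n)
            adj = bh_adjust(p)
            order = np.argsort(p)
            brute = np.empty(n)
            for rank_i, idx in enumerate(order):
                candidates = [
                    p[order[j]] * n / (j + 1) for j in range(rank_i, n)
                ]
                brute[idx] = min(1.0, min(candidates))
            np.testing.assert_allclose(adj, brute, rtol=1e-12)
            assert np.all(adj >= p - 1e-15)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValidationError):
                bh_adjust(np.array(bad))


class TestRankProfile:
    def test_single_probe_gene_is_rank_difference(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10, 6))
        exp = _two_group_experiment(vals, 3, 3, [f"p{i}" for i in range(10)])
        prof = rank_profile(exp, "A", "B", {f"p{i}": f"g{i}" for i in range(10)})
        ranks = pd.DataFrame(vals).rank(axis=0)
        expected = ranks.iloc[:, :3].mean(axis=1) - ranks.iloc[:, 3:].mean(axis=1)
        lookup = {f"g{i}": expected.iloc[i] for i in range(10)}
        np.testing.assert_allclose(prof.scores, [lookup[g] for g in prof.feature_ids])

    def test_multi_probe_gene_matches_pair_enumeration(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(7, 6))
        exp = _two_group_experiment(vals, 3, 3, [f"p{i}" for i in range(7)])
        pmap = {f"p{i}": "gA" if i < 4 else "gB" for i in range(7)}
        prof = rank_profile(exp, "A", "B", pmap)
        ranks = pd.DataFrame(vals, index=[f"p{i}" for i in range(7)]).rank(axis=0)
        mean_a = ranks.iloc[:, :3].mean(axis=1)
        mean_b = ranks.iloc[:, 3:].mean(axis=1)
        for gene, probes in [("gA", [f"p{i}" for i in range(4)]), ("gB", [f"p{i}" for i in range(4, 7)])]:
            pairs = [mean_a[p] - mean_b[q] for p in probes for q in probes]
            idx = list(prof.feature_ids).index(gene)
            assert prof.scores[idx] == pytest.approx(np.median(pairs))

    def test_group_mean_rank_hand_example(self):
        # probes with group-mean ranks a=(10,20), b=(12,16):
        # median(-2, -6, 8, 4) = 1.0
        pairs = np.array([10 - 12, 10 - 16, 20 - 12, 20 - 16])
        assert np.median(pairs) == pytest.approx(1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(1, 10, size=(12, 8))
        exp = _two_group_experiment(vals, 4, 4, [f"p{i}" for i in range(12)])
        pmap = {f"p{i}": f"g{i % 5}" for i in range(12)}
        prof1 = rank_profile(exp, "A", "B", pmap)
        exp2 = exp.replace(values=np.exp(exp.values * 0.7) + 5.0)
        prof2 = rank_profile(exp2, "A", "B", pmap)
        np.testing.assert_array_equal(prof1.scores, prof2.scores)


class TestMapToHuman:
    def _map(self):
        entries = {("mouse", f"m{i}"): f"H{i}" for i in range(5)}
        flags = {k: True for k in entries}
        flags[("mouse", "m4")] = False
        return HomologMap(entries=entries, one_to_one=flags)

    def _profile(self, genes):
        from desearch.datamodel import DEProfile

        return DEProfile(
            "p", "gene", np.array(genes, dtype=object), np.arange(float(len(genes)))
        )

    def test_human_identity(self):
        prof = self._profile(["H1", "H2"])
        assert map_to_human(prof, self._map(), "human") is prof

    def test_non_one_to_one_dropped(self):
        prof = self._profile([f"m{i}" for i in range(5)])
        out = map_to_human(prof, self._map(), "mouse")
        assert list(out.feature_ids) == ["H0", "H1", "H2", "H3"]
        np.testing.assert_array_equal(out.scores, [0.0, 1.0, 2.0, 3.0])

    def test_disjoint_map_fails(self):
        prof = self._profile(["x1", "x2"])
        with pytest.raises(MappingError, match="failed to map"):
            map_to_human(prof, self._map(), "mouse")


class TestEnumerateComparisons:
    def _exp(self, groups):
        samples = [f"s{i}" for i in range(2 * len(groups))]
        mapping = {s: groups[i // 2] for i, s in enumerate(samples)}
        vals = pd.DataFrame(np.ones((2, len(samples))), index=["g0", "g1"], columns=samples)
        return ExpressionExperiment("e", vals, mapping, factor="time", is_log_scale=True)

    def test_time_course_worked_example(self):
        exp = self._exp(["1 hr", "2 hr", "4 hr"])
        assert enumerate_comparisons(exp) == [("1 hr", "2 hr"), ("1 hr", "4 hr"), ("2 hr", "4 hr")]

    def test_two_groups_single_pair(self):
        assert len(enumerate_comparisons(self._exp(["A", "B"]))) == 1

    def test_five_groups_give_ten_pairs(self):
        pairs = enumerate_comparisons(self._exp(list("ABCDE")))
        assert len(pairs) == 10
        assert len(set(pairs)) == 10

    def test_single_group_errors(self):
        with pytest.raises(ValidationError):
            enumerate_comparisons(self._exp(["A", "A"]))


class TestBuildProfile:
    def test_representations_share_features_and_sign(self, small_sim):
        exp = small_sim.experiments[0]
        pmap = small_sim.probe_maps[exp.experiment_id]
        logfc = build_profile(exp, "case", "control", "logfc", pmap, small_sim.homolog_map)
        pval = build_profile(exp, "case", "control", "pvalue", pmap, small_sim.homolog_map)
        assert list(logfc.feature_ids) == list(pval.feature_ids)
        assert logfc.pvalues is not None and logfc.variances is not None
        # p-value scores carry the fold-change sign
        strong = np.abs(logfc.scores) > 1.0
        assert np.all(np.sign(pval.scores[strong]) == np.sign(logfc.scores[strong]))
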