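import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from octacrmb.metrics import CRMB_NAMES
from octacrmb.stats import (
    bh_adjust,
    cluster_crmbs,
    demographics_from_summary,
    demographics_table,
    group_difference_tests,
    kendall_matrix,
    lasso_model,
    two_proportion_chisq,
    welch_t_from_summary,
)
from conftest import random_crmb_table


def kendall_tau_b_oracle(x, y):
    """O(n²) concordant/discordant enumeration with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


class TestKendallMatrix:
    def test_self_copy_and_negation(self):
        rng = np.random.default_rng(0)
        df = random_crmb_table(0, n=30)
        df["PDCS"] = df["PDL"]
        df["FAS"] = -df["PDL"]
        corr = kendall_matrix(df)
        i = corr.variables.index("PDL")
        j = corr.variables.index("PDCS")
        k = corr.variables.index("FAS")
        assert corr.tau[i, j] == pytest.approx(1.0)
        assert corr.tau[i, k] == pytest.approx(-1.0)
        assert corr.significant[i, j]

    def test_matches_enumeration_oracle_with_ties(self):
        """tau-b equals brute-force pair enumeration on tied data."""
        rng = np.random.default_rng(7)
        df = random_crmb_table(7, n=50)
        # introduce ties
        for v in CRMB_NAMES[:4]:
            df[v] = np.round(df[v], 1)
        corr = kendall_matrix(df)
        for a in range(4):
            for b in range(a + 1, 4):
                oracle = kendall_tau_b_oracle(df[CRMB_NAMES[a]], df[CRMB_NAMES[b]])
                assert corr.tau[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_symmetry_and_bounds(self):
        corr = kendall_matrix(random_crmb_table(3, n=40))
        np.testing.assert_allclose(corr.tau, corr.tau.T)
        assert np.all(np.abs(corr.tau) <= 1 + 1e-12)
        np.testing.assert_array_equal(corr.significant, corr.significant.T)

    def test_constant_variable_flagged(self):
        df = random_crmb_table(4, n=30)
        df["MVT"] = 1.0
        corr = kendall_matrix(df)
        i = corr.variables.index("MVT")
        off_diag = [j for j in range(len(corr.variables)) if j != i]
        assert np.isnan(corr.tau[i, off_diag]).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            kendall_matrix(random_crmb_table(0, n=5))


class TestClusterCRMBs:
    def _block_table(self, seed, blocks):
        rng = np.random.default_rng(seed)
        n = 80
        cols = {}
        truth = []
        for b, members in enumerate(blocks):
            latent = rng.normal(size=n)
            for m in members:
                cols[m] = latent + rng.normal(0, 0.3, n)
                truth.append(b)
        return pd.DataFrame(cols), truth

    def test_two_perfect_blocks(self):
        df, truth = self._block_table(0, [CRMB_NAMES[:6], CRMB_NAMES[6:]])
        corr = kendall_matrix(df, variables=CRMB_NAMES)
        labels, order = cluster_crmbs(corr, n_subtrees=2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_three_engineered_clusters(self):
        df, truth = self._block_table(
            1, [CRMB_NAMES[:4], CRMB_NAMES[4:8], CRMB_NAMES[8:]]
        )
        corr = kendall_matrix(df, variables=CRMB_NAMES)
        labels, _ = cluster_crmbs(corr, n_subtrees=3)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_singletons(self):
        corr = kendall_matrix(random_crmb_table(2, n=40))
        labels, _ = cluster_crmbs(corr, n_subtrees=len(corr.variables))
        assert len(set(labels)) == len(corr.variables)

    def test_too_many_subtrees_rejected(self):
        corr = kendall_matrix(random_crmb_table(2, n=40))
        with pytest.raises(ValueError):
            cluster_crmbs(corr, n_subtrees=50)


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        df = random_crmb_table(0, n=40)
        half = df.iloc[:20].copy()
        half2 = half.copy()
        half["group"] = "normal"
        half2["group"] = "RVO"
        out = group_difference_tests(pd.concat([half, half2]))
        assert (out["p_raw"] > 0.99).all()
        assert not out["significant"].any()

    def test_signal_detected(self):
        df = random_crmb_table(1, n=73, signal=True)
        out = group_difference_tests(df)
        assert out.set_index("variable").loc["PDCS", "significant"]
        assert out.set_index("variable").loc["FAS", "significant"]

    def test_null_fdr_simulation(self):
        """Global null: any-rejection rate compatible with BH at q=0.1."""
        rng = np.random.default_rng(0)
        hits = 0
        reps = 200
        for i in range(reps):
            df = random_crmb_table(1000 + i, n=40)
            out = group_difference_tests(df)
            hits += int(out["significant"].any())
        assert hits / reps <= 0.1 + 3.5 * math.sqrt(0.1 * 0.9 / reps)

    def test_zero_variance_flagged(self):
        df = random_crmb_table(2, n=30)
        df["MVT"] = 1.0
        out = group_difference_tests(df).set_index("variable")
        assert out.loc["MVT", "flag"] == "zero-variance"


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        adj = bh_adjust([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.0266667, 0.8], rtol=1e-5)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_ties_at_one_rank(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 8), [0.04] * 8)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_monotone_and_idempotent(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        np.testing.assert_allclose(bh_adjust(adj), bh_adjust(adj))
        assert np.all((adj >= np.asarray(ps) - 1e-12) & (adj <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestProportionAndWelch:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((19, 24, 17, 13), 0.2940),
            ((15, 28, 0, 30), 0.0003),
            ((10, 10, 10, 10), 1.0),
        ],
    )
    def test_chisq_values(self, counts, expected):
        assert two_proportion_chisq(*counts) == pytest.approx(expected, abs=1e-4)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(1, 60)] * 4))
    def test_chisq_invariances(self, counts):
        a, b, c, d = counts
        p = two_proportion_chisq(a, b, c, d)
        assert two_proportion_chisq(c, d, a, b) == pytest.approx(p, rel=1e-9)
        assert two_proportion_chisq(a, c, b, d) == pytest.approx(p, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_chisq(0, 10, 0, 10)

    def test_welch_from_summary(self):
        t, df, p = welch_t_from_summary(55.42, 12.95, 43, 44.74, 15.37, 30)
        assert p == pytest.approx(0.0029, abs=0.0005)
        t2, _, p2 = welch_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t2 == 0.0 and p2 == pytest.approx(1.0)

    def test_welch_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 0.0, 10, 2, 1.0, 10)
        with pytest.raises(ValueError):
            welch_t_from_summary(1, 1.0, 1, 2, 1.0, 10)


def _signal_table(seed, n=200, family="gaussian"):
    r = np.random.default_rng(seed)
    X = pd.DataFrame(r.normal(size=(n, 12)), columns=CRMB_NAMES)
    X["age"] = r.normal(50, 10, n)
    X["sex"] = r.choice(["men", "women"], n)
    eta = 1.5 * X["PDCS"] - 1.5 * X["FAS"] + 1.2 * X["FDD"]
    if family == "gaussian":
        X["bcva_initial"] = eta + r.normal(0, 1, n)
        X["group"] = r.choice(["normal", "RVO"], n)
    else:
        prob = 1 / (1 + np.exp(-eta))
        X["group"] = np.where(r.uniform(size=n) < prob, "RVO", "normal")
        X["bcva_initial"] = r.normal(size=n)
    return X


class TestLasso:
    def test_support_recovery_gaussian(self):
        res = lasso_model(_signal_table(1), "bcva_initial", seed=0)
        assert {"PDCS", "FAS", "FDD"} <= set(res.nonzero)
        res1se = lasso_model(_signal_table(1), "bcva_initial", seed=0, rule="1se")
        assert {"PDCS", "FAS", "FDD"} <= set(res1se.nonzero)

    def test_support_recovery_binomial(self):
        res = lasso_model(_signal_table(2, family="binomial"), "rvo_status", seed=0)
        assert {"PDCS", "FAS", "FDD"} <= set(res.nonzero)
        assert res.family == "binomial" and res.lambda_selected > 0

    def test_null_near_empty_selection(self):
        """Pure-noise outcomes select (almost) nothing under the 1-SE rule."""
        clean = 0
        for s in range(5):
            r = np.random.default_rng(500 + s)
            df = pd.DataFrame(r.normal(size=(200, 12)), columns=CRMB_NAMES)
            df["bcva_initial"] = r.normal(size=200)
            df["group"] = r.choice(["normal", "RVO"], 200)
            res = lasso_model(df, "bcva_initial", seed=s, rule="1se")
            clean += len(res.nonzero) <= 1
        assert clean >= 4

    def test_duplicated_predictor_fit_quality(self):
        df = _signal_table(3)
        df["PDCS_copy"] = df["PDCS"]
        preds = CRMB_NAMES + ["PDCS_copy"]
        a = lasso_model(df, "bcva_initial", predictors=CRMB_NAMES, seed=0)
        b = lasso_model(df, "bcva_initial", predictors=preds, seed=0)
        # collinear duplicate splits the coefficient without changing the fit:
        # the L1 path depends only on the summed weight of identical columns
        assert abs(b.coefficients["PDCS"] + b.coefficients["PDCS_copy"]
                   - a.coefficients["PDCS"]) < 0.2

    def test_determinism(self):
        df = _signal_table(4)
        a = lasso_model(df, "bcva_initial", seed=3)
        b = lasso_model(df, "bcva_initial", seed=3)
        assert a.nonzero == b.nonzero
        assert a.lambda_selected == b.lambda_selected

    def test_shrinks_to_zero_at_strong_penalty(self):
        """The coefficient path vanishes as the penalty grows."""
        from sklearn.linear_model import Lasso
        df = _signal_table(5)
        X = (df[CRMB_NAMES] - df[CRMB_NAMES].mean()) / df[CRMB_NAMES].std()
        y = df["bcva_initial"].to_numpy()
        norms = [
            np.abs(Lasso(alpha=a).fit(X, y).coef_).sum()
            for a in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] == 0.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            lasso_model(_signal_table(6, n=10), "bcva_initial")


class TestDemographics:
    def test_identical_groups(self):
        df = random_crmb_table(0, n=40)
        half = df.iloc[:20].copy()
        h1, h2 = half.copy(), half.copy()
        h1["group"], h2["group"] = "normal", "RVO"
        out = demographics_table(pd.concat([h1, h2]))
        ok = out["p_raw"].notna()
        assert (out.loc[ok, "p_raw"] > 0.99).all()

    def test_row_order_invariance(self):
        df = random_crmb_table(1, n=60)
        a = demographics_table(df)
        b = demographics_table(df.sample(frac=1, random_state=0))
        merged = a.merge(b, on="row", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_raw_a"], merged["p_raw_b"])

    def test_from_summary_schema(self):
        rows = pd.DataFrame(
            [
                {"row": "x", "kind": "binary", "a": 10, "b": 20, "c": 15, "d": 15},
                {"row": "y", "kind": "continuous", "mean1": 1.0, "sd1": 0.5,
                 "n1": 20, "mean2": 1.5, "sd2": 0.5, "n2": 20},
            ]
        )
        out = demographics_from_summary(rows)
        assert list(out["row"]) == ["x", "y"]
        # BH runs on the 4-decimal (printed-precision) raw column
        rounded = np.round(out["p_raw"].to_numpy(), 4)
        assert ((out["p_adj"].to_numpy() >= rounded - 1e-12)
                & (out["p_adj"].to_numpy() <= 1)).all()
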