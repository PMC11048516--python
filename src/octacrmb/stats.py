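"""Cohort-level statistics for CRMB tables.

Covers the analysis layer applied to a case/control biomarker cohort:
pairwise Kendall rank correlations with Bonferroni control and
complete-linkage clustering of the correlation structure; per-biomarker
Welch t-tests with Benjamini-Hochberg (BH) false-discovery control;
penalized (LASSO) regression of disease status (binomial deviance) or
visual acuity (squared-error deviance) on biomarkers plus clinical
covariates, with the penalty chosen by 10-fold cross-validation; and the
demographics-table statistics (two-proportion chi-square without
continuity correction for binary rows, Welch t from summary statistics for
continuous rows, BH across the tested rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .metrics import CRMB_NAMES

DEFAULT_COVARIATES = [
    "age", "sex", "diabetes", "hypertension", "hyperlipidaemia", "atherosclerosis",
]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    tau: np.ndarray
    p_raw: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected p < alpha
    alpha: float = 0.05
    cluster_labels: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.variables, columns=self.variables)


@dataclass
class LassoResult:
    family: str
    lambda_selected: float
    coefficients: pd.Series
    cv_folds: int
    seed: int

    @property
    def nonzero(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])


def kendall_matrix(
    table: pd.DataFrame, variables: list[str] | None = None, alpha: float = 0.05
) -> CorrelationMatrix:
    """Pairwise Kendall tau-b with Bonferroni-corrected significance.

    The correction multiplies each raw two-sided p by the number of distinct
    pairs (capped at 1). Constant variables yield NaN rows/columns.
    """
    variables = variables or [v for v in CRMB_NAMES if v in table.columns]
    if len(table) < 10:
        raise ValueError("need at least 10 subjects for the correlation matrix")
    k = len(variables)
    tau = np.eye(k)
    p_raw = np.zeros((k, k))
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            x = table[variables[i]].to_numpy(dtype=float)
            y = table[variables[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                tau[i, j] = tau[j, i] = np.nan
                p_raw[i, j] = p_raw[j, i] = np.nan
                continue
            t, p = sps.kendalltau(x[ok], y[ok])
            tau[i, j] = tau[j, i] = t
            p_raw[i, j] = p_raw[j, i] = p
    with np.errstate(invalid="ignore"):
        significant = np.minimum(p_raw * n_pairs, 1.0) < alpha
    np.fill_diagonal(significant, False)
    return CorrelationMatrix(variables, tau, p_raw, significant, alpha)


def cluster_crmbs(
    corr: CorrelationMatrix, n_subtrees: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage clustering of biomarkers at distance 1 - tau.

    Returns per-variable subtree labels (dendrogram cut into ``n_subtrees``)
    and the dendrogram leaf order for heatmap display. The signed distance
    (1 - tau, not 1 - |tau|) keeps anticorrelated markers apart.
    """
    k = len(corr.variables)
    if n_subtrees > k:
        raise ValueError("more subtrees requested than variables")
    d = 1.0 - corr.tau
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(z, t=n_subtrees, criterion="maxclust")
    corr.cluster_labels = labels
    return labels, leaves_list(z)


def group_difference_tests(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group_col: str = "group",
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Welch two-sided t-test per biomarker, BH-adjusted across biomarkers."""
    variables = variables or [v for v in CRMB_NAMES if v in table.columns]
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {list(groups)}")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    rows = []
    for v in variables:
        x = a[v].dropna().to_numpy(dtype=float)
        y = b[v].dropna().to_numpy(dtype=float)
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            rows.append({"variable": v, "t": np.nan, "p_raw": np.nan,
                         "flag": "zero-variance"})
            continue
        t, p = sps.ttest_ind(x, y, equal_var=False)
        rows.append({"variable": v, "t": float(t), "p_raw": float(p), "flag": ""})
    out = pd.DataFrame(rows)
    ok = out["p_raw"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())
    out["p_adj"] = adj
    out["significant"] = out["p_adj"] < alpha
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_proportion_chisq(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square (1 df, no continuity correction) on [[a,b],[c,d]]."""
    tab = np.array([[a, b], [c, d]], dtype=float)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin in the 2x2 table")
    _, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(p)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t, Satterthwaite df, and two-sided p from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def lasso_model(
    table: pd.DataFrame,
    outcome: str = "rvo_status",
    predictors: list[str] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    rule: str = "min",
) -> LassoResult:
    """L1-penalized regression with the penalty chosen by cross-validation.

    ``rvo_status`` fits a binomial model (deviance = log loss) on the group
    label; ``bcva_initial`` fits a gaussian model (squared-error deviance).
    Continuous predictors are standardized to zero mean / unit variance and
    coefficients are reported on that standardized scale; the predictors
    with nonzero coefficients at the selected penalty are the selected
    ones. ``rule='min'`` takes the deviance-minimizing penalty;
    ``rule='1se'`` the strongest penalty within one standard error of the
    minimum (sparser; recommended when false selections are costly).
    """
    if predictors is None:
        predictors = [v for v in CRMB_NAMES if v in table.columns] + [
            c for c in DEFAULT_COVARIATES if c in table.columns
        ]
    if len(table) < 20:
        raise ValueError("need at least 20 subjects for the penalized fit")
    X = table[predictors].copy()
    for c in X.columns:
        if X[c].dtype == object or X[c].dtype == bool:
            X[c] = pd.factorize(X[c])[0].astype(float)
    X = X.to_numpy(dtype=float)
    # standardize every column; binary dummies share the scale convention
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    if outcome == "rvo_status":
        y = (table["group"].astype(str) == "RVO").to_numpy(dtype=int)
        cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
        Cs = np.logspace(-3, 3, n_lambdas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = LogisticRegressionCV(
                Cs=Cs,
                cv=cv,
                penalty="l1",
                solver="liblinear",
                scoring="neg_log_loss",
                max_iter=5000,
            ).fit(Xs, y)
            if rule == "1se":
                # scores_: (folds, n_Cs) neg log loss per fold
                scores = model.scores_[1]
                mean, se = scores.mean(0), scores.std(0, ddof=1) / np.sqrt(folds)
                best = int(np.argmax(mean))
                ok_idx = np.nonzero(mean >= mean[best] - se[best])[0]
                c_sel = float(Cs[ok_idx[0]])  # smallest C = strongest penalty
                from sklearn.linear_model import LogisticRegression
                refit = LogisticRegression(C=c_sel, penalty="l1",
                                           solver="liblinear", max_iter=5000)
                refit.fit(Xs, y)
                lam = 1.0 / c_sel
                coefs = pd.Series(refit.coef_[0], index=predictors)
            else:
                lam = float(1.0 / model.C_[0])
                coefs = pd.Series(model.coef_[0], index=predictors)
        family = "binomial"
    elif outcome == "bcva_initial":
        y = table["bcva_initial"].to_numpy(dtype=float)
        cv = KFold(folds, shuffle=True, random_state=seed)
        model = LassoCV(alphas=n_lambdas, cv=cv, max_iter=50000).fit(Xs, y)
        if rule == "1se":
            mean = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
            best = int(np.argmin(mean))
            ok_idx = np.nonzero(mean <= mean[best] + se[best])[0]
            alpha_sel = float(model.alphas_[ok_idx[0]])  # alphas_ descending
            from sklearn.linear_model import Lasso
            refit = Lasso(alpha=alpha_sel, max_iter=50000).fit(Xs, y)
            lam = alpha_sel
            coefs = pd.Series(refit.coef_, index=predictors)
        else:
            lam = float(model.alpha_)
            coefs = pd.Series(model.coef_, index=predictors)
        family = "gaussian"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    coefs[np.abs(coefs) < 1e-10] = 0.0
    return LassoResult(family, lam, coefs, folds, seed)


# ---------------------------------------------------------------------------
# Demographics ("Table 1" style) summaries


def demographics_from_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Demographics statistics from printed group summaries.

    ``rows`` needs columns: ``row`` (label), ``kind`` ('binary' or
    'continuous'); binary rows give ``a, b, c, d`` (group-1 yes/no,
    group-2 yes/no counts); continuous rows give ``mean1, sd1, n1, mean2,
    sd2, n2``. Returns the per-row raw p (chi-square or Welch) plus the
    BH-adjusted column computed across all tested rows.

    BH is applied to the p-values rounded to 4 decimals — the convention of
    published demographic tables, whose adjusted columns are derived from
    the printed raw column.
    """
    out = []
    for _, r in rows.iterrows():
        if r["kind"] == "binary":
            p = two_proportion_chisq(int(r["a"]), int(r["b"]), int(r["c"]), int(r["d"]))
            desc = f"{int(r['a'])}/{int(r['b'])} vs {int(r['c'])}/{int(r['d'])}"
        elif r["kind"] == "continuous":
            _, _, p = welch_t_from_summary(r["mean1"], r["sd1"], int(r["n1"]),
                                           r["mean2"], r["sd2"], int(r["n2"]))
            desc = (f"{r['mean1']} ± {r['sd1']} vs {r['mean2']} ± {r['sd2']}")
        else:
            raise ValueError(f"unknown row kind {r['kind']!r}")
        out.append({"row": r["row"], "summary": desc, "p_raw": p})
    df = pd.DataFrame(out)
    df["p_adj"] = bh_adjust(np.round(df["p_raw"].to_numpy(), 4))
    return df


def demographics_table(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Demographics statistics from a subject-level cohort table.

    Continuous rows (age, initial BCVA): mean ± SD per group, Welch p.
    Binary rows (sex, eye, comorbidities): counts per group, uncorrected
    chi-square p. One BH adjustment across all tested rows.
    """
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError("demographics table needs exactly two groups")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    rows = []
    binary_specs = [("sex", "men"), ("eye", "right"), ("diabetes", True),
                    ("hypertension", True), ("hyperlipidaemia", True),
                    ("atherosclerosis", True)]
    for col, level in binary_specs:
        if col not in table.columns:
            continue
        a = int((g1[col] == level).sum()); b = len(g1) - a
        c = int((g2[col] == level).sum()); d = len(g2) - c
        try:
            p = two_proportion_chisq(a, b, c, d)
        except ValueError:
            p = np.nan
        rows.append({"row": col, "kind": "binary",
                     "summary": f"{a}/{b} vs {c}/{d}", "p_raw": p})
    for col in ("age", "bcva_initial"):
        if col not in table.columns:
            continue
        x, y = g1[col].astype(float), g2[col].astype(float)
        _, _, p = welch_t_from_summary(x.mean(), x.std(ddof=1), len(x),
                                       y.mean(), y.std(ddof=1), len(y))
        rows.append({"row": col, "kind": "continuous",
                     "summary": f"{x.mean():.2f} ± {x.std(ddof=1):.2f} vs "
                                f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                     "p_raw": p})
    df = pd.DataFrame(rows)
    ok = df["p_raw"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(df.loc[ok, "p_raw"].to_numpy())
    df["p_adj"] = adj
    return df
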