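"""Cohort-level statistics over per-animal phenotypes.

Factorial ANOVAs (Collection × Knockdown, Type II sums of squares) with
Dunnett many-to-one and Tukey all-pairs post-hocs and η² effect sizes;
pooled one-way ANOVAs with a Kruskal-Wallis companion when the response
fails normality screening; a four-test normality screen; and 2×k
contingency tests (Pearson χ², G, Fisher exact) on rhythmic/arrhythmic
counts.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import lilliefors, normal_ad


@dataclass
class AnovaResult:
    factors: List[str]
    table: pd.DataFrame  # term, sum_sq, df, F, p, eta_sq, partial_eta_sq
    posthoc: List[dict] = field(default_factory=list)  # comparison, p_adj, method
    kruskal: Optional[dict] = None  # H, df, p (pooled one-way companion)
    normality: Optional[dict] = None
    degraded_to_main_effects: bool = False
    degenerate: bool = False

    def p(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        return float(row["p"].iloc[0])

    def eta_sq(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term]
        return float(row["eta_sq"].iloc[0])


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic_kind: str
    statistic: float
    df: int
    p: float
    all_stats: Dict[str, dict] = field(default_factory=dict)
    dropped_groups: List[str] = field(default_factory=list)


# ---------------------------------------------------------------- ANOVA

def _clean_df(rows: pd.DataFrame, response: str, factors: Sequence[str]) -> pd.DataFrame:
    df = rows[[response, *factors]].dropna().copy()
    df.columns = ["y", *[f"f{i}" for i in range(len(factors))]]
    for c in df.columns[1:]:
        df[c] = df[c].astype(str)
    return df


def _anova_table(fit, data: pd.DataFrame, term_names: Dict[str, str]) -> pd.DataFrame:
    aov = sm.stats.anova_lm(fit, typ=2)
    ss_total = float(((data["y"] - data["y"].mean()) ** 2).sum())
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    rows = []
    for raw, pretty in term_names.items():
        if raw not in aov.index:
            continue
        ss = float(aov.loc[raw, "sum_sq"])
        rows.append(
            dict(
                term=pretty,
                sum_sq=ss,
                df=float(aov.loc[raw, "df"]),
                F=float(aov.loc[raw, "F"]),
                p=float(aov.loc[raw, "PR(>F)"]),
                eta_sq=ss / ss_total if ss_total > 0 else np.nan,
                partial_eta_sq=ss / (ss + ss_resid) if (ss + ss_resid) > 0 else np.nan,
            )
        )
    rows.append(
        dict(term="Residual", sum_sq=ss_resid, df=float(aov.loc["Residual", "df"]),
             F=np.nan, p=np.nan, eta_sq=ss_resid / ss_total if ss_total > 0 else np.nan,
             partial_eta_sq=np.nan)
    )
    return pd.DataFrame(rows)


def _posthocs(df: pd.DataFrame, group_col: str, control_level: Optional[str]) -> List[dict]:
    levels = sorted(df[group_col].unique())
    groups = {lv: df.loc[df[group_col] == lv, "y"].to_numpy(dtype=float) for lv in levels}
    out: List[dict] = []
    if control_level is not None and str(control_level) in groups and len(levels) >= 2:
        ctrl = groups[str(control_level)]
        others = [lv for lv in levels if lv != str(control_level)]
        if others and all(groups[lv].size >= 2 for lv in others) and ctrl.size >= 2:
            res = sps.dunnett(*[groups[lv] for lv in others], control=ctrl)
            for lv, p in zip(others, np.atleast_1d(res.pvalue)):
                out.append(dict(comparison=f"{lv} vs {control_level}", p_adj=float(p),
                                method="dunnett"))
    if len(levels) >= 2 and all(g.size >= 2 for g in groups.values()):
        res = sps.tukey_hsd(*[groups[lv] for lv in levels])
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                out.append(dict(comparison=f"{levels[i]} vs {levels[j]}",
                                p_adj=float(res.pvalue[i, j]), method="tukey"))
    return out


def two_way_anova(
    rows: pd.DataFrame,
    response: str,
    factors: Tuple[str, str] = ("collection", "knockdown"),
    control_level: Optional[str] = None,
) -> AnovaResult:
    """Unbalanced two-factor ANOVA with interaction (Type II SS).

    Dunnett comparisons of each level of the second factor against
    ``control_level`` (pooled over the first factor) and Tukey all-pairs
    are reported alongside.  If any factor cell has fewer than two
    observations the interaction is dropped and a main-effects model is
    fitted instead.
    """
    df = _clean_df(rows, response, factors)
    if df["f0"].nunique() < 2 or df["f1"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    cell_sizes = df.groupby(["f0", "f1"]).size()
    full_grid = df["f0"].nunique() * df["f1"].nunique()
    degraded = (len(cell_sizes) < full_grid) or (cell_sizes.min() < 2)
    if degraded:
        warnings.warn("empty or singleton cell: fitting main effects only")
        fit = smf.ols("y ~ C(f0) + C(f1)", data=df).fit()
        names = {"C(f0)": factors[0], "C(f1)": factors[1]}
    else:
        fit = smf.ols("y ~ C(f0) * C(f1)", data=df).fit()
        names = {"C(f0)": factors[0], "C(f1)": factors[1],
                 "C(f0):C(f1)": f"{factors[0]}:{factors[1]}"}
    table = _anova_table(fit, df, names)
    return AnovaResult(
        factors=list(factors),
        table=table,
        posthoc=_posthocs(df, "f1", control_level),
        degraded_to_main_effects=degraded,
    )


def kruskal_wallis(groups: Sequence[np.ndarray]) -> dict:
    H, p = sps.kruskal(*groups)
    return dict(H=float(H), df=len(groups) - 1, p=float(p))


def one_way_pooled_anova(
    rows: pd.DataFrame,
    response: str,
    group: str = "knockdown",
    control_level: Optional[str] = None,
) -> AnovaResult:
    """Pooled one-way ANOVA with normality screening.

    When the response fails the four-test normality screen, a
    Kruskal-Wallis test is computed alongside for comparison (the
    parametric table is still reported).
    """
    df = _clean_df(rows, response, [group])
    levels = sorted(df["f0"].unique())
    groups = [df.loc[df["f0"] == lv, "y"].to_numpy(dtype=float) for lv in levels]
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(df["y"].to_numpy()) == 0:
        table = pd.DataFrame([dict(term=group, sum_sq=0.0, df=float(len(levels) - 1),
                                   F=np.nan, p=np.nan, eta_sq=np.nan,
                                   partial_eta_sq=np.nan)])
        return AnovaResult(factors=[group], table=table, degenerate=True)
    fit = smf.ols("y ~ C(f0)", data=df).fit()
    table = _anova_table(fit, df, {"C(f0)": group})
    screen = normality_screen(df["y"].to_numpy(dtype=float))
    kr = None
    if not screen["passed"] and all(g.size >= 2 for g in groups):
        kr = kruskal_wallis(groups)
    return AnovaResult(
        factors=[group],
        table=table,
        posthoc=_posthocs(df, "f0", control_level),
        kruskal=kr,
        normality=screen,
    )


# ------------------------------------------------------- normality screen

def normality_screen(values: np.ndarray, alpha: float = 0.05) -> dict:
    """Four-test normality screen: pass = at least two tests with p > alpha.

    Tests: Anderson-Darling, D'Agostino-Pearson, Shapiro-Wilk and
    (Lilliefors-corrected) Kolmogorov-Smirnov.  With fewer than 8 values
    or a constant vector the screen fails conservatively.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    out: dict = {"n": int(x.size), "pvalues": {}, "passed": False, "reason": None}
    if x.size < 8:
        out["reason"] = "n < 8"
        return out
    if np.ptp(x) == 0:
        out["reason"] = "constant vector"
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            out["pvalues"]["anderson_darling"] = float(normal_ad(x)[1])
        except Exception:
            pass
        if x.size >= 20:
            out["pvalues"]["dagostino_pearson"] = float(sps.normaltest(x).pvalue)
        try:
            out["pvalues"]["shapiro_wilk"] = float(sps.shapiro(x).pvalue)
        except Exception:
            pass
        out["pvalues"]["kolmogorov_smirnov"] = float(lilliefors(x, dist="norm")[1])
    out["passed"] = sum(p > alpha for p in out["pvalues"].values()) >= 2
    return out


# ------------------------------------------------------- contingency tests

def pearson_chi2_2xk(table: np.ndarray) -> Tuple[float, int, float]:
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def g_test_2xk(table: np.ndarray) -> Tuple[float, int, float]:
    res = sps.chi2_contingency(table, correction=False, lambda_="log-likelihood")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Exact conditional p-value for a 2×k table (fixed margins).

    Enumerates all tables with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table.  Feasible for the cohort sizes seen here (k ≤ 4,
    n of a few hundred).
    """
    table = np.asarray(table, dtype=int)
    col_tot = table.sum(axis=0)
    row0 = int(table[0].sum())
    k = table.shape[1]

    lf = [math.lgamma(i + 1) for i in range(int(table.sum()) + 1)]

    def log_prob(top: Sequence[int]) -> float:
        # product of per-column binomials over the top-row margin binomial
        lp = 0.0
        for c in range(k):
            n_c, a_c = int(col_tot[c]), int(top[c])
            lp += lf[n_c] - lf[a_c] - lf[n_c - a_c]
        N = int(table.sum())
        lp -= lf[N] - lf[row0] - lf[N - row0]
        return lp

    obs_lp = log_prob(table[0])
    total = 0.0
    extreme = 0.0

    def rec(c: int, remaining: int, lp_acc: float):
        nonlocal total, extreme
        if c == k - 1:
            if 0 <= remaining <= col_tot[c]:
                lp = lp_acc + lf[col_tot[c]] - lf[remaining] - lf[col_tot[c] - remaining]
                N = int(table.sum())
                lp -= lf[N] - lf[row0] - lf[N - row0]
                pr = math.exp(lp)
                total += pr
                if lp <= obs_lp + 1e-12:
                    extreme += pr
            return
        lo = max(0, remaining - int(col_tot[c + 1 :].sum()))
        hi = min(int(col_tot[c]), remaining)
        for a in range(lo, hi + 1):
            rec(c + 1, remaining - a, lp_acc + lf[col_tot[c]] - lf[a] - lf[col_tot[c] - a])

    rec(0, row0, 0.0)
    return float(min(1.0, extreme / total))


def rhythmicity_contingency(
    calls: Dict[str, Tuple[int, int]],
    statistic_kind: str = "pearson_chi2",
) -> ContingencyResult:
    """Contingency test on per-group (n_rhythmic, n_arrhythmic) counts.

    All three statistics (Pearson χ², G, Fisher exact) are computed side
    by side; ``statistic_kind`` selects which one heads the result.
    Groups with zero total are dropped with a warning.
    """
    if statistic_kind not in ("pearson_chi2", "g_test", "fisher_exact"):
        raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
    kept, dropped = {}, []
    for grp, (nr, na) in calls.items():
        if nr + na == 0:
            dropped.append(grp)
            warnings.warn(f"group {grp!r} has zero total; dropped")
        else:
            kept[grp] = (int(nr), int(na))
    if len(kept) < 2:
        raise ValueError("need at least two non-empty groups")
    table = np.array([[v[0] for v in kept.values()], [v[1] for v in kept.values()]])
    k = table.shape[1]
    chi2, df, p_chi2 = pearson_chi2_2xk(table)
    g, _, p_g = g_test_2xk(table)
    p_fisher = fisher_exact_2xk(table)
    all_stats = {
        "pearson_chi2": dict(statistic=chi2, df=df, p=p_chi2),
        "g_test": dict(statistic=g, df=df, p=p_g),
        "fisher_exact": dict(statistic=np.nan, df=k - 1, p=p_fisher),
    }
    head = all_stats[statistic_kind]
    return ContingencyResult(
        table=table,
        statistic_kind=statistic_kind,
        statistic=float(head["statistic"]),
        df=int(head["df"]),
        p=float(head["p"]),
        all_stats=all_stats,
        dropped_groups=dropped,
    )
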