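"""Group-statistics layer of the pipeline.

Variance-equality gating (Levene), two-way sex x intervention ANOVA
with Bonferroni or Games-Howell post-hocs, a repeated-measures
three-way (split-plot) ANOVA for weekly caloric intake, and the
nonparametric Kruskal-Wallis + Dunn-Bonferroni screen with
Benjamini-Hochberg FDR used for imaging-MS signals.

Conventions, fixed once for the whole package: Levene uses the mean as
the group center; unbalanced factorial ANOVA uses Type II sums of
squares; the FDR method is Benjamini-Hochberg; the within factor of the
split-plot ANOVA is Greenhouse-Geisser corrected; the post-hoc selector
runs Games-Howell when Levene rejects at 0.05 and Bonferroni-adjusted
pairwise Welch tests otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "levene_test",
    "two_way_anova",
    "games_howell",
    "pairwise_welch_bonferroni",
    "select_posthoc",
    "bonferroni_adjust",
    "bh_fdr",
    "rm_three_way_anova",
    "kruskal_wallis",
    "dunn_bonferroni",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    comparison: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    adjusted_p: float = math.nan
    adjustment: str = "none"
    flag: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in out):
        raise ValueError("every group needs at least 2 values")
    return out


def levene_test(groups) -> TestResult:
    """Levene's equality-of-variance test with the mean as group center."""
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0.0:
        return TestResult("levene", 0.0, (float(len(gs) - 1), float(pooled.size - len(gs))),
                          1.0, flag="degenerate: all values equal")
    stat, p = stats.levene(*gs, center="mean")
    df = (float(len(gs) - 1), float(pooled.size - len(gs)))
    flag = ""
    if math.isnan(stat):  # all groups internally constant
        stat, p, flag = 0.0, 1.0, "degenerate: zero within-group variance"
    return TestResult("levene", float(stat), df, float(p), flag=flag)


def two_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    factor_a: str = "sex",
    factor_b: str = "intervention",
) -> pd.DataFrame:
    """Two-way factorial ANOVA (Type II SS) with interaction.

    Returns one row per effect (factor_a, factor_b, interaction) with
    F, dfs and p.  Requires every factor-level combination to be
    populated when the interaction is estimated.
    """
    d = data[[response, factor_a, factor_b]].dropna().copy()
    cells = d.groupby([factor_a, factor_b], observed=True).size()
    full = list(itertools.product(d[factor_a].unique(), d[factor_b].unique()))
    missing = [c for c in full if c not in cells.index]
    if missing:
        raise ValueError(f"empty design cell(s) for interaction: {missing}")

    if float(np.ptp(d[response].to_numpy(dtype=float))) == 0.0:
        # constant response: all effect sums of squares vanish
        rows = []
        for eff in (factor_a, factor_b, f"{factor_a}:{factor_b}"):
            rows.append({"effect": eff, "F": 0.0, "df_num": math.nan,
                         "df_den": math.nan, "p_value": 1.0})
        return pd.DataFrame(rows)

    model = ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=d).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    rows = []
    name_map = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    df_den = float(tab.loc["Residual", "df"])
    for raw, eff in name_map.items():
        rows.append({
            "effect": eff,
            "F": float(tab.loc[raw, "F"]),
            "df_num": float(tab.loc[raw, "df"]),
            "df_den": df_den,
            "p_value": float(tab.loc[raw, "PR(>F)"]),
        })
    return pd.DataFrame(rows)


def games_howell(data: pd.DataFrame, response: str = "value",
                 group: str = "group") -> pd.DataFrame:
    """Games-Howell pairwise comparisons for unequal variances.

    Per pair: Welch-type t statistic, Welch-Satterthwaite df, and the
    p-value from the studentized-range distribution with k groups using
    the q = t*sqrt(2) convention.
    """
    d = data[[response, group]].dropna()
    labels = list(pd.unique(d[group]))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = {g: d.loc[d[group] == g, response].to_numpy(dtype=float) for g in labels}
    if any(v.size < 2 for v in samples.values()):
        raise ValueError("every group needs at least 2 values")
    k = len(labels)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        x, y = samples[a], samples[b]
        na, nb = x.size, y.size
        va, vb = x.var(ddof=1), y.var(ddof=1)
        se2 = va / na + vb / nb
        diff = x.mean() - y.mean()
        flag = ""
        if se2 == 0.0:
            # zero-variance limiting case
            tstat = 0.0 if diff == 0.0 else math.inf * np.sign(diff)
            df = float(na + nb - 2)
            p = 1.0 if diff == 0.0 else 0.0
            flag = "degenerate: zero variance in both groups"
        else:
            tstat = diff / math.sqrt(se2)
            num = se2**2
            den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            df = num / den if den > 0 else float(na + nb - 2)
            if den == 0:
                flag = "degenerate: zero variance in one group"
            p = float(stats.studentized_range.sf(abs(tstat) * math.sqrt(2.0), k, df))
        rows.append({
            "group_a": a, "group_b": b, "mean_diff": float(diff),
            "t": float(tstat), "df": float(df), "p_value": float(min(p, 1.0)),
            "method": "games-howell", "flag": flag,
        })
    return pd.DataFrame(rows)


def pairwise_welch_bonferroni(data: pd.DataFrame, response: str = "value",
                              group: str = "group") -> pd.DataFrame:
    """Pairwise Welch t-tests with Bonferroni adjustment over all pairs."""
    d = data[[response, group]].dropna()
    labels = list(pd.unique(d[group]))
    samples = {g: d.loc[d[group] == g, response].to_numpy(dtype=float) for g in labels}
    rows = []
    for a, b in itertools.combinations(labels, 2):
        t, p = stats.ttest_ind(samples[a], samples[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b,
                     "mean_diff": float(samples[a].mean() - samples[b].mean()),
                     "t": float(t), "p_value": float(p), "method": "welch-bonferroni"})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bonferroni_adjust(out["p_value"].to_numpy())
    return out


def select_posthoc(data: pd.DataFrame, response: str = "value",
                   group: str = "group", alpha: float = ALPHA) -> pd.DataFrame:
    """Variance-gated post-hoc selection.

    Runs Levene on the groups; when it rejects at ``alpha`` the
    heteroscedastic Games-Howell procedure is used, otherwise pairwise
    Welch tests with Bonferroni adjustment.
    """
    d = data[[response, group]].dropna()
    gs = [d.loc[d[group] == g, response].to_numpy(dtype=float)
          for g in pd.unique(d[group])]
    lev = levene_test(gs)
    if lev.p_value < alpha:
        out = games_howell(d, response, group)
        out["adjusted_p"] = out["p_value"]  # studentized range is familywise already
    else:
        out = pairwise_welch_bonferroni(d, response, group)
    out.attrs["levene_p"] = lev.p_value
    return out


def bonferroni_adjust(p_values) -> np.ndarray:
    """min(1, m * p) for m simultaneous tests."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x conditions matrix."""
    k = wide.shape[1]
    if k < 2:
        return 1.0
    S = np.cov(wide, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(S.mean(axis=1) ** 2) + k**2 * grand**2)
    if den <= 0:
        return 1.0
    eps = num / den
    return float(min(1.0, max(eps, 1.0 / (k - 1))))


def rm_three_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    subject: str = "subject",
    within: str = "period",
    between_a: str = "sex",
    between_b: str = "intervention",
    gg_correct: bool = True,
) -> pd.DataFrame:
    """Split-plot ANOVA: two between-subject factors, one within factor.

    Between effects (A, B, A:B) are tested against the subject-within-
    groups mean square; within effects (W and its interactions) against
    the W x subject-within-groups mean square.  Subjects missing any
    within-factor level are dropped listwise with a warning.  The
    within-factor p-values are Greenhouse-Geisser corrected by default.
    """
    d = data[[response, subject, within, between_a, between_b]].dropna().copy()
    levels = list(pd.unique(d[within]))
    counts = d.groupby(subject, observed=True)[within].nunique()
    complete = counts[counts == len(levels)].index
    if len(complete) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(complete)} subject(s) with incomplete "
            f"{within} measurements (listwise deletion)", stacklevel=2,
        )
        d = d[d[subject].isin(complete)]
    if d.empty:
        raise ValueError("no complete subjects remain")

    f_a, f_b, f_w = f"C({between_a})", f"C({between_b})", f"C({within})"
    formula = (f"{response} ~ {f_a} * {f_b} * {f_w} + C({subject})")
    model = ols(formula, data=d).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)

    ss = tab["sum_sq"].to_dict()
    dfs = tab["df"].to_dict()
    # subject SS in the presence of the between effects = subjects within groups
    ss_subj, df_subj = ss[f"C({subject})"], dfs[f"C({subject})"]
    ss_err_w, df_err_w = ss["Residual"], dfs["Residual"]
    ms_subj = ss_subj / df_subj
    ms_err_w = ss_err_w / df_err_w if df_err_w > 0 else math.nan

    # GG epsilon from the pooled within-cell covariance of the wide matrix
    wide = d.pivot_table(index=subject, columns=within, values=response, observed=True)
    groups = d.groupby(subject, observed=True)[[between_a, between_b]].first()
    centered = []
    for _, idx in groups.groupby([between_a, between_b], observed=True).groups.items():
        block = wide.loc[idx].to_numpy(dtype=float)
        if block.shape[0] > 1:
            centered.append(block - block.mean(axis=0))
    eps = _gg_epsilon(np.vstack(centered)) if centered else 1.0

    def row(effect_key: str, effect_name: str, within_effect: bool):
        ss_e, df_e = ss[effect_key], dfs[effect_key]
        ms_e = ss_e / df_e
        if within_effect:
            F = ms_e / ms_err_w
            d1, d2 = df_e, df_err_w
            if gg_correct:
                d1, d2 = d1 * eps, d2 * eps
        else:
            F = ms_e / ms_subj
            d1, d2 = df_e, df_subj
        p = float(stats.f.sf(F, d1, d2)) if F >= 0 and d1 > 0 and d2 > 0 else math.nan
        return {"effect": effect_name, "F": float(F), "df_num": float(d1),
                "df_den": float(d2), "p_value": p,
                "gg_epsilon": eps if within_effect and gg_correct else math.nan}

    rows = [
        row(f_a, between_a, False),
        row(f_b, between_b, False),
        row(f"{f_a}:{f_b}", f"{between_a}:{between_b}", False),
        row(f_w, within, True),
        row(f"{f_a}:{f_w}", f"{between_a}:{within}", True),
        row(f"{f_b}:{f_w}", f"{between_b}:{within}", True),
        row(f"{f_a}:{f_b}:{f_w}", f"{between_a}:{between_b}:{within}", True),
    ]
    return pd.DataFrame(rows)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction."""
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0.0:
        return TestResult("kruskal-wallis", 0.0, float(len(gs) - 1), 1.0,
                          flag="degenerate: all values tied")
    stat, p = stats.kruskal(*gs)
    return TestResult("kruskal-wallis", float(stat), float(len(gs) - 1), float(p))


def dunn_bonferroni(groups, labels=None, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks, Bonferroni adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C_ties) (1/n_i + 1/n_j))
    with the tie correction C = sum(t^3 - t) / (12 (N - 1)).
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    pooled = np.concatenate(gs)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks, sizes, start = [], [], 0
    for g in gs:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    rows = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        denom = var_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if denom <= 0:
            z, p, flag = 0.0, 1.0, "degenerate: all values tied"
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(denom)
            p = 2.0 * float(stats.norm.sf(abs(z)))
            flag = ""
        rows.append({"group_a": labels[i], "group_b": labels[j], "z": float(z),
                     "p_value": min(p, 1.0), "flag": flag})
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["adjusted_p"] = bonferroni_adjust(out["p_value"].to_numpy())
    elif adjust == "none":
        out["adjusted_p"] = out["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["method"] = "dunn"
    return out
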