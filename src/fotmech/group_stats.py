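"""Group-comparison machinery for fitted parameters and BAL outcomes.

Implements the study's two statistical workflows:

* two-way fixed-effects ANOVA with interaction (dose x particle, or
  treatment x PEEP).  Balanced designs use the textbook cell-means sums of
  squares; unbalanced (n = 4-6) designs use Type II sums of squares via an
  OLS fit, appropriate when no interaction is emphasised a priori.
* pairwise follow-up: either Fisher's protected LSD (pairwise t-tests on
  the pooled residual mean square, gated on a significant omnibus F) or
  step-down Holm-Sidak adjustment 1 - (1 - p)^k with enforced monotonicity.

``compare_parameters`` applies the treatment x PEEP ANOVA and Holm-Sidak
pairwise treatment comparisons, per parameter, the way the reported
physiology summaries (E0, a/c, beta, dE, b) are compared at a fixed PEEP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "two_way_anova",
    "protected_ttests",
    "holm_sidak",
    "compare_parameters",
]

DEFAULT_PARAMETERS: tuple[str, ...] = ("e0", "a_over_c", "beta", "de", "b")


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA decomposition.

    ``table`` has index [factor_a, factor_b, interaction, Residual] and
    columns sum_sq, df, mean_sq, F, p.  ``no_variance`` flags the
    degenerate all-observations-equal case, where F ratios are undefined
    and reported as NaN.
    """

    table: pd.DataFrame
    factor_a: str
    factor_b: str
    no_variance: bool = False

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residual", "df"])

    @property
    def ss_total(self) -> float:
        return float(self.table["sum_sq"].sum())


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise comparison with its raw and adjusted p-value."""

    label: str
    p_raw: float
    p_adjusted: float
    significant: bool

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-12 or self.p_adjusted > 1.0 + 1e-12:
            raise ValueError("adjusted p must satisfy p_raw <= p_adj <= 1")


def _check_cells(table: pd.DataFrame, outcome: str, fa: str, fb: str) -> pd.DataFrame:
    counts = table.groupby([fa, fb], observed=True)[outcome].count()
    levels_a = table[fa].unique()
    levels_b = table[fb].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError(f"both factors need >= 2 levels ({fa}: {len(levels_a)}, {fb}: {len(levels_b)})")
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index or counts.loc[(la, lb)] == 0:
                raise ValueError(f"empty design cell: {fa}={la}, {fb}={lb}")
    n_cells = len(levels_a) * len(levels_b)
    if len(table) < n_cells + 2:
        raise ValueError("need at least 2 replicates beyond the cell count for a residual estimate")
    return counts


def _balanced_anova(table: pd.DataFrame, outcome: str, fa: str, fb: str) -> pd.DataFrame:
    y = table[outcome].to_numpy(dtype=float)
    grand = y.mean()
    mean_a = table.groupby(fa, observed=True)[outcome].mean()
    mean_b = table.groupby(fb, observed=True)[outcome].mean()
    mean_ab = table.groupby([fa, fb], observed=True)[outcome].mean()
    n_cell = len(table) // (len(mean_a) * len(mean_b))

    ss_a = n_cell * len(mean_b) * float(((mean_a - grand) ** 2).sum())
    ss_b = n_cell * len(mean_a) * float(((mean_b - grand) ** 2).sum())
    dev_ab = mean_ab - grand
    for (la, lb), _ in mean_ab.items():
        dev_ab.loc[(la, lb)] -= (mean_a.loc[la] - grand) + (mean_b.loc[lb] - grand)
    ss_ab = n_cell * float((dev_ab**2).sum())
    cell_of = table.set_index([fa, fb]).index
    fitted = mean_ab.loc[cell_of].to_numpy(dtype=float)
    ss_res = float(((y - fitted) ** 2).sum())

    df_a = len(mean_a) - 1
    df_b = len(mean_b) - 1
    df_ab = df_a * df_b
    df_res = len(table) - len(mean_a) * len(mean_b)
    return pd.DataFrame(
        {"sum_sq": [ss_a, ss_b, ss_ab, ss_res], "df": [df_a, df_b, df_ab, df_res]},
        index=[fa, fb, f"{fa}:{fb}", "Residual"],
    )


def _type2_anova(table: pd.DataFrame, outcome: str, fa: str, fb: str) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table[[outcome, fa, fb]].copy()
    data.columns = ["y", "A", "B"]
    model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame(
        {"sum_sq": aov["sum_sq"].to_numpy(), "df": aov["df"].to_numpy().astype(int)},
        index=[fa, fb, f"{fa}:{fb}", "Residual"],
    )
    return out


def two_way_anova(table: pd.DataFrame, outcome: str, factor_a: str, factor_b: str) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Balanced designs use closed-form cell-means sums of squares (which
    exactly conserve SS_total); unbalanced designs use Type II SS.
    """
    table = table.dropna(subset=[outcome]).copy()
    counts = _check_cells(table, outcome, factor_a, factor_b)
    y = table[outcome].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())

    balanced = counts.nunique() == 1
    ss = _balanced_anova(table, outcome, factor_a, factor_b) if balanced else _type2_anova(
        table, outcome, factor_a, factor_b
    )

    ss["mean_sq"] = ss["sum_sq"] / ss["df"].replace(0, np.nan)
    ms_res = ss.loc["Residual", "mean_sq"]
    no_variance = ss_total <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2)
    if no_variance or ms_res == 0 or not np.isfinite(ms_res):
        ss["F"] = np.nan
        ss["p"] = np.nan
    else:
        ss["F"] = ss["mean_sq"] / ms_res
        ss["p"] = stats.f.sf(ss["F"], ss["df"], ss.loc["Residual", "df"])
    ss.loc["Residual", ["F", "p"]] = np.nan
    return AnovaResult(table=ss, factor_a=factor_a, factor_b=factor_b, no_variance=bool(no_variance))


def protected_ttests(
    table: pd.DataFrame,
    omnibus: AnovaResult,
    outcome: str,
    factor: str,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Fisher's protected LSD over the levels of ``factor``.

    Pairwise two-sample t-tests use the omnibus ANOVA's pooled residual
    mean square and residual df; they count as significant only when the
    omnibus F for ``factor`` is itself significant at ``alpha`` (raw
    p-values are recorded either way, with no multiplicity adjustment —
    protection is the gate).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if factor not in (omnibus.factor_a, omnibus.factor_b):
        raise ValueError(f"factor {factor!r} was not part of the omnibus ANOVA")
    gate_p = omnibus.p_value(factor)
    gate_open = np.isfinite(gate_p) and gate_p < alpha

    mse = omnibus.residual_ms
    df = omnibus.residual_df
    means = table.groupby(factor, observed=True)[outcome].agg(["mean", "count"])
    out: list[PairwiseResult] = []
    for la, lb in itertools.combinations(means.index, 2):
        na, nb = means.loc[la, "count"], means.loc[lb, "count"]
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        if se == 0 or not np.isfinite(se):
            p = 1.0
        else:
            t = (means.loc[la, "mean"] - means.loc[lb, "mean"]) / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        out.append(
            PairwiseResult(
                label=f"{la} vs {lb}",
                p_raw=p,
                p_adjusted=p,
                significant=bool(gate_open and p < alpha),
            )
        )
    return out


def holm_sidak(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Sidak adjustment.

    Sorted ascending, p_(i) is adjusted to 1 - (1 - p_(i))^(m - i + 1),
    made monotone nondecreasing down the list and clamped at 1; decisions
    follow the step-down comparison against ``alpha``.  Returns
    (adjusted p, reject) in the original input order.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted < alpha
    return adjusted, reject


def compare_parameters(
    fit_table: pd.DataFrame,
    alpha: float = 0.05,
    peep: float = 3.0,
    parameters = DEFAULT_PARAMETERS,
    treatment_col: str = "treatment",
    peep_col: str = "peep",
) -> dict[str, dict]:
    """Per-parameter treatment x PEEP ANOVA with Holm-Sidak treatment pairs.

    For each parameter: a two-way ANOVA across treatment and PEEP, then all
    pairwise treatment comparisons at the fixed ``peep`` (default 3 cmH2O,
    where the spectra are customarily compared), Holm-Sidak adjusted within
    the parameter family.  The pairwise t statistics pool the within-cell
    variance at that PEEP (df = t(n-1)): per-animal parameters are shared
    across PEEP levels, so the full-model residual df would overstate the
    information in the variance estimate.
    """
    if peep not in set(fit_table[peep_col]):
        raise ValueError(f"no rows at PEEP {peep}")
    report: dict[str, dict] = {}
    for param in parameters:
        anova = two_way_anova(fit_table, param, treatment_col, peep_col)
        at_peep = fit_table[fit_table[peep_col] == peep]
        stats_tp = at_peep.groupby(treatment_col, observed=True)[param].agg(["mean", "var", "count"])
        if (stats_tp["count"] < 2).any():
            raise ValueError("single-animal groups: insufficient residual degrees of freedom")
        # pooled within-cell variance at this PEEP
        df_pool = int((stats_tp["count"] - 1).sum())
        mse = float((stats_tp["var"] * (stats_tp["count"] - 1)).sum() / df_pool)
        labels, raw = [], []
        for la, lb in itertools.combinations(stats_tp.index, 2):
            na, nb = stats_tp.loc[la, "count"], stats_tp.loc[lb, "count"]
            se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
            if se == 0 or not np.isfinite(se):
                p = 1.0
            else:
                t = (stats_tp.loc[la, "mean"] - stats_tp.loc[lb, "mean"]) / se
                p = float(2.0 * stats.t.sf(abs(t), df_pool))
            labels.append(f"{la} vs {lb}")
            raw.append(p)
        adjusted, reject = holm_sidak(raw, alpha)
        pairwise = [
            PairwiseResult(label=l, p_raw=pr, p_adjusted=float(pa), significant=bool(rj))
            for l, pr, pa, rj in zip(labels, raw, adjusted, reject)
        ]
        report[param] = {"anova": anova, "pairwise": pairwise}
    return report
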