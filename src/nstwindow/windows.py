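"""Protection-window inference from residue concentration series.

The idea: a seed treatment protects while treated tissue carries more active
ingredient than untreated tissue.  Two estimators of the day protection ends:

1. *Decay flattening* — fit the dissipation curve and report the day its rate
   has decayed to a small fraction of the initial rate (see
   :mod:`nstwindow.decay`).
2. *Contrast convergence* — at every sampling date, fit a randomized complete
   block (treatment + block) model to log concentrations of plot means and
   test the planned contrasts "untreated (naked + fungicide) vs low" and
   "untreated vs high"; protection ends at the first date from which the
   contrast stays non-significant for the rest of the season.

Per-year end days are reconciled across years by their arithmetic mean.
Trial summaries (yield / stand / ratings) use the same RCB model with Tukey
HSD compact-letter displays.

All ANOVA quantities use the exact balanced closed-form sums-of-squares
decomposition (one observation per treatment x block cell), which for these
designs is identical to the OLS fit and orders of magnitude faster for the
Monte-Carlo checks.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "ProtectionWindow",
    "rcb_anova",
    "planned_contrast",
    "convergence_date",
    "reconcile_years",
    "tukey_hsd",
    "contrast_table",
    "CONTRAST_SETS",
]

#: The two planned contrast weight sets: untreated controls vs each
#: insecticide rate.  Weights sum to zero.
CONTRAST_SETS: dict[str, dict[str, float]] = {
    "untreated_vs_low": {"naked": 0.5, "fungicide": 0.5, "low": -1.0, "high": 0.0},
    "untreated_vs_high": {"naked": 0.5, "fungicide": 0.5, "low": 0.0, "high": -1.0},
}


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects (treatment + block) decomposition, balanced."""

    f_treatment: float
    f_block: float
    df_treatment: int
    df_block: int
    df_error: int
    p_treatment: float
    p_block: float
    ss_treatment: float
    ss_block: float
    ss_error: float
    ss_total: float
    mse: float


@dataclass(frozen=True)
class ContrastResult:
    """A planned contrast at one sampling date."""

    dpp: int
    label: str
    estimate: float
    F: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class ProtectionWindow:
    """Interval [0, end_dpp] of expected pest protection for one tissue."""

    region: str
    treatment: str
    end_dpp: float
    method: str  # "decay_flattening" | "contrast_convergence"
    per_year: dict | None = None


def _cell_table(df: pd.DataFrame, value: str, treatment: str, block: str):
    """Pivot to a treatments x blocks cell matrix, enforcing balance."""
    counts = df.groupby([treatment, block], observed=True)[value].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError(
            "unbalanced design: need exactly one observation (plot mean) per "
            "treatment x block cell"
        )
    return df.pivot(index=treatment, columns=block, values=value)


def rcb_anova(
    df: pd.DataFrame,
    value: str = "value",
    treatment: str = "treatment",
    block: str = "block",
) -> AnovaResult:
    """Randomized-complete-block ANOVA with treatment and block fixed.

    Requires the balanced one-observation-per-cell layout (plot means), for
    which SS_total = SS_treatment + SS_block + SS_error exactly.
    """
    cells = _cell_table(df, value, treatment, block)
    y = cells.to_numpy(dtype=float)
    t, b = y.shape
    if t < 2 or b < 2:
        raise ValueError("need >= 2 treatments and >= 2 blocks")
    grand = y.mean()
    ss_treat = b * float(((y.mean(axis=1) - grand) ** 2).sum())
    ss_block = t * float(((y.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_treat - ss_block
    df_t, df_b = t - 1, b - 1
    df_e = df_t * df_b
    mse = ss_err / df_e
    if mse > 0:
        f_t = (ss_treat / df_t) / mse
        f_b = (ss_block / df_b) / mse
        p_t = float(stats.f.sf(f_t, df_t, df_e))
        p_b = float(stats.f.sf(f_b, df_b, df_e))
    else:
        f_t = np.inf if ss_treat > 0 else 0.0
        f_b = np.inf if ss_block > 0 else 0.0
        p_t = 0.0 if ss_treat > 0 else 1.0
        p_b = 0.0 if ss_block > 0 else 1.0
    return AnovaResult(
        f_treatment=float(f_t), f_block=float(f_b),
        df_treatment=df_t, df_block=df_b, df_error=df_e,
        p_treatment=p_t, p_block=p_b,
        ss_treatment=ss_treat, ss_block=ss_block,
        ss_error=max(ss_err, 0.0), ss_total=ss_total, mse=mse,
    )


def planned_contrast(
    df: pd.DataFrame,
    weights: dict[str, float],
    value: str = "value",
    group: str = "treatment",
    block: str | None = "block",
    dpp: int = 0,
    label: str = "",
) -> ContrastResult:
    """F test of a planned contrast among group means at one date.

    The error term is the residual mean square of the treatment + block model
    when ``block`` is given (the per-date RCB model on plot means, error df
    (T-1)(B-1)), else the pooled within-group mean square (one-way layout).
    F = L^2 / (MSE * sum(w_i^2 / n_i)) on (1, df_error); an exactly-zero MSE
    is flagged by F = inf, p = 0.
    """
    w = {g: float(v) for g, v in weights.items()}
    if abs(sum(w.values())) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    present = set(df[group].unique())
    missing = [g for g, v in w.items() if v != 0 and g not in present]
    if missing:
        raise ValueError(f"contrast names absent group(s) {missing}")

    means = df.groupby(group, observed=True)[value].mean()
    ns = df.groupby(group, observed=True)[value].count()

    if block is not None:
        res = rcb_anova(df, value=value, treatment=group, block=block)
        mse, df_e = res.mse, res.df_error
    else:
        # Pooled within-group variance.
        resid = df[value] - df[group].map(means)
        df_e = len(df) - means.size
        if df_e <= 0:
            raise ValueError("no error degrees of freedom for the contrast")
        mse = float((resid ** 2).sum()) / df_e

    estimate = float(sum(v * means[g] for g, v in w.items() if v != 0.0))
    scale = float(sum(v * v / ns[g] for g, v in w.items() if v != 0.0))
    if mse <= 0.0:
        f_stat = np.inf if estimate != 0 else 0.0
        p = 0.0 if estimate != 0 else 1.0
    else:
        f_stat = estimate ** 2 / (mse * scale)
        p = float(stats.f.sf(f_stat, 1, df_e))
    return ContrastResult(dpp=int(dpp), label=label, estimate=estimate,
                          F=float(f_stat), df1=1, df2=int(df_e), p=p)


def convergence_date(contrasts, alpha: float = 0.05) -> int | None:
    """First sampled day from which the contrast stays non-significant.

    Returns the smallest sampled dpp d with p(d) > alpha and p(d') > alpha
    for every later sampled d'; ``None`` if the series never settles above
    alpha ("no convergence observed within the sampling horizon").
    """
    series = sorted(contrasts, key=lambda c: c.dpp)
    if not series:
        raise ValueError("need at least one contrast result")
    result = None
    for c in series:
        if c.p > alpha:
            if result is None:
                result = c.dpp
        else:
            result = None
    return result


def reconcile_years(end_days) -> float:
    """Cross-year reconciliation: arithmetic mean of per-year end days."""
    days = list(end_days)
    if not days:
        raise ValueError("need at least one per-year end day")
    return float(np.mean(days))


def _compact_letters(names, separated) -> dict[str, str]:
    """Compact letter display for an all-pairs comparison with a single
    threshold.  ``names`` must be ordered by ascending mean; ``separated``
    is a predicate on index pairs (i < j) that is interval-monotone (true of
    a pair implies true of any wider pair), which holds for Tukey HSD on
    balanced groups."""
    g = len(names)
    intervals = []
    for i in range(g):
        j = i
        while j + 1 < g and not separated(i, j + 1):
            j += 1
        intervals.append((i, j))
    # Drop intervals nested inside another.
    maximal = [
        iv for iv in intervals
        if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)
    ]
    maximal = sorted(set(maximal))
    letters: dict[str, list[str]] = {n: [] for n in names}
    for letter, (lo, hi) in zip(string.ascii_lowercase, maximal):
        for idx in range(lo, hi + 1):
            letters[names[idx]].append(letter)
    return {n: "".join(v) for n, v in letters.items()}


def tukey_hsd(
    means: dict[str, float],
    mse: float,
    df_error: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey honest-significant-difference letters for balanced groups.

    Pairs whose mean difference exceeds HSD = q_{1-alpha}(k, df) *
    sqrt(MSE / n) are declared different; groups sharing a letter are
    statistically indistinguishable.
    """
    if df_error <= 0:
        raise ValueError("df_error must be > 0")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be > 0")
    names = sorted(means, key=means.get)
    vals = np.array([means[n] for n in names])
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 groups")
    q_crit = stats.studentized_range.ppf(1.0 - alpha, k, df_error)
    hsd = q_crit * np.sqrt(mse / n_per_group)
    letters = _compact_letters(
        names, lambda i, j: abs(vals[j] - vals[i]) > hsd
    )
    return pd.DataFrame(
        {
            "group": names,
            "mean": vals,
            "letters": [letters[n] for n in names],
            "hsd": hsd,
        }
    )


def contrast_table(
    residues: pd.DataFrame,
    alpha: float = 0.05,
    contrast_sets: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-date planned contrasts on natural-log plot-mean concentrations.

    For every (year, region, dpp): average plant-level concentrations to plot
    means, take natural logs, fit the treatment + block RCB model, and test
    each contrast set.  Returns one row per (year, region, dpp, contrast).
    LOD substitution must have been applied first — zeros cannot be logged.
    """
    sets = contrast_sets or CONTRAST_SETS
    if (residues["conc"] <= 0).any():
        raise ValueError(
            "non-positive concentrations; apply an LOD policy before the "
            "log-scale contrasts"
        )
    plot_means = (
        residues.groupby(["year", "region", "dpp", "treatment", "block"],
                         observed=True)["conc"]
        .mean()
        .reset_index()
    )
    plot_means["log_conc"] = np.log(plot_means["conc"])
    rows = []
    for (year, region, dpp), sub in plot_means.groupby(
        ["year", "region", "dpp"], observed=True
    ):
        for label, weights in sets.items():
            c = planned_contrast(
                sub, weights, value="log_conc", group="treatment",
                block="block", dpp=dpp, label=label,
            )
            rows.append({
                "year": year, "region": region, "dpp": int(dpp),
                "contrast": label, "estimate": c.estimate, "F": c.F,
                "df1": c.df1, "df2": c.df2, "p": c.p,
                "significant": c.p <= alpha,
            })
    return pd.DataFrame(rows).sort_values(
        ["year", "region", "contrast", "dpp"]
    ).reset_index(drop=True)
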