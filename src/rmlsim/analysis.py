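"""Turn trial records into condition-binned regressors and statistics.

The simulated dACC signal is composed per task from the model's latent
signals (net value expectation, boost, surprise), binned by the task's
condition variable, and compared across candidate polynomial shapes with
AIC / Akaike weights; linear trends across participants are tested with
one-sample t-tests on per-participant regression slopes, and WM accuracy
with a repeated-measures ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bin_speeded",
    "bin_wm",
    "bin_foraging",
    "compose_dacc_signal",
    "fit_polynomial_aic",
    "akaike_weights",
    "linear_trend_ttest",
    "participant_slopes",
    "anova_load",
]

_SPEEDED_SIGNALS = {
    "boost": "boost",
    "value": "value_regressor",
    "surprise": "surprise_regressor",
    "accuracy": "correct",
    "rt": "rt_cycles",
}


def bin_speeded(
    records: pd.DataFrame, per_participant: bool = False
) -> pd.DataFrame:
    """Mean signals per value-difference bin (-5..+5).

    Trials are averaged within participant first, then across participants,
    matching how condition-mean activity profiles are built.  An unoccupied
    bin raises (the balanced design guarantees occupancy).
    """
    expected = np.arange(-5, 6)
    per = (
        records.groupby(["participant", "value_difference"])[
            list(_SPEEDED_SIGNALS.values())
        ]
        .mean()
        .rename(columns={v: k for k, v in _SPEEDED_SIGNALS.items()})
        .reset_index()
    )
    counts = records.groupby("value_difference").size()
    missing = sorted(set(expected) - set(counts.index))
    if missing:
        raise ValueError(f"empty value-difference bin(s): {missing}")
    if per_participant:
        return per
    out = per.groupby("value_difference").mean().drop(columns="participant")
    out["n_trials"] = counts
    return out


def bin_wm(records: pd.DataFrame, per_participant: bool = False) -> pd.DataFrame:
    """Mean signals per WM load (within participant, then across)."""
    cols = {
        "boost": "boost",
        "value": "value_regressor",
        "surprise": "surprise_regressor",
        "accuracy": "correct",
    }
    per = (
        records.groupby(["participant", "load"])[list(cols.values())]
        .mean()
        .rename(columns={v: k for k, v in cols.items()})
        .reset_index()
    )
    if per_participant:
        return per
    out = per.groupby("load").mean().drop(columns="participant")
    out["n_trials"] = records.groupby("load").size()
    return out


def bin_foraging(
    records: pd.DataFrame,
    by: str = "forage_value",
    n_bins: int = 8,
    per_participant: bool = False,
) -> pd.DataFrame:
    """Mean boost (and boost+value composite) over quantile bins of the
    foraging value or the choice difficulty.

    Bin edges are pooled quantiles of the binning variable, so every
    participant shares the same bins; the bin center reported is the mean of
    the variable within the bin.
    """
    if by not in ("forage_value", "choice_difficulty"):
        raise ValueError(f"unknown foraging binning variable: {by!r}")
    x = records[by].to_numpy()
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if edges.size - 1 < 3:
        raise ValueError("too few distinct bins for a polynomial comparison")
    binned = records.copy()
    binned["bin"] = pd.cut(binned[by], bins=edges, include_lowest=True)
    binned["composite"] = binned["boost"] + binned["value_regressor"]
    grouped = binned.groupby(["participant", "bin"], observed=True)
    per = grouped[["boost", "composite", by]].mean().reset_index()
    per = per.rename(columns={by: "bin_center"})
    if per_participant:
        return per
    out = per.groupby("bin", observed=True)[["boost", "composite", "bin_center"]].mean()
    out["n_trials"] = binned.groupby("bin", observed=True).size()
    if (out["n_trials"] == 0).any():
        raise ValueError("empty foraging bin")
    return out.reset_index(drop=True)


def compose_dacc_signal(table: pd.DataFrame, task_id: str) -> pd.Series:
    """Simulated dACC activity per bin, with a task-specific recipe.

    speeded: net value expectation + boost; wm: boost alone; foraging:
    boost alone (use the binned 'composite' column for the whole-MPFC
    boost+value variant).
    """
    if task_id == "speeded":
        return table["value"] + table["boost"]
    if task_id == "wm":
        return table["boost"].copy()
    if task_id == "foraging":
        return table["boost"].copy()
    raise ValueError(f"unknown task id: {task_id!r}")


def _aic(n: int, rss: float, k: int, corrected: bool) -> float:
    aic = n * np.log(rss / n) + 2 * k
    if corrected and n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def akaike_weights(aics) -> np.ndarray:
    """Relative model evidence w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    aics = np.asarray(list(aics), dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def fit_polynomial_aic(
    x,
    y,
    degrees=(1, 2, 4),
    corrected: bool = False,
) -> pd.DataFrame:
    """Least-squares polynomial fits compared by AIC and Akaike weights.

    AIC = n ln(RSS/n) + 2k with k counting the polynomial coefficients plus
    the noise variance (k = degree + 2).  Returns one row per degree with
    the RSS, AIC, Akaike weight (normalized over the degrees supplied) and
    the fitted leading and quadratic coefficients.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    degrees = tuple(int(d) for d in degrees)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < max(degrees) + 2:
        raise ValueError("need at least max(degree) + 2 points")
    if np.unique(x).size <= max(degrees):
        raise ValueError("design is rank-deficient for the requested degree")
    rows = []
    for deg in degrees:
        coeffs = np.polyfit(x, y, deg)
        resid = y - np.polyval(coeffs, x)
        rss = float(resid @ resid)
        k = deg + 2
        quad = 0.0
        if deg >= 2:
            quad = float(coeffs[deg - 2])
        rows.append(
            {
                "degree": deg,
                "rss": max(rss, 1e-300),
                "aic": _aic(x.size, max(rss, 1e-300), k, corrected),
                "leading_coeff": float(coeffs[0]),
                "quadratic_coeff": quad,
            }
        )
    out = pd.DataFrame(rows).set_index("degree")
    out["akaike_weight"] = akaike_weights(out["aic"])
    return out


def participant_slopes(
    per_participant: pd.DataFrame, x: str, y: str
) -> pd.Series:
    """Per-participant linear-regression slope of y on x (condition means)."""
    def slope(g: pd.DataFrame) -> float:
        if g[x].nunique() < 2:
            raise ValueError("need >= 2 condition levels per participant")
        return float(np.polyfit(g[x].to_numpy(float), g[y].to_numpy(float), 1)[0])

    return per_participant.groupby("participant").apply(slope, include_groups=False)


def linear_trend_ttest(slopes) -> dict:
    """One-sample t-test of per-participant slopes against zero."""
    slopes = np.asarray(list(slopes), dtype=float)
    if slopes.size < 2:
        raise ValueError("need at least two participants")
    res = stats.ttest_1samp(slopes, 0.0)
    return {
        "t": float(res.statistic),
        "df": int(slopes.size - 1),
        "p": float(res.pvalue),
        "mean_slope": float(slopes.mean()),
    }


def anova_load(accuracy: pd.DataFrame) -> dict:
    """Repeated-measures one-way ANOVA for the load main effect on accuracy.

    ``accuracy`` is a complete participants x loads table.  The standard
    within-subject decomposition gives df = (L-1, (L-1)(N-1)); these are
    reported as computed, never forced to match any externally printed df
    structure.
    """
    if accuracy.isna().any().any():
        raise ValueError("accuracy table has missing cells")
    a = accuracy.to_numpy(dtype=float)
    n, L = a.shape
    if n < 2 or L < 2:
        raise ValueError("need >= 2 participants and >= 2 load levels")
    grand = a.mean()
    ss_cond = n * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subj = L * ((a.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((a - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = L - 1, (L - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return {"F": float(f), "df1": df1, "df2": df2, "p": p}
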