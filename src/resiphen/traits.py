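"""Per-animal production and resilience traits from QC-passed records.

Production traits: ADG (kg/d, from the first and last in-window weights),
AFI (g/d) and FCR (g feed per g gain, AFI/ADG). Resilience traits quantify
within-individual deviations of a longitudinal series from its expectation;
smaller deviations are read as higher general resilience:

* ``lnvar_weight``, ``skew_weight``, ``lag1_weight`` — log-variance,
  skewness and lag-one autocorrelation of the residuals about the animal's
  own Gompertz curve;
* ``lnMSE_weight`` / ``lnMSE_FI`` / ``lnMSE_dur`` / ``lnMSE_n_visit`` —
  log mean-squared error about a per-animal linear regression on age
  (MSE = RSS/n, the ML residual variance, so the trait is comparable to
  lnvar);
* ``lnvar_weight_standardized`` — log-variance of the animal's weights
  after per-day standardization against the population (mean 0, SD 1 per
  day of age), removing the age trend without any within-animal modelling;
* ``straightness`` and ``mean_speed`` — trajectory statistics in the
  (age, weight) plane: Euclidean start-end distance over path length, and
  path length over age span;
* ``QR_FI`` / ``QR_dur`` — number of off-feed days, i.e. days on which the
  value falls strictly below the 5 % quantile-regression line of the trait
  on age fitted over all animal-days jointly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gompertz import fit_gompertz

__all__ = [
    "residual_lnvar",
    "residual_skew",
    "residual_lag1",
    "lnmse_linear",
    "standardized_lnvar",
    "trajectory_metrics",
    "quantile_offdays",
    "production_traits",
    "trait_outlier_filter",
    "derive_traits",
    "animal_metadata",
]

RESILIENCE_TRAITS = [
    "lnvar_weight", "lnMSE_weight", "lnvar_weight_standardized", "skew_weight",
    "lag1_weight", "straightness", "mean_speed", "lnMSE_FI", "lnMSE_dur",
    "lnMSE_n_visit", "QR_FI", "QR_dur",
]


def residual_lnvar(residuals) -> float:
    """Natural log of the sample variance (n-1) of curve residuals."""
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) < 2:
        raise ValueError("lnvar needs at least 2 residuals")
    v = np.var(r, ddof=1)
    return float(np.log(v)) if v > 0 else np.nan


def residual_skew(residuals) -> float:
    """Moment skewness g1 = m3 / m2^(3/2); zero-variance series -> missing."""
    r = np.asarray(residuals, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) < 3:
        raise ValueError("skewness needs at least 3 residuals")
    if np.var(r) == 0:
        return np.nan
    return float(stats.skew(r, bias=True))


def residual_lag1(residuals, ages, max_gap: int = 1) -> float:
    """Lag-one autocorrelation of residuals over consecutive recorded days.

    Divisor-n, mean-centred estimator; a pair only forms when the age step
    between successive records is at most ``max_gap`` days (gaps break the
    pairing). For evenly thinned series pass ``max_gap`` = the thinning step.
    """
    r = np.asarray(residuals, dtype=float)
    a = np.asarray(ages, dtype=float)
    keep = ~np.isnan(r)
    r, a = r[keep], a[keep]
    order = np.argsort(a)
    r, a = r[order], a[order]
    if len(r) < 3:
        raise ValueError("lag-1 autocorrelation needs at least 3 residuals")
    denom = np.sum((r - r.mean()) ** 2)
    if denom == 0:
        return np.nan
    x = r - r.mean()
    pair = np.diff(a) <= max_gap
    if not pair.any():
        return np.nan
    num = np.sum(x[:-1][pair] * x[1:][pair])
    return float(num / denom)


def lnmse_linear(ages, values) -> float:
    """ln(RSS/n) of an OLS regression of the series on age; exact fits -> missing."""
    a = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = ~np.isnan(y)
    a, y = a[keep], y[keep]
    if len(y) < 3:
        raise ValueError("linear MSE needs at least 3 points")
    coef = np.polyfit(a, y, 1)
    rss = float(np.sum((y - np.polyval(coef, a)) ** 2))
    if rss <= 1e-12 * max(1.0, float(np.sum(y**2))):  # numerically exact fit
        return np.nan
    return float(np.log(rss / len(y)))


def standardized_lnvar(records: pd.DataFrame, min_animals_per_day: int = 2) -> pd.Series:
    """Per-animal ln-variance of per-day population-standardized weights.

    Each day of age with at least ``min_animals_per_day`` weighed animals is
    standardized to mean 0, sample SD 1 across animals; other days are
    excluded from every animal's z-series. Animals pinned at the population
    mean (zero z-variance) come out missing.
    """
    df = records.dropna(subset=["weight_kg"])[["animal_id", "age_d", "weight_kg"]]
    stats_d = df.groupby("age_d")["weight_kg"].agg(["mean", "std", "count"])
    ok_days = stats_d.index[(stats_d["count"] >= min_animals_per_day) & (stats_d["std"] > 0)]
    df = df[df["age_d"].isin(ok_days)].copy()
    mu = stats_d.loc[df["age_d"], "mean"].to_numpy()
    sd = stats_d.loc[df["age_d"], "std"].to_numpy()
    df["z"] = (df["weight_kg"].to_numpy() - mu) / sd
    out = {}
    for aid, grp in df.groupby("animal_id"):
        if len(grp) < 2:
            out[aid] = np.nan
            continue
        v = grp["z"].var(ddof=1)
        out[aid] = np.log(v) if v > 0 else np.nan
    return pd.Series(out, name="lnvar_weight_standardized")


def trajectory_metrics(ages, weights) -> tuple[float, float]:
    """Straightness index and mean speed of the (age, weight) trajectory.

    straightness = start-end Euclidean distance / total path length (1 for a
    perfectly straight line); mean_speed = path length / age span (>= 1 for
    daily records, inflated by weight deviations).
    """
    a = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = ~np.isnan(w)
    a, w = a[keep], w[keep]
    order = np.argsort(a)
    a, w = a[order], w[order]
    if len(a) < 2:
        raise ValueError("trajectory needs at least 2 points")
    span = a[-1] - a[0]
    if span <= 0:
        raise ValueError("trajectory needs a positive age span")
    steps = np.hypot(np.diff(a), np.diff(w))
    path = float(steps.sum())
    euclid = float(np.hypot(span, w[-1] - w[0]))
    return euclid / path, path / span


def quantile_offdays(
    records: pd.DataFrame, value_col: str, tau: float = 0.05
) -> tuple[pd.Series, float]:
    """Off-feed day counts from pooled linear quantile regression on age.

    Fits the ``tau`` conditional quantile of ``value_col`` on age over all
    animal-days jointly (check-loss / pinball minimisation) and counts, per
    animal, the days with a value strictly below the fitted line. Returns the
    per-animal counts and the overall flagged fraction (which converges to
    ``tau`` as the pooled sample grows).
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    df = records.dropna(subset=[value_col])[["animal_id", "age_d", value_col]]
    X = sm.add_constant(df["age_d"].to_numpy(dtype=float))
    with warnings.catch_warnings():
        # IRLS can cycle between equivalent vertex solutions; the fitted line
        # is stable long before the iteration cap
        warnings.simplefilter("ignore")
        fit = sm.QuantReg(df[value_col].to_numpy(dtype=float), X).fit(q=tau, max_iter=2000)
    line = X @ fit.params
    below = df[value_col].to_numpy() < line
    counts = pd.Series(below, index=df["animal_id"]).groupby(level=0).sum().astype(int)
    return counts, float(below.mean())


def production_traits(ages, weights, feed) -> tuple[float, float, float]:
    """(ADG kg/d, AFI g/d, FCR g/g) for one animal.

    ADG uses the weights at the animal's minimum and maximum recorded ages;
    AFI is total intake over days with an intake record; FCR = AFI / ADG in
    g feed per g gain, missing when ADG <= 0.
    """
    a = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    f = np.asarray(feed, dtype=float)
    kw = ~np.isnan(w)
    if kw.sum() < 2:
        raise ValueError("ADG needs at least 2 weight records")
    aw, ww = a[kw], w[kw]
    i0, i1 = np.argmin(aw), np.argmax(aw)
    if aw[i1] == aw[i0]:
        raise ValueError("ADG needs a positive age span")
    adg = (ww[i1] - ww[i0]) / (aw[i1] - aw[i0])
    fk = f[~np.isnan(f)]
    afi = float(fk.sum() / len(fk)) if len(fk) else np.nan
    fcr = afi / (adg * 1000.0) if adg > 0 and np.isfinite(afi) else np.nan
    return float(adg), afi, fcr


def trait_outlier_filter(traits: pd.DataFrame, n_sd: float = 4.0, columns=None) -> tuple[pd.DataFrame, pd.Series]:
    """Set trait values more than ``n_sd`` sample SDs from the mean to missing.

    Single pass per trait across animals; returns the filtered table and the
    per-trait removal counts.
    """
    out = traits.copy()
    cols = columns if columns is not None else out.select_dtypes("number").columns
    removed = {}
    for col in cols:
        x = out[col]
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            removed[col] = 0
            continue
        bad = (x - mu).abs() > n_sd * sd
        removed[col] = int(bad.sum())
        out.loc[bad, col] = np.nan
    return out, pd.Series(removed, name="n_removed")


def animal_metadata(records: pd.DataFrame) -> pd.DataFrame:
    """One row per animal: housing, sex, dates and max recorded age (model covariate)."""
    keep = [c for c in ("sex", "farm", "pen", "compartment", "cg", "birth_date", "entry_date")
            if c in records.columns]
    meta = records.groupby("animal_id").agg({c: "first" for c in keep})
    meta["max_age"] = records.groupby("animal_id")["age_d"].max()
    meta["n_days"] = records.groupby("animal_id")["age_d"].nunique()
    return meta


def derive_traits(
    records: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
    tau: float = 0.05,
    outlier_filter: bool = True,
    lag_max_gap: int = 1,
    min_deviation_records: int = 4,
    window: tuple[int, int] = (95, 155),
) -> pd.DataFrame:
    """Full per-animal trait table (production + resilience traits).

    ``min_deviation_records`` is the minimum number of usable residuals for
    the deviation traits (post-QC data guarantees >= 20; reduced-density
    subsets from the design-robustness analysis pass smaller values).
    Animals whose Gompertz fit does not converge get missing curve-based
    traits. When ``outlier_filter`` is set, the 4-SD cross-animal filter is
    applied to every derived trait as the last step.
    """
    anchor_map = {}
    if anchors is not None and len(anchors):
        for aid, grp in anchors.groupby("animal_id"):
            anchor_map[aid] = (grp["age_d"].to_numpy(), grp["weight_kg"].to_numpy())

    rows = []
    for aid, grp in records.groupby("animal_id"):
        grp = grp.sort_values("age_d")
        ages = grp["age_d"].to_numpy(dtype=float)
        w = grp["weight_kg"].to_numpy(dtype=float)
        row = dict(animal_id=aid)
        kw = ~np.isnan(w)

        try:
            row["ADG"], row["AFI"], row["FCR"] = production_traits(
                ages, w, grp["fi_g_per_d"].to_numpy(dtype=float)
            )
        except ValueError:
            row["ADG"] = row["AFI"] = row["FCR"] = np.nan

        if kw.sum() >= 2 and ages[kw].max() > ages[kw].min():
            row["straightness"], row["mean_speed"] = trajectory_metrics(ages, w)

        a_ages, a_w = anchor_map.get(aid, (None, None))
        fit = None
        if kw.sum() >= max(4, min_deviation_records):
            try:
                fit = fit_gompertz(ages, w, a_ages, a_w, window=window)
            except ValueError:
                fit = None
        if fit is not None and fit.converged:
            row["A"], row["B"], row["k"] = fit.A, fit.B, fit.k
            row["gompertz_converged"] = True
            res, res_ages = fit.residuals, fit.residual_ages
            if len(res) >= max(2, min_deviation_records):
                row["lnvar_weight"] = residual_lnvar(res)
            if len(res) >= max(3, min_deviation_records):
                row["skew_weight"] = residual_skew(res)
                row["lag1_weight"] = residual_lag1(res, res_ages, max_gap=lag_max_gap)
        else:
            row["gompertz_converged"] = False

        if kw.sum() >= max(3, min_deviation_records):
            row["lnMSE_weight"] = lnmse_linear(ages, w)
        for col, name in (("fi_g_per_d", "lnMSE_FI"), ("dur_s_per_d", "lnMSE_dur"),
                          ("nvisits_per_d", "lnMSE_n_visit")):
            vals = grp[col].to_numpy(dtype=float)
            if (~np.isnan(vals)).sum() >= max(3, min_deviation_records):
                row[name] = lnmse_linear(ages, vals)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("animal_id")
    table["lnvar_weight_standardized"] = standardized_lnvar(records)

    qr_fi, _ = quantile_offdays(records, "fi_g_per_d", tau=tau)
    qr_dur, _ = quantile_offdays(records, "dur_s_per_d", tau=tau)
    table["QR_FI"] = qr_fi.reindex(table.index)
    table["QR_dur"] = qr_dur.reindex(table.index)
    table["tau"] = tau

    if outlier_filter:
        filter_cols = [c for c in ("ADG", "AFI", "FCR", "A", "B", "k", *RESILIENCE_TRAITS)
                       if c in table.columns]
        table, _ = trait_outlier_filter(table, columns=filter_cols)
    return table
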