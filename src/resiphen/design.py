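"""Robustness of traits to observation frequency and observation period.

Automated feeding stations are expensive; the practical question is how
much sparser or shorter recording can get before a resilience trait loses
its signal. Two reductions are studied:

* thinning — keep 1 record in every ``k`` (k = 4, 7, 14) per animal, by
  record index within the age-sorted series;
* period splitting — cut the 60-day window into early [95, 115), middle
  [115, 135) and late [135, 155] 20-day periods and recompute traits per
  period.

Agreement between the full-data trait and its reduced-data version is
summarised by the phenotypic correlation (Pearson, animals with both) and
the genetic correlation from a bivariate animal model treating the two
versions as separate traits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reml import fit_bivariate
from .traits import derive_traits

__all__ = [
    "thin_records",
    "split_periods",
    "reduced_traits",
    "robustness_correlations",
]

PERIOD_BOUNDS = (95, 115, 135, 155)
PERIOD_NAMES = ("early", "middle", "late")


def thin_records(records: pd.DataFrame, keep_every: int, offset: int = 0) -> pd.DataFrame:
    """Keep every ``keep_every``-th record per animal (by age-sorted index).

    ``offset`` selects which record of each block is retained; the default 0
    keeps the first (and hence the last complete block's first), preserving
    the trajectory endpoints of a gap-free series.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if not 0 <= offset < keep_every:
        raise ValueError("offset must lie in [0, keep_every)")
    if keep_every == 1:
        return records.copy()
    parts = []
    for _, grp in records.groupby("animal_id", sort=False):
        grp = grp.sort_values("age_d")
        parts.append(grp.iloc[offset::keep_every])
    return pd.concat(parts).reset_index(drop=True)


def split_periods(records: pd.DataFrame, bounds: tuple = PERIOD_BOUNDS) -> dict[str, pd.DataFrame]:
    """Partition records into early/middle/late 20-day windows.

    Boundaries are half-open on the left: an age-115 record is *middle*, an
    age-135 record is *late*; the final bound is inclusive so the windows
    cover the whole 95-155 d range.
    """
    lo, b1, b2, hi = bounds
    ages = records["age_d"]
    return {
        "early": records[(ages >= lo) & (ages < b1)].copy(),
        "middle": records[(ages >= b1) & (ages < b2)].copy(),
        "late": records[(ages >= b2) & (ages <= hi)].copy(),
    }


def reduced_traits(
    records: pd.DataFrame,
    keep_every: int | None = None,
    period: str | None = None,
    min_days: int = 7,
    tau: float = 0.05,
) -> pd.DataFrame:
    """Trait table from a thinned or period-restricted copy of the records.

    Eligibility is kept proportionate: animals with fewer than ``min_days``
    recorded days in the subset are dropped (7/20 days for a period mirrors
    the 20/60 full-window rule). For thinned data the lag-1 pairing gap is
    widened to the thinning step so consecutive retained records still pair.
    """
    sub = records
    lag_gap = 1
    if keep_every is not None:
        sub = thin_records(sub, keep_every)
        lag_gap = keep_every
    if period is not None:
        sub = split_periods(sub)[period]
    counts = sub.groupby("animal_id")["age_d"].nunique()
    keep = counts.index[counts >= min_days]
    sub = sub[sub["animal_id"].isin(keep)]
    window = (int(sub["age_d"].min()), int(sub["age_d"].max())) if len(sub) else (95, 155)
    return derive_traits(
        sub,
        tau=tau,
        lag_max_gap=lag_gap,
        min_deviation_records=min(4, min_days),
        window=window,
    )


def robustness_correlations(
    trait_full: pd.Series,
    trait_reduced: pd.Series,
    kinv=None,
    kinv_ids=None,
    model_data: pd.DataFrame | None = None,
    min_overlap: int = 50,
    **model_kw,
) -> dict:
    """Phenotypic (and optionally genetic) correlation between trait versions.

    ``trait_full``/``trait_reduced`` are animal-indexed. When a relationship
    inverse and model metadata are supplied, the genetic correlation is
    estimated with a bivariate animal model treating the two versions as
    distinct traits (residual covariance fixed at zero).
    """
    joined = pd.concat(
        [trait_full.rename("full"), trait_reduced.rename("reduced")], axis=1
    ).dropna()
    if len(joined) < min_overlap:
        raise ValueError(f"only {len(joined)} animals have both trait versions")
    r_p = float(joined["full"].corr(joined["reduced"]))
    out = dict(r_p=r_p, n=len(joined))
    if kinv is not None and model_data is not None:
        d1 = model_data.copy()
        d1["_full"] = trait_full.reindex(d1["animal"]).to_numpy()
        d2 = model_data.copy()
        d2["_reduced"] = trait_reduced.reindex(d2["animal"]).to_numpy()
        biv = fit_bivariate(d1, d2, "_full", "_reduced", kinv, kinv_ids, **model_kw)
        out["r_g"] = biv.r_g
        out["h2_full"] = biv.h2[0]
        out["h2_reduced"] = biv.h2[1]
    return out
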