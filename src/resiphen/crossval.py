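"""Masking-based cross-validation of breeding-value prediction.

Three masking designs probe different prediction scenarios:

* ``within_family`` — per sire, offspring are split into 5 folds, so a
  masked animal keeps phenotyped full/half sibs (close relationships);
* ``across_family`` — sires are split into 5 folds and a fold masks all
  their progeny, leaving only distant relatives as information;
* ``temporal`` — animals born after a cutoff date are masked (forward
  prediction).

Family schemes run ``replicates × folds`` (default 10 × 5 = 50) model
solves per trait and relationship matrix; each animal is masked exactly
once per replicate. Variance components are estimated once on the full
data and held fixed across folds; phenotypes are pre-adjusted to
``y* = y − Xb̂ − Wĉ`` from the same full-data fit. Predictive ability is
the Pearson correlation r(EBV_masked, y*) over masked animals, and
accuracy divides it by √h² of the full-data fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import VarianceComponents, fit_univariate, solve_blup

__all__ = [
    "MaskingScheme",
    "CVResult",
    "assign_folds",
    "adjust_phenotypes",
    "predict_masked",
    "predictive_ability",
    "run_crossval",
]


@dataclass
class MaskingScheme:
    kind: str  # within_family | across_family | temporal
    folds: int = 5
    replicates: int = 10
    cutoff: pd.Timestamp | str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("within_family", "across_family", "temporal"):
            raise ValueError(f"unknown masking scheme {self.kind!r}")
        if self.kind == "temporal" and self.cutoff is None:
            raise ValueError("temporal masking needs a cutoff date")


@dataclass
class CVResult:
    table: pd.DataFrame  # replicate, fold, n_masked, r, accuracy
    mean_r: float
    sd_r: float
    mean_accuracy: float
    sd_accuracy: float
    h2: float


def assign_folds(meta: pd.DataFrame, scheme: MaskingScheme) -> pd.DataFrame:
    """Fold assignments (replicate, fold, animal) for the maskable animals.

    ``meta`` needs columns ``animal`` and ``sire`` (family schemes) or
    ``birth_date`` (temporal). Offspring of sires with fewer offspring than
    folds are spread round-robin so each animal is still masked exactly once
    per replicate.
    """
    rows = []
    if scheme.kind == "temporal":
        if "birth_date" not in meta.columns or meta["birth_date"].isna().any():
            raise ValueError("temporal masking needs birth dates for every animal")
        cutoff = pd.Timestamp(scheme.cutoff)
        masked = meta.loc[pd.to_datetime(meta["birth_date"]) > cutoff, "animal"]
        for a in masked:
            rows.append(dict(replicate=0, fold=0, animal=a))
        return pd.DataFrame(rows, columns=["replicate", "fold", "animal"])

    if "sire" not in meta.columns:
        raise ValueError("family masking needs a sire column")
    fam = meta[meta["sire"].notna() & (meta["sire"] != 0)]
    rng = np.random.default_rng(scheme.seed)
    for rep in range(scheme.replicates):
        if scheme.kind == "within_family":
            for _, grp in fam.groupby("sire"):
                animals = grp["animal"].to_numpy().copy()
                rng.shuffle(animals)
                for i, a in enumerate(animals):
                    rows.append(dict(replicate=rep, fold=i % scheme.folds, animal=a))
        else:  # across_family
            sires = fam["sire"].unique()
            sires = sires.copy()
            rng.shuffle(sires)
            fold_of_sire = {s: i % scheme.folds for i, s in enumerate(sires)}
            for _, row in fam.iterrows():
                rows.append(
                    dict(replicate=rep, fold=fold_of_sire[row["sire"]], animal=row["animal"])
                )
    return pd.DataFrame(rows, columns=["replicate", "fold", "animal"])


def adjust_phenotypes(fit: VarianceComponents) -> pd.Series:
    """Adjusted phenotypes y* = y − Xb̂ − Wĉ = â + ê from a full-data fit."""
    return fit.adjusted_phenotypes()


def predict_masked(
    data: pd.DataFrame,
    response: str,
    masked_ids,
    kinv,
    kinv_ids,
    varcomp: VarianceComponents,
    animal_col: str = "animal",
    **model_kw,
) -> pd.Series:
    """EBVs of masked animals from a BLUP solve without their phenotypes."""
    masked_ids = list(masked_ids)
    if not masked_ids:
        raise ValueError("masked set is empty")
    train = data[~data[animal_col].isin(masked_ids)]
    ebv = solve_blup(train, response, kinv, kinv_ids, varcomp,
                     animal_col=animal_col, **model_kw)
    return ebv.loc[masked_ids]


def predictive_ability(ebv_masked: pd.Series, ystar: pd.Series, h2: float) -> tuple[float, float]:
    """Pearson r(EBV_masked, y*) and accuracy r/√h² over the masked animals."""
    joined = pd.concat([ebv_masked.rename("ebv"), ystar.rename("ystar")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("predictive ability needs at least 3 masked animals")
    if joined["ebv"].std() == 0 or joined["ystar"].std() == 0:
        return np.nan, np.nan
    r = float(joined["ebv"].corr(joined["ystar"]))
    return r, r / float(np.sqrt(h2))


def run_crossval(
    data: pd.DataFrame,
    response: str,
    meta: pd.DataFrame,
    scheme: MaskingScheme,
    kinv,
    kinv_ids,
    animal_col: str = "animal",
    full_fit: VarianceComponents | None = None,
    **model_kw,
) -> CVResult:
    """Full cross-validation for one trait and one relationship matrix.

    Fits the univariate model once on all data, adjusts phenotypes, then for
    every replicate × fold drops the masked phenotypes, re-solves the MME at
    the full-data variance components and scores r(EBV_masked, y*).
    """
    if full_fit is None:
        full_fit = fit_univariate(data, response, kinv, kinv_ids,
                                  animal_col=animal_col, **model_kw)
    ystar = adjust_phenotypes(full_fit)
    ystar = ystar.groupby(level=0).first()  # one record per animal

    folds = assign_folds(meta, scheme)
    rows = []
    for (rep, fold), grp in folds.groupby(["replicate", "fold"]):
        masked = [a for a in grp["animal"] if a in ystar.index]
        if len(masked) < 3:
            continue
        ebv_m = predict_masked(
            data, response, masked, kinv, kinv_ids, full_fit,
            animal_col=animal_col, **model_kw,
        )
        r, acc = predictive_ability(ebv_m, ystar.loc[masked], full_fit.h2)
        rows.append(dict(replicate=rep, fold=fold, n_masked=len(masked), r=r, accuracy=acc))
    table = pd.DataFrame(rows)
    return CVResult(
        table=table,
        mean_r=float(table["r"].mean()),
        sd_r=float(table["r"].std(ddof=1)) if len(table) > 1 else np.nan,
        mean_accuracy=float(table["accuracy"].mean()),
        sd_accuracy=float(table["accuracy"].std(ddof=1)) if len(table) > 1 else np.nan,
        h2=full_fit.h2,
    )
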