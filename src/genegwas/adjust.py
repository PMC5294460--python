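"""Fixed-effect adjustment of phenotypes.

Traits are regressed by ordinary least squares on an intercept,
dummy-coded categorical covariates (year, farm, gender), continuous
covariates (fattening days, entering weight) and the first structure
PCs; the residuals become the working phenotype for the association
stages. Rows with incomplete covariates are dropped (with a logged
count) and aliased design columns are reported by name rather than
silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import DegenerateInputError, logger
from .structure import StructurePCs

__all__ = ["AdjustedPhenotype", "AliasedDesignError", "adjust_phenotype", "build_design"]

CATEGORICAL_COVARIATES = ("year", "farm", "gender")
CONTINUOUS_COVARIATES = ("fattening_days", "entering_weight")


class AliasedDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""

    def __init__(self, aliased: Sequence[str]):
        self.aliased = list(aliased)
        super().__init__(
            "rank-deficient design; aliased columns: " + ", ".join(self.aliased)
        )


@dataclass
class AdjustedPhenotype:
    """Residual phenotypes after the fixed-effect fit."""

    individual_ids: np.ndarray
    residuals: pd.DataFrame  # one column per trait, aligned to individual_ids
    r_squared: dict[str, float] = field(default_factory=dict)
    design_columns: list[str] = field(default_factory=list)
    n_dropped_incomplete: int = 0

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def trait(self, name: str) -> np.ndarray:
        return self.residuals[name].to_numpy()


def build_design(
    covariates: pd.DataFrame,
    pcs: StructurePCs | np.ndarray | None = None,
    categorical: Sequence[str] = CATEGORICAL_COVARIATES,
    continuous: Sequence[str] = CONTINUOUS_COVARIATES,
) -> pd.DataFrame:
    """Intercept + dummy-coded categoricals + continuous covariates + PCs.

    Dummy coding uses the first level as reference; the choice does not
    affect the residuals. Covariates absent from the table are skipped.
    """
    n = len(covariates)
    parts: list[pd.DataFrame] = [pd.DataFrame({"Intercept": np.ones(n)}, index=covariates.index)]
    for name in categorical:
        if name in covariates:
            dummies = pd.get_dummies(
                covariates[name].astype("category"), prefix=name, drop_first=True
            ).astype(float)
            parts.append(dummies)
    for name in continuous:
        if name in covariates:
            col = covariates[[name]].astype(float)
            if col[name].nunique() <= 1:
                # a constant covariate is the intercept in disguise
                logger.info("build_design: dropping constant covariate %s", name)
                continue
            parts.append(col)
    if pcs is not None:
        scores = pcs.scores if isinstance(pcs, StructurePCs) else np.asarray(pcs)
        if scores.shape[0] != n:
            raise DegenerateInputError(
                f"PC scores have {scores.shape[0]} rows, covariates have {n}"
            )
        pc_df = pd.DataFrame(
            scores,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
            index=covariates.index,
        )
        parts.append(pc_df)
    return pd.concat(parts, axis=1)


def _check_full_rank(x: np.ndarray, columns: Sequence[str]) -> None:
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        aliased = [columns[i] for i in sorted(piv[rank:])]
        raise AliasedDesignError(aliased)


def adjust_phenotype(
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    pcs: StructurePCs | np.ndarray | None = None,
    traits: Sequence[str] | None = None,
) -> AdjustedPhenotype:
    """OLS-adjust each trait for fixed effects and structure PCs.

    Parameters
    ----------
    phenotypes
        Table with ``individual_id`` plus one column per trait.
    covariates
        Table with ``individual_id`` plus the covariate columns.
    pcs
        Structure PC scores aligned by individual id (``StructurePCs``)
        or a plain array already aligned to the merged rows.
    traits
        Trait columns to adjust; default: every non-id column of
        ``phenotypes``.
    """
    if traits is None:
        traits = [c for c in phenotypes.columns if c != "individual_id"]
    merged = phenotypes.merge(covariates, on="individual_id", how="inner")

    if isinstance(pcs, StructurePCs):
        pc_df = pd.DataFrame(
            pcs.scores,
            columns=[f"PC{i + 1}" for i in range(pcs.k)],
        )
        pc_df.insert(0, "individual_id", pcs.individual_ids)
        merged = merged.merge(pc_df, on="individual_id", how="inner")
        pc_cols = [c for c in merged.columns if c.startswith("PC")]
        pc_arr: np.ndarray | None = merged[pc_cols].to_numpy()
        merged = merged.drop(columns=pc_cols)
    else:
        pc_arr = np.asarray(pcs) if pcs is not None else None

    complete = merged.drop(columns=traits).notna().all(axis=1)
    complete &= merged[traits].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("adjust_phenotype: dropped %d incomplete rows", n_dropped)
    merged = merged.loc[complete].reset_index(drop=True)
    if pc_arr is not None:
        pc_arr = pc_arr[complete.to_numpy()]
    if len(merged) == 0:
        raise DegenerateInputError("no complete phenotype/covariate rows remain")

    design = build_design(merged, pc_arr)
    x = design.to_numpy(dtype=np.float64)
    _check_full_rank(x, list(design.columns))

    residuals = {}
    r2 = {}
    for trait in traits:
        y = merged[trait].to_numpy(dtype=np.float64)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        resid = y - fitted
        residuals[trait] = resid
        tss = float(((y - y.mean()) ** 2).sum())
        r2[trait] = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0

    return AdjustedPhenotype(
        individual_ids=merged["individual_id"].to_numpy(dtype=object),
        residuals=pd.DataFrame(residuals),
        r_squared=r2,
        design_columns=list(design.columns),
        n_dropped_incomplete=n_dropped,
    )
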