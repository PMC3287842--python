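"""Two-stage covariate adjustment by ordinary-least-squares residualization.

Phenotypes are regressed on an intercept plus the chosen covariates (Age,
Smoking, ...) and the residuals are taken forward as the adjusted phenotypes;
the association tests then run on the residuals exactly as they would on a
raw trait.  Binary traits are residualized through the same linear model —
the whole pipeline, tests included, is deliberately linear for every trait.

Residualization is an orthogonal projection, so it is idempotent and leaves
anything already orthogonal to the covariate span untouched.  With an empty
covariate list the trait is still mean-centered (intercept-only fit), which
keeps adjusted and unadjusted analyses on one code path and changes no
permutation p-value.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .core import PhenotypeTable, ValidationError

log = logging.getLogger(__name__)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Greedily identify columns that do not increase the design rank."""
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    return bad


def adjust_phenotype(
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """OLS residuals of y on [1, covariates]; the adjusted phenotype.

    With ``covariates=None`` (or zero columns) this reduces to mean-centering.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((y.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if covariates.shape[0] != y.size:
        raise ValueError("covariate rows do not match phenotype length")
    X = np.column_stack([np.ones(y.size), covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        colnames = ["intercept"] + (
            list(names) if names is not None
            else [f"covariate_{j}" for j in range(covariates.shape[1])]
        )
        raise ValidationError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X, colnames)}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def adjust_table(table: PhenotypeTable, covariate_names: Sequence[str]) -> PhenotypeTable:
    """Residualize every trait (quantitative and binary) on the named covariates.

    The fit is done independently within each replicate — each replicate is a
    fresh phenotype realization over the same samples.  Covariate columns are
    retained but recorded as consumed in ``adjusted_for``.  Residualized
    binary traits are no longer {0,1}, so they are reported under the
    continuous traits of the returned table.
    """
    unknown = [c for c in covariate_names if c not in table.covariates]
    if unknown:
        raise ValidationError(f"unknown covariates: {unknown}")
    data = table.data.copy()
    outcome_cols = [*table.traits, *table.binary_traits]
    data[outcome_cols] = data[outcome_cols].astype(float)
    groups = (
        [data.index]
        if table.replicate_col is None
        else [g.index for _, g in data.groupby(table.replicate_col, sort=True)]
    )
    for rows in groups:
        cov = data.loc[rows, list(covariate_names)].to_numpy(dtype=float) if covariate_names else None
        for col in outcome_cols:
            data.loc[rows, col] = adjust_phenotype(
                data.loc[rows, col].to_numpy(dtype=float), cov, names=covariate_names
            )
    log.info("residualized %s on covariates %s", outcome_cols, list(covariate_names))
    return dataclasses.replace(
        table,
        data=data,
        traits=[*table.traits, *table.binary_traits],
        binary_traits=[],
        adjusted_for=tuple(covariate_names),
    )
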