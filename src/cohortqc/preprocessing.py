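"""Preparation of raw study tables for outlier detection.

The detectors expect complete, standardized matrices.  Preparation runs in
three steps: (1) optional covariate adjustment — each variable is replaced by
its residuals from a full-factorial linear regression on age, sex and years
of education, fitted on the rows where the variable is observed; (2) mean
imputation of missing entries; (3) scaling of every column to zero mean and
unit sample standard deviation.  Adjustment precedes imputation so the
imputation constant never leaks into the regression slopes, and
standardization runs last so the prepared columns have exactly mean 0 / sd 1
with imputed cells sitting exactly at 0.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datasets import CovariateTable, PreparedDataset, RawDataset

__all__ = [
    "DESIGN_TERMS",
    "design_matrix",
    "adjust_covariates",
    "standardize",
    "impute_missing",
    "prepare_variants",
]

#: Terms of the full-factorial adjustment model (intercept, three main
#: effects, three two-way interactions, one three-way interaction).
DESIGN_TERMS = (
    "intercept",
    "age",
    "sex",
    "education",
    "age:sex",
    "age:education",
    "sex:education",
    "age:sex:education",
)

# A column is treated as constant when its spread is negligible relative to
# the magnitude of its values (exact-fit residuals land here).
_CONSTANT_RTOL = 1e-10


def design_matrix(cov: CovariateTable) -> np.ndarray:
    """Full-factorial design matrix with columns ordered as DESIGN_TERMS."""
    a, s, e = cov.age, cov.sex, cov.education
    return np.column_stack(
        [np.ones_like(a), a, s, e, a * s, a * e, s * e, a * s * e]
    )


def _collinear_terms(design: np.ndarray) -> list[str]:
    """Names of design columns that do not increase the matrix rank."""
    bad, rank = [], 0
    for j in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            bad.append(DESIGN_TERMS[j])
        rank = new_rank
    return bad


def _is_constant(column: np.ndarray) -> bool:
    obs = column[~np.isnan(column)]
    if obs.size == 0:
        return True
    sd = obs.std(ddof=1) if obs.size > 1 else 0.0
    rms = float(np.sqrt(np.mean(obs**2)))
    return sd <= _CONSTANT_RTOL * max(1.0, rms)


def adjust_covariates(data: RawDataset, cov: CovariateTable) -> RawDataset:
    """Residualize every variable against the full-factorial covariate model.

    Each variable is regressed (ordinary least squares) on age, sex, years of
    education and all their interactions, using only the rows where the
    variable is observed; its entries are replaced by the residuals.  Missing
    entries stay missing.

    Raises
    ------
    ValueError
        If any participant lacks covariates, or the design matrix is rank
        deficient (the collinear terms are named in the message).
    """
    cov = cov.aligned_to(data.ids)
    design = design_matrix(cov)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_terms(design)
        raise ValueError(
            f"covariate design matrix is rank deficient; collinear terms: {bad}"
        )
    residuals = np.full_like(data.values, np.nan)
    for j in range(data.p):
        y = data.values[:, j]
        obs = ~np.isnan(y)
        d_obs = design[obs]
        if np.linalg.matrix_rank(d_obs) < design.shape[1]:
            bad = _collinear_terms(d_obs)
            raise ValueError(
                f"design rank deficient on observed rows of "
                f"{data.variable_names[j]!r}; collinear terms: {bad}"
            )
        beta, *_ = np.linalg.lstsq(d_obs, y[obs], rcond=None)
        residuals[obs, j] = y[obs] - d_obs @ beta
    return RawDataset(list(data.ids), residuals, list(data.variable_names))


def standardize(data: RawDataset, adjusted: bool = False) -> PreparedDataset:
    """Scale each column to mean 0 and sample standard deviation 1.

    Centers and scales come from the observed entries of each column; missing
    entries (NaN) are carried through unchanged — run :func:`impute_missing`
    first (or use :func:`prepare_variants`) to obtain a complete matrix.
    Constant columns are centered, kept on scale 1, and reported via a
    warning and the ``constant_columns`` field.
    """
    centers = np.empty(data.p)
    scales = np.empty(data.p)
    constant = []
    for j in range(data.p):
        col = data.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(
                f"column {data.variable_names[j]!r} is entirely missing")
        centers[j] = obs.mean()
        if _is_constant(col):
            scales[j] = 1.0
            constant.append(data.variable_names[j])
        else:
            scales[j] = obs.std(ddof=1)
    if constant:
        warnings.warn(f"constant columns kept on scale 1: {constant}",
                      stacklevel=2)
    values = (data.values - centers) / scales
    return PreparedDataset(
        ids=list(data.ids),
        variable_names=list(data.variable_names),
        values=values,
        imputed_mask=np.isnan(data.values),
        centers=centers,
        scales=scales,
        adjusted=adjusted,
        constant_columns=constant,
    )


def impute_missing(data: RawDataset) -> tuple[RawDataset, np.ndarray]:
    """Replace missing entries with the column mean of the observed entries.

    Returns the completed dataset and the boolean mask of imputed positions.
    A fully-missing column is an error.
    """
    values = data.values.copy()
    mask = np.isnan(values)
    for j in range(data.p):
        if mask[:, j].all():
            raise ValueError(
                f"column {data.variable_names[j]!r} is entirely missing")
        if mask[:, j].any():
            values[mask[:, j], j] = values[~mask[:, j], j].mean()
    return RawDataset(list(data.ids), values, list(data.variable_names)), mask


def _prepare(data: RawDataset, adjusted: bool) -> PreparedDataset:
    completed, mask = impute_missing(data)
    prepared = standardize(completed, adjusted=adjusted)
    prepared.imputed_mask = mask
    # Mean imputation preserves the column mean, so imputed cells are exactly
    # the center and standardize maps them to 0; pin them to avoid roundoff.
    prepared.values[mask] = 0.0
    return prepared


def prepare_variants(
    data: RawDataset, cov: CovariateTable | None = None
) -> dict[str, PreparedDataset]:
    """Build the standardized matrices the detectors consume.

    Returns ``{"unadjusted": ..., "adjusted": ...}``; the adjusted variant
    (covariate residuals, then imputation, then standardization) is only
    produced when a covariate table is given.
    """
    variants = {"unadjusted": _prepare(data, adjusted=False)}
    if cov is not None:
        variants["adjusted"] = _prepare(adjust_covariates(data, cov), adjusted=True)
    return variants
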