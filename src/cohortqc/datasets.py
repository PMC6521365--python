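"""Tabular containers for participants-by-variables study data.

A :class:`RawDataset` is the participants-by-variables numeric table as it
arrives from a data platform (missing entries allowed, stored as NaN).
A :class:`CovariateTable` carries the demographic adjustment covariates
(age in years, sex as a 0/1 indicator, education in years) keyed by the same
participant identifiers.  A :class:`PreparedDataset` is the complete,
standardized matrix the outlier detectors consume, together with the
imputation mask and the scaling parameters needed to map back to raw units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RawDataset", "CovariateTable", "PreparedDataset", "DEFAULT_NA_TOKENS"]

DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")


def _as_float_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def _check_unique(labels, what: str) -> None:
    seen = set()
    dupes = [x for x in labels if x in seen or seen.add(x)]
    if dupes:
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class RawDataset:
    """A participants-by-variables numeric table, possibly with missing entries.

    Parameters
    ----------
    ids
        Unique participant identifiers, one per row.
    values
        ``(n, p)`` float matrix; missing entries are NaN.
    variable_names
        Unique labels for the ``p`` columns.
    """

    ids: list[str]
    values: np.ndarray
    variable_names: list[str]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.variable_names = [str(v) for v in self.variable_names]
        self.values = _as_float_matrix(self.values)
        n, p = self.values.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if len(self.variable_names) != p:
            raise ValueError(f"{len(self.variable_names)} names for {p} columns")
        if n < 2:
            raise ValueError("need at least 2 participants")
        if p < 1:
            raise ValueError("need at least 1 variable")
        _check_unique(self.ids, "participant ids")
        _check_unique(self.variable_names, "variable names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def copy(self) -> "RawDataset":
        return RawDataset(list(self.ids), self.values.copy(), list(self.variable_names))

    def row_index(self, participant_id: str) -> int:
        return self.ids.index(str(participant_id))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str | None = None) -> "RawDataset":
        df = df.copy()
        if id_column is None:
            id_column = df.columns[0]
        ids = df[id_column].astype(str).tolist()
        data = df.drop(columns=[id_column])
        return cls(ids, data.to_numpy(dtype=float), list(data.columns))

    @classmethod
    def from_csv(cls, path, id_column: str | None = None,
                 na_tokens=DEFAULT_NA_TOKENS) -> "RawDataset":
        df = pd.read_csv(path, na_values=list(na_tokens), keep_default_na=False)
        return cls.from_dataframe(df, id_column=id_column)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "participant_id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CovariateTable:
    """Adjustment covariates: age (years), sex (0/1), education (years)."""

    ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    education: np.ndarray
    sex_reference: str | None = None  # the level coded as 1, if sex came as labels

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "participant ids")
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.education = np.asarray(self.education, dtype=float)
        n = len(self.ids)
        for name, arr in (("age", self.age), ("sex", self.sex),
                          ("education", self.education)):
            if arr.shape != (n,):
                raise ValueError(f"covariate {name!r} has shape {arr.shape}, expected ({n},)")
        missing = [self.ids[i] for i in range(n)
                   if np.isnan(self.age[i]) or np.isnan(self.sex[i])
                   or np.isnan(self.education[i])]
        if missing:
            raise ValueError(f"missing covariate values for participants: {missing}")
        bad_sex = sorted(set(self.sex) - {0.0, 1.0})
        if bad_sex:
            raise ValueError(f"sex must be coded 0/1, found values {bad_sex}")

    def aligned_to(self, ids: list[str]) -> "CovariateTable":
        """Reorder rows to match ``ids``; every id must be present."""
        index = {pid: i for i, pid in enumerate(self.ids)}
        missing = [pid for pid in ids if pid not in index]
        if missing:
            raise ValueError(f"covariates missing for participants: {missing}")
        order = [index[pid] for pid in ids]
        return CovariateTable([self.ids[i] for i in order], self.age[order],
                              self.sex[order], self.education[order],
                              self.sex_reference)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str | None = None,
                       sex_reference: str | None = None) -> "CovariateTable":
        if id_column is None:
            id_column = df.columns[0]
        ids = df[id_column].astype(str).tolist()
        cols = {c.lower(): c for c in df.columns}
        for required in ("age", "sex", "education"):
            if required not in cols:
                raise ValueError(f"covariate table needs a {required!r} column")
        sex_raw = df[cols["sex"]]
        if sex_raw.dtype.kind in "OUS":
            if sex_reference is None:
                raise ValueError(
                    "sex column is categorical; pass sex_reference to choose the "
                    "level coded as 1")
            sex = (sex_raw.astype(str) == str(sex_reference)).astype(float).to_numpy()
        else:
            sex = sex_raw.to_numpy(dtype=float)
        return cls(ids, df[cols["age"]].to_numpy(dtype=float), sex,
                   df[cols["education"]].to_numpy(dtype=float), sex_reference)

    @classmethod
    def from_csv(cls, path, id_column: str | None = None,
                 sex_reference: str | None = None) -> "CovariateTable":
        return cls.from_dataframe(pd.read_csv(path), id_column=id_column,
                                  sex_reference=sex_reference)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"participant_id": self.ids, "age": self.age,
                             "sex": self.sex, "education": self.education})


@dataclass
class PreparedDataset:
    """Standardized (optionally covariate-adjusted) complete data matrix.

    ``values`` has zero column means and unit sample standard deviation except
    for constant columns, which are centered and left on scale 1.  Cells that
    were imputed with the column mean are exactly 0 after standardization and
    are marked in ``imputed_mask``.
    """

    ids: list[str]
    variable_names: list[str]
    values: np.ndarray
    imputed_mask: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    adjusted: bool = False
    constant_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.imputed_mask.shape != self.values.shape:
            raise ValueError("imputed_mask shape mismatch")
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def log(self) -> dict:
        """Preprocessing provenance, serializable to JSON."""
        return {
            "adjusted": bool(self.adjusted),
            "n": self.n,
            "p": self.p,
            "centers": dict(zip(self.variable_names, self.centers.tolist())),
            "scales": dict(zip(self.variable_names, self.scales.tolist())),
            "constant_columns": list(self.constant_columns),
            "n_imputed": int(self.imputed_mask.sum()),
            "imputed_cells": [
                [self.ids[i], self.variable_names[j]]
                for i, j in zip(*np.nonzero(self.imputed_mask))
            ],
        }

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "participant_id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
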