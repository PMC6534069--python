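"""Sample-aligned data containers for multi-omic tables.

Three containers cover the study's data types: a generic samples x variables
:class:`FeatureTable` (diet or metabolite intensities), a
:class:`CompositionMatrix` holding relative abundances on the simplex
(optionally with the raw counts they were closed from), and
:class:`SampleMetadata` carrying the covariates used in normalization
(gender, total caloric intake, batch, BMI).

All containers wrap a :class:`pandas.DataFrame` indexed by sample id, so the
usual pandas machinery (alignment, selection, round-trip to TSV) applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CompositionMatrix",
    "SampleMetadata",
    "to_composition",
    "align_samples",
]

_CLOSE_TOL = 1e-9


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class FeatureTable:
    """Samples x variables numeric matrix with optional per-variable metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric values, rows = samples, columns = variables. NaN marks an
        explicitly missing cell (e.g. below the limit of detection); it is
        never silently treated as zero.
    variable_meta : mapping, optional
        variable_id -> {"pathway": ..., "sub_pathway": ...} annotations.
    """

    data: pd.DataFrame
    variable_meta: Mapping[str, Mapping[str, str]] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "variable ids")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (inf) values in feature table")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], self.variable_meta)

    def select_variables(self, variable_ids: Sequence[str]) -> "FeatureTable":
        meta = None
        if self.variable_meta is not None:
            meta = {v: self.variable_meta[v] for v in variable_ids
                    if v in self.variable_meta}
        return FeatureTable(self.data.loc[:, list(variable_ids)], meta)


@dataclass
class CompositionMatrix:
    """Relative abundances on the simplex: rows are samples summing to one.

    ``counts`` optionally retains the integer table the proportions were
    closed from, so compositional invariance (results unchanged under
    per-sample rescaling of counts) can be asserted.
    """

    proportions: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.proportions.index, "sample ids")
        _check_unique(self.proportions.columns, "taxon ids")
        p = self.proportions.to_numpy(dtype=float)
        if (p < -_CLOSE_TOL).any():
            raise ValueError("negative proportions")
        rowsums = p.sum(axis=1)
        bad = np.abs(rowsums - 1.0) > _CLOSE_TOL
        if bad.any():
            names = list(self.proportions.index[bad][:5])
            raise ValueError(f"rows do not sum to 1 (within {_CLOSE_TOL}): {names}")
        if self.counts is not None and (
            list(self.counts.index) != list(self.proportions.index)
            or list(self.counts.columns) != list(self.proportions.columns)
        ):
            raise ValueError("counts and proportions are not aligned")
        self.proportions = self.proportions.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def values(self) -> np.ndarray:
        return self.proportions.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.proportions.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "CompositionMatrix":
        ids = list(sample_ids)
        counts = self.counts.loc[ids] if self.counts is not None else None
        return CompositionMatrix(self.proportions.loc[ids], counts)


@dataclass
class SampleMetadata:
    """Per-sample covariates: gender, total caloric intake, batch, BMI.

    ``data`` must carry at least ``gender`` and ``total_kcal`` columns when
    the residual-adjustment stage is used; extra covariate columns pass
    through untouched.
    """

    data: pd.DataFrame
    required: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        for col in self.required:
            if col not in self.data.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if "total_kcal" in self.data.columns:
            kcal = pd.to_numeric(self.data["total_kcal"])
            if (kcal <= 0).any():
                bad = list(self.data.index[kcal <= 0][:5])
                raise ValueError(f"total_kcal must be positive; offending samples {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)], self.required)


def to_composition(counts: FeatureTable) -> CompositionMatrix:
    """Close a non-negative count table to relative abundances.

    Raises on negative entries and on samples whose row sum is zero (an
    empty sample carries no compositional information).
    """
    vals = counts.values
    if np.isnan(vals).any():
        raise ValueError("count table contains missing values")
    if (vals < 0).any():
        raise ValueError("count table contains negative values")
    rowsums = vals.sum(axis=1)
    zero = rowsums == 0
    if zero.any():
        names = [counts.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample rows: {names}")
    props = pd.DataFrame(
        vals / rowsums[:, None], index=counts.data.index, columns=counts.data.columns
    )
    return CompositionMatrix(props, counts=counts.data.copy())


def align_samples(*tables):
    """Intersect and identically order the sample sets of two or more tables.

    Accepts any mix of :class:`FeatureTable`, :class:`CompositionMatrix` and
    :class:`SampleMetadata`. The output order follows the first table's
    sample order restricted to the intersection. Returns the tables in the
    order given, plus nothing else; dropped-sample counts are available from
    the inputs' sizes.
    """
    if len(tables) < 2:
        raise ValueError("align_samples needs at least two tables")
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if not common:
        raise ValueError("sample intersection is empty")
    order = [s for s in tables[0].sample_ids if s in common]
    return tuple(t.select_samples(order) for t in tables)
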