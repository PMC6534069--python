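"""Readers/writers for sample-aligned tables and run configuration.

Tables are plain TSV/CSV (dialect auto-detected from the extension) with one
header row of variable ids and the first column holding sample ids. Missing
cells are empty or ``NA`` and come back as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, SampleMetadata

__all__ = ["read_feature_table", "write_feature_table", "read_metadata",
           "RunConfig"]

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_table(path, orientation: str = "samples-in-rows",
                       variable_meta=None) -> FeatureTable:
    """Read a delimited numeric table into a :class:`FeatureTable`.

    Parameters
    ----------
    orientation : {"samples-in-rows", "samples-in-columns"}
        Layout of the file; the returned table is always samples x variables.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     na_values=_NA_VALUES, keep_default_na=False)
    if orientation == "samples-in-columns":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample ids in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate variable ids in {path.name}: {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # numpy's string->double conversion is correctly rounded
            # (pd.to_numeric's fast path is not bit-exact)
            numeric[col] = df[col].astype(float)
        except (TypeError, ValueError):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric cell in {path.name} at row {row!r}, "
                f"column {col!r}: {df.loc[row, col]!r}"
            ) from None
    return FeatureTable(numeric, variable_meta=variable_meta)


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index_label="sample_id",
                      na_rep="NA", float_format="%.17g")


def read_metadata(path, required=("gender", "total_kcal")) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     na_values=_NA_VALUES, keep_default_na=False)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample ids in {path.name}: {dups}")
    return SampleMetadata(df, required=tuple(required))


@dataclass
class RunConfig:
    """Pipeline configuration: seeds, thresholds, and stage parameters.

    One master seed governs all randomness; each stage derives its own seed
    as ``master_seed + stage offset`` so stages are reproducible in
    isolation. Defaults mirror the analysis protocol: Spearman 0.9
    deduplication, Shapiro alpha 0.05, top-50 genera, 100 bootstraps with
    a strict >70 selection threshold, 10-fold CV.
    """

    master_seed: int = 0
    spearman_dedup: float = 0.9
    shapiro_alpha: float = 0.05
    top_k_taxa: int = 50
    n_bootstrap: int = 100
    selection_min: int = 70
    cv_folds: int = 10
    n_lambda: int = 100
    distance: str = "jaccard"
    min_module_size: int = 10
    cut_height: float | None = None
    mediation_bootstrap: int = 500
    ci_level: float = 0.95
    # synthetic-data scale (desk-scale default; full_scale preset in simulate)
    n_samples: int = 136
    n_taxa: int = 130
    n_diet: int = 91
    n_metabolites: int = 200
    output_dir: str = "triomix_out"

    _STAGE_OFFSETS = {
        "simulate": 11, "preprocess": 23, "modules": 37, "global": 41,
        "logcontrast": 53, "mediate": 67, "enterotype": 79,
    }

    def __post_init__(self) -> None:
        if not (0.0 < self.spearman_dedup < 1.0):
            raise ValueError("spearman_dedup must be in (0, 1)")
        if not (0.0 <= self.shapiro_alpha <= 1.0):
            raise ValueError("shapiro_alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.top_k_taxa < 1:
            raise ValueError("top_k_taxa must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0 <= self.selection_min <= self.n_bootstrap):
            raise ValueError("selection_min must be in [0, n_bootstrap]")
        if not (0.5 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0.5, 1)")
        if self.distance not in ("euclidean", "bray-curtis", "jaccard"):
            raise ValueError(f"unknown distance {self.distance!r}")

    def stage_seed(self, stage: str) -> int:
        return int(self.master_seed) + self._STAGE_OFFSETS[stage]

    def to_yaml(self, path) -> None:
        d = {k: v for k, v in asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
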