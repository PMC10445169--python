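"""Mature-miRNA composition statistics, expressed-feature counting and volcano
classification of differential-expression tables."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io import validate_de_table

__all__ = [
    "MiRNACountMatrix",
    "VolcanoClass",
    "read_mirna_counts",
    "relative_abundance",
    "count_expressed",
    "classify_volcano",
    "classify_volcano_table",
    "top_n",
]


@dataclass(frozen=True)
class MiRNACountMatrix:
    """Raw mature-miRNA counts (miRNA x sample) with a group label per sample."""

    counts: pd.DataFrame
    groups: pd.Series  # sample_id -> group label

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValidationError("duplicate miRNA identifiers")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("miRNA counts must be integers")
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("miRNA counts must be nonnegative")
        groups = self.groups.reindex(self.counts.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValidationError(f"samples without a group label: {missing}")
        object.__setattr__(self, "groups", groups)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def read_mirna_counts(counts_path: str | Path, groups: Mapping[str, str] | str | Path) -> MiRNACountMatrix:
    """Read a miRNA x sample count TSV plus a sample->group mapping.

    ``groups`` may be a mapping or the path of a two-column TSV
    (sample_id, group).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if isinstance(groups, (str, Path)):
        gdf = pd.read_csv(groups, sep="\t", dtype=str)
        if gdf.shape[1] < 2:
            raise FormatError(f"{groups}: expected two columns (sample_id, group)")
        groups = dict(zip(gdf.iloc[:, 0], gdf.iloc[:, 1]))
    series = pd.Series(dict(groups), name="group")
    return MiRNACountMatrix(counts=counts, groups=series)


def relative_abundance(
    matrix: MiRNACountMatrix, group: str, mode: str = "pooled"
) -> pd.Series:
    """Percentage of total miRNA counts attributed to each miRNA within a group.

    ``mode="pooled"`` (default) sums counts over the group's samples before
    dividing — the share of all sequenced miRNA molecules each species
    represents.  ``mode="mean_fraction"`` averages per-sample fractions
    instead, which down-weights deep libraries.
    """
    samples = matrix.samples_in(group)
    if not samples:
        raise ValidationError(f"no samples in group {group!r}")
    sub = matrix.counts[samples]
    if mode == "pooled":
        totals = sub.sum(axis=1)
        grand = totals.sum()
        if grand == 0:
            raise ValidationError(f"group {group!r} has zero total counts")
        pct = 100.0 * totals / grand
    elif mode == "mean_fraction":
        colsum = sub.sum(axis=0)
        if (colsum == 0).any():
            raise ValidationError("a sample has zero total counts")
        pct = 100.0 * (sub / colsum).mean(axis=1)
    else:
        raise ValidationError(f"unknown abundance mode {mode!r}")
    return pct.sort_values(ascending=False).rename("percent")


def count_expressed(matrix: MiRNACountMatrix, min_count: int = 1) -> int:
    """Number of miRNAs with count >= min_count in at least one sample."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    return int((matrix.counts >= min_count).any(axis=1).sum())


class VolcanoClass(enum.Enum):
    """Quadrant of a volcano plot given significance and fold-change thresholds."""

    SIG_AND_LARGE = "sig_and_large"
    LARGE_ONLY = "large_only"
    SIG_ONLY = "sig_only"
    NEITHER = "neither"


def classify_volcano(
    log2_fold_change: float, p_adj: float, p_thresh: float = 0.05, lfc_thresh: float = 1.0
) -> VolcanoClass:
    """Classify one feature by the joint significance / effect-size criterion
    (significant means p_adj < p_thresh; large means |log2FC| > lfc_thresh)."""
    if not (np.isfinite(log2_fold_change) and np.isfinite(p_adj)):
        raise ValidationError("volcano classification needs finite inputs")
    sig = p_adj < p_thresh
    large = abs(log2_fold_change) > lfc_thresh
    if sig and large:
        return VolcanoClass.SIG_AND_LARGE
    if large:
        return VolcanoClass.LARGE_ONLY
    if sig:
        return VolcanoClass.SIG_ONLY
    return VolcanoClass.NEITHER


def classify_volcano_table(
    table: pd.DataFrame, p_thresh: float = 0.05, lfc_thresh: float = 1.0
) -> pd.DataFrame:
    """Append a ``volcano_class`` column to a DE table."""
    table = validate_de_table(table)
    classes = [
        classify_volcano(lfc, p, p_thresh, lfc_thresh).value
        for lfc, p in zip(table["log2_fold_change"], table["p_adj"])
    ]
    out = table.copy()
    out["volcano_class"] = classes
    return out


def top_n(
    table: pd.DataFrame,
    direction: str,
    n: int = 10,
    p_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Top-n up- or downregulated features passing both volcano criteria.

    Rows are ordered by ascending adjusted p, ties by |log2FC| descending then
    feature id; fewer than n rows may be returned.
    """
    if direction not in {"up", "down"}:
        raise ValidationError("direction must be 'up' or 'down'")
    if n < 1:
        raise ValidationError("n must be >= 1")
    table = validate_de_table(table)
    sign_ok = table["log2_fold_change"] > 0 if direction == "up" else table["log2_fold_change"] < 0
    sig = (table["p_adj"] < p_thresh) & (table["log2_fold_change"].abs() > lfc_thresh)
    sub = table[sign_ok & sig].copy()
    sub["_abs_lfc"] = sub["log2_fold_change"].abs()
    sub = sub.sort_values(
        by=["p_adj", "_abs_lfc", "feature_id"], ascending=[True, False, True]
    ).drop(columns="_abs_lfc")
    return sub.head(n).reset_index(drop=True)
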