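"""Domain containers and readers/writers for the text formats the pipeline touches.

Gene identifiers are HUGO symbols matched by exact, case-sensitive string
equality; no aliasing or cross-namespace mapping is attempted.  All tabular
formats are UTF-8 tab-separated text with ``.`` as the decimal mark and no
quoting.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ContingencyTable2x2",
    "read_gmt",
    "write_gmt",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_exclusion_list",
    "apply_exclusion",
    "read_de_table",
    "read_sample_annotation",
]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative expression values for uniquely named genes across samples.

    ``values`` is a genes x samples DataFrame.  Units are arbitrary but must be
    consistent within one matrix (TPM, normalized counts, ...); downstream
    rank-based scoring is invariant to monotone per-sample transforms.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0 or v.shape[1] == 0:
            raise ValidationError("expression matrix must have at least one gene and one sample")
        dup = v.index[v.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene identifier(s): {sorted(set(dup))}")
        dupc = v.columns[v.columns.duplicated()]
        if len(dupc):
            raise ValidationError(f"duplicate sample identifier(s): {sorted(set(dupc))}")
        if v.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if (v.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathways as sets of gene identifiers (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] for a 2x2 clinical contingency table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any((not isinstance(x, (int,)) or x < 0) for x in cells):
            raise ValidationError("contingency table entries must be nonnegative integers")
        if sum(cells) == 0:
            raise ValidationError("contingency table total must be positive")

    def as_array(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, fields name, description, members...

    Duplicate member genes within a line are collapsed; a line with fewer than
    three fields (i.e. a member-less set) or a repeated set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= 2:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a GeneSetCollection as GMT; members are written sorted for determinism."""
    with _open_text(path, "wt") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene row(s): {sorted(set(dup))}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.rename_axis(index=None)
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line exclusion list; '#' starts a comment."""
    genes: set[str] = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    return frozenset(genes)


def apply_exclusion(matrix: ExpressionMatrix, excluded: Iterable[str]) -> ExpressionMatrix:
    """Drop excluded genes (e.g. housekeeping, immune/stromal markers) from a matrix.

    Idempotent; raises if the exclusion would remove every gene.
    """
    excluded = frozenset(excluded)
    keep = [g for g in matrix.values.index if g not in excluded]
    if not keep:
        raise ValidationError("exclusion list removes every gene in the matrix")
    if len(keep) == matrix.shape[0]:
        return matrix
    return ExpressionMatrix(matrix.values.loc[keep])


_DE_COLUMN_ALIASES = {
    "feature_id": ("feature_id", "gene", "gene_id", "mirna", "feature", "id"),
    "log2_fold_change": ("log2_fold_change", "log2foldchange", "log2fc", "lfc"),
    "p_adj": ("p_adj", "padj", "fdr", "adj_p", "qvalue"),
}


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression result table (TSV).

    Accepts DESeq2-style headers (``log2FoldChange``, ``padj``) and normalizes
    them to columns ``feature_id``, ``log2_fold_change``, ``p_adj``.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename: dict[str, str] = {}
    for canonical, aliases in _DE_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
        else:
            raise FormatError(f"{path}: missing a column for {canonical!r} (have {list(df.columns)})")
    df = df.rename(columns=rename)[list(_DE_COLUMN_ALIASES)]
    return validate_de_table(df)


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"feature_id", "log2_fold_change", "p_adj"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"DE table missing columns: {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValidationError(f"DE table has duplicate feature ids: {dups}")
    p = df["p_adj"].astype(float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("adjusted p-values must lie in [0, 1]")
    out = df.copy()
    out["log2_fold_change"] = out["log2_fold_change"].astype(float)
    out["p_adj"] = p
    return out


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read sample annotations: TSV with columns sample_id, class_label[, origin]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation is missing column {col!r}")
    if "origin" not in df.columns:
        df["origin"] = "tissue"
    if df["sample_id"].duplicated().any():
        raise ValidationError("annotation has duplicate sample ids")
    return df[["sample_id", "class_label", "origin"]]


def class_labels(annotation: pd.DataFrame, sample_ids: Iterable[str]) -> pd.Series:
    """Return the class label for each requested sample, erroring on gaps."""
    mapping: Mapping[str, str] = dict(zip(annotation["sample_id"], annotation["class_label"]))
    sample_ids = list(sample_ids)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"samples without annotation: {missing}")
    return pd.Series([mapping[s] for s in sample_ids], index=sample_ids, name="class_label")
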