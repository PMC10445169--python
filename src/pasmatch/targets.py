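"""miRNA target consensus across prediction sources and over-representation statistics.

Target predictions from several databases (e.g. TargetScan, miRDB, miRTarBase)
are intersected with a downregulated gene list; the consensus is the set of
genes every source agrees on.  Category enrichment in a gene list is tested
with the upper-tail hypergeometric distribution and summarized by the
enrichment ratio (k/n)/(K/N), with Benjamini-Hochberg correction across
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError
from .io import GeneSetCollection

__all__ = [
    "TargetPredictionSet",
    "ConsensusResult",
    "read_target_predictions",
    "downregulated_genes",
    "consensus",
    "hypergeom_enrichment",
    "enrichment_table",
]


@dataclass(frozen=True)
class TargetPredictionSet:
    """Predicted target genes of one miRNA from one prediction source."""

    source: str
    mirna: str
    genes: frozenset[str]


@dataclass(frozen=True)
class ConsensusResult:
    """Per-source intersections with a gene list, their consensus and union."""

    per_source: dict[str, frozenset[str]]
    consensus: frozenset[str]
    union: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        out = {source: len(genes) for source, genes in self.per_source.items()}
        out["consensus"] = len(self.consensus)
        out["union"] = len(self.union)
        return out


def read_target_predictions(path: str | Path, source: str, mirna: str | None = None) -> TargetPredictionSet:
    """Read a flat two-column TSV (miRNA, target gene) for one prediction source."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (miRNA, gene)")
    mir_col, gene_col = df.columns[:2]
    if mirna is not None:
        df = df[df[mir_col] == mirna]
        found = mirna
    else:
        mirnas = df[mir_col].unique()
        if len(mirnas) != 1:
            raise ValidationError(f"{path}: multiple miRNAs present; pass `mirna` to select one")
        found = mirnas[0]
    return TargetPredictionSet(source=source, mirna=found, genes=frozenset(df[gene_col].dropna()))


def downregulated_genes(table: pd.DataFrame, p_thresh: float = 0.05, lfc_thresh: float = 1.0) -> frozenset[str]:
    """Genes significantly downregulated: p_adj < p_thresh and log2FC < -lfc_thresh."""
    mask = (table["p_adj"] < p_thresh) & (table["log2_fold_change"] < -lfc_thresh)
    return frozenset(table.loc[mask, "feature_id"])


def consensus(down: Iterable[str], predictions: Sequence[TargetPredictionSet]) -> ConsensusResult:
    """Intersect a downregulated gene set with each prediction source.

    consensus = genes in every source's intersection; union = genes in at
    least one.  Order-invariant in the prediction list and idempotent under
    source duplication.
    """
    if not predictions:
        raise ValidationError("at least one target-prediction source is required")
    down = frozenset(down)
    per_source: dict[str, frozenset[str]] = {}
    for pred in predictions:
        hit = down & pred.genes
        if pred.source in per_source and per_source[pred.source] != hit:
            raise ValidationError(f"conflicting duplicate source {pred.source!r}")
        per_source[pred.source] = hit
    sets = list(per_source.values())
    inter = frozenset.intersection(*sets)
    union = frozenset.union(*sets)
    return ConsensusResult(per_source=per_source, consensus=inter, union=union)


def hypergeom_enrichment(k: int, n: int, category_size: int, universe: int) -> tuple[float, float]:
    """Upper-tail hypergeometric over-representation test.

    ``k`` hits in a list of ``n`` genes, for a category of ``category_size``
    genes within a universe of ``universe`` genes.  Returns
    ``(P(X >= k), enrichment_ratio)`` with enrichment_ratio =
    (k/n) / (category_size/universe).
    """
    if not (0 <= k <= min(n, category_size) <= universe) or n < 1 or category_size < 1:
        raise ValidationError(
            f"inconsistent counts: k={k}, n={n}, category={category_size}, universe={universe}"
        )
    if n > universe:
        raise ValidationError("gene list larger than universe")
    p = float(stats.hypergeom.sf(k - 1, universe, category_size, n))
    ratio = (k / n) / (category_size / universe)
    return min(p, 1.0), ratio


def enrichment_table(
    gene_list: Iterable[str],
    categories: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of each category in a gene list, BH-adjusted.

    Categories and the gene list are restricted to the universe before
    testing; categories with no representation in the universe are skipped.
    """
    universe = frozenset(universe)
    genes = frozenset(gene_list) & universe
    if not genes:
        raise ValidationError("gene list has no overlap with the universe")
    rows = []
    for name, members in categories.items():
        cat = members & universe
        if not cat:
            continue
        k = len(genes & cat)
        p, ratio = hypergeom_enrichment(k, len(genes), len(cat), len(universe))
        rows.append((name, k, len(cat), ratio, p))
    df = pd.DataFrame(rows, columns=["category", "hits", "category_size", "enrichment_ratio", "p_value"])
    if len(df):
        df["p_adj"] = stats.false_discovery_control(df["p_value"], method="bh")
        df = df.sort_values(["p_value", "category"]).reset_index(drop=True)
    return df
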