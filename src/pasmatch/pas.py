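"""Rank-truncated pathway activity scores (PAS).

For one sample's expression profile the genes are sorted in decreasing order
of expression and gene ``g`` receives rank ``i_g`` (1 = highest).  A pathway
``P`` is scored as

    PAS = sum_{g in P} max(K - i_g, 0) / (|P| * K)

so only members ranked within the top ``K`` genes contribute, with weight
proportional to how high they rank.  ``|P|`` is the full pathway size: members
absent from the matrix stay in the denominator and contribute 0, which keeps
scores comparable across matrices with different gene coverage.  Scores lie in
[0, 1); a pathway of size m <= K whose members occupy ranks 1..m attains the
maximum (K - (m+1)/2) / K / 1 ... i.e. (K - (m+1)/2) / K.

Ranks are ordinal: ties are broken by descending value then ascending gene
identifier, so scoring is deterministic across runs and platforms.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .io import ExpressionMatrix, GeneSetCollection

__all__ = ["PASMatrix", "rank_genes", "pas_score", "pas_matrix", "write_pas_matrix", "read_pas_matrix"]

DEFAULT_K = 3000


@dataclass(frozen=True)
class PASMatrix:
    """Pathway x sample matrix of PAS values together with the truncation K."""

    scores: pd.DataFrame
    k: int
    exclusion_checksum: str | None = None

    @property
    def pathway_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _ordinal_ranks(values: np.ndarray, gene_lex_rank: np.ndarray) -> np.ndarray:
    """1-based ranks by decreasing value; ties by ascending gene identifier."""
    order = np.lexsort((gene_lex_rank, -values))
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def rank_genes(profile: pd.Series) -> pd.Series:
    """Rank one sample's expression profile, 1 = highest expression.

    Strictly higher values get strictly smaller ranks; ties are resolved by
    ascending gene id so the result is a deterministic permutation of 1..N.
    """
    if len(profile) == 0:
        raise ValidationError("cannot rank an empty expression profile")
    genes = profile.index.to_numpy(dtype=object)
    lex = np.empty(len(genes), dtype=np.int64)
    lex[np.argsort(genes, kind="stable")] = np.arange(len(genes))
    ranks = _ordinal_ranks(profile.to_numpy(dtype=float), lex)
    return pd.Series(ranks, index=profile.index, name="rank")


def pas_score(ranks: Mapping[str, int], pathway: Iterable[str], k: int = DEFAULT_K) -> float:
    """PAS of one pathway on one ranked profile.

    Pathway members missing from ``ranks`` contribute 0 but still count in the
    pathway size used for normalization.
    """
    pathway = frozenset(pathway)
    if not pathway:
        raise ValidationError("pathway is empty")
    if k < 1:
        raise ValidationError("K must be a positive integer")
    total = 0.0
    for g in pathway:
        i_g = ranks.get(g)
        if i_g is not None and i_g < k:
            total += k - i_g
    return total / (len(pathway) * k)


def pas_matrix(matrix: ExpressionMatrix, sets: GeneSetCollection, k: int = DEFAULT_K) -> PASMatrix:
    """PAS for every pathway and every sample of an expression matrix."""
    if k < 1:
        raise ValidationError("K must be a positive integer")
    if len(sets) == 0:
        raise ValidationError("gene set collection is empty")
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    genes = matrix.values.index.to_numpy(dtype=object)
    lex = np.empty(n_genes, dtype=np.int64)
    lex[np.argsort(genes, kind="stable")] = np.arange(n_genes)

    weights = np.empty((n_genes, n_samples), dtype=float)
    for j in range(n_samples):
        ranks = _ordinal_ranks(values[:, j], lex)
        weights[:, j] = np.maximum(k - ranks, 0)

    gene_index = {g: i for i, g in enumerate(genes)}
    names = list(sets)
    membership = np.zeros((len(names), n_genes), dtype=float)
    sizes = np.empty(len(names), dtype=float)
    for row, name in enumerate(names):
        members = sets[name]
        sizes[row] = len(members)  # full |P|, including genes absent from the matrix
        idx = [gene_index[g] for g in members if g in gene_index]
        membership[row, idx] = 1.0

    scores = membership @ weights / (sizes[:, None] * k)
    frame = pd.DataFrame(scores, index=names, columns=matrix.values.columns)
    return PASMatrix(scores=frame, k=k)


_HEADER_RE = re.compile(r"^#\s*K=(\d+)(?:\s+exclusion_sha256=(\S+))?\s*$")


def write_pas_matrix(pas: PASMatrix, path: str | Path) -> None:
    """Write a PAS matrix as TSV with a header comment recording K (and, when
    known, the checksum of the exclusion list that produced it)."""
    with open(path, "w", encoding="utf-8") as fh:
        header = f"# K={pas.k}"
        if pas.exclusion_checksum:
            header += f" exclusion_sha256={pas.exclusion_checksum}"
        fh.write(header + "\n")
        pas.scores.to_csv(fh, sep="\t", index_label="pathway")


def read_pas_matrix(path: str | Path) -> PASMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        m = _HEADER_RE.match(first)
        if not m:
            raise FormatError(f"{path}: missing '# K=...' header comment")
        k = int(m.group(1))
        checksum = m.group(2)
        frame = pd.read_csv(fh, sep="\t", index_col=0).rename_axis(index=None)
    return PASMatrix(scores=frame, k=k, exclusion_checksum=checksum)


def exclusion_checksum(excluded: Iterable[str]) -> str:
    """Stable sha256 over the sorted exclusion list, for provenance headers."""
    payload = "\n".join(sorted(excluded)).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()
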