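"""Configuration-driven orchestration of the analysis stages with provenance.

The full pipeline is: gene exclusion -> PAS -> pathway selection -> sample
similarity -> hierarchical clustering, plus (when miRNA inputs are present)
miRNA profiling -> target consensus -> over-representation.  Every stage
writes its output under the configured directory and the run ends with a
manifest recording the configuration hash, the seed and a checksum per output
file, so re-running any stage from its persisted inputs is bit-for-bit
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from . import mirna as pmirna
from . import targets as ptargets
from .errors import PasmatchError, ValidationError
from .pas import exclusion_checksum, pas_matrix, write_pas_matrix
from .selection import select_pathways, select_to_count, write_selection
from .similarity import cluster_samples, similarity_matrix

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("pasmatch")


@dataclass(frozen=True)
class RunConfig:
    """Validated inputs and parameters for one pipeline run."""

    expression: str
    gene_sets: str
    annotation: str
    output_dir: str
    exclusion: str | None = None
    de_table: str | None = None
    mirna_counts: str | None = None
    mirna_groups: str | None = None
    target_predictions: dict[str, str] = field(default_factory=dict)  # source -> path
    k: int = 3000
    penalty: float | str = "auto"
    target_count: int | None = None
    p_thresh: float = 0.05
    lfc_thresh: float = 1.0
    linkage: str = "average"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValidationError("K must be >= 1")
        if self.p_thresh <= 0 or self.lfc_thresh <= 0:
            raise ValidationError("thresholds must be positive")
        required = {"expression": self.expression, "gene_sets": self.gene_sets, "annotation": self.annotation}
        optional = {
            "exclusion": self.exclusion,
            "de_table": self.de_table,
            "mirna_counts": self.mirna_counts,
            "mirna_groups": self.mirna_groups,
            **{f"targets[{s}]": p for s, p in self.target_predictions.items()},
        }
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise ValidationError(f"config: {name} file not found: {path}")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a nested key-value YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: v for k, v in config.__dict__.items()}, sort_keys=True, default=str
    ).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest.

    Any stage error aborts the run with the failing stage named; outputs
    written before the failure are flagged stale in the manifest.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)
            written.append(p)
        log.info("stage=%s status=ok outputs=%s", stage, [p.name for p in paths])

    stage = "load"
    try:
        matrix = pio.read_expression_matrix(config.expression)
        sets = pio.read_gmt(config.gene_sets)
        annotation = pio.read_sample_annotation(config.annotation)
        record(stage)

        stage = "exclusion"
        checksum = None
        if config.exclusion:
            excluded = pio.read_exclusion_list(config.exclusion)
            matrix = pio.apply_exclusion(matrix, excluded)
            checksum = exclusion_checksum(excluded)
        record(stage)

        stage = "pas"
        pas = replace(pas_matrix(matrix, sets, k=config.k), exclusion_checksum=checksum)
        pas_path = outdir / "pas.tsv"
        write_pas_matrix(pas, pas_path)
        record(stage, pas_path)

        stage = "selection"
        labels = pio.class_labels(annotation, pas.sample_ids)
        if config.target_count is not None:
            result = select_to_count(pas, labels, config.target_count, seed=config.seed)
        else:
            result = select_pathways(pas, labels, penalty=config.penalty, seed=config.seed)
        sel_path = outdir / "selection.tsv"
        write_selection(result, sel_path)
        record(stage, sel_path)

        stage = "similarity"
        panel = result.selected_pathways if len(result.selected_pathways) >= 3 else pas.pathway_names
        sim = similarity_matrix(pas, panel)
        sim_path = outdir / "similarity.tsv"
        sim.pcc.to_csv(sim_path, sep="\t", index_label="sample")
        record(stage, sim_path)

        stage = "clustering"
        clust = cluster_samples(sim, method=config.linkage)
        tree_path = outdir / "dendrogram.nwk"
        tree_path.write_text(clust.newick + "\n", encoding="utf-8")
        order_path = outdir / "leaf_order.txt"
        order_path.write_text("\n".join(clust.leaf_order) + "\n", encoding="utf-8")
        record(stage, tree_path, order_path)

        if config.mirna_counts and config.mirna_groups:
            stage = "mirna_profiling"
            mat = pmirna.read_mirna_counts(config.mirna_counts, config.mirna_groups)
            frames = []
            for group in sorted(mat.groups.unique()):
                pct = pmirna.relative_abundance(mat, group).rename(group)
                frames.append(pct)
            abundance = pd.concat(frames, axis=1)
            ab_path = outdir / "mirna_abundance.tsv"
            abundance.to_csv(ab_path, sep="\t", index_label="mirna")
            record(stage, ab_path)

        if config.de_table:
            stage = "volcano"
            de = pio.read_de_table(config.de_table)
            annotated = pmirna.classify_volcano_table(de, config.p_thresh, config.lfc_thresh)
            volcano_path = outdir / "volcano.tsv"
            annotated.to_csv(volcano_path, sep="\t", index=False)
            record(stage, volcano_path)

            if config.target_predictions:
                stage = "target_consensus"
                down = ptargets.downregulated_genes(de, config.p_thresh, config.lfc_thresh)
                preds = [
                    ptargets.read_target_predictions(path, source=source)
                    for source, path in sorted(config.target_predictions.items())
                ]
                result = ptargets.consensus(down, preds)
                cons_path = outdir / "consensus.json"
                cons_path.write_text(
                    json.dumps(
                        {
                            "per_source": {s: sorted(g) for s, g in result.per_source.items()},
                            "consensus": sorted(result.consensus),
                            "union": sorted(result.union),
                            "counts": result.counts,
                        },
                        indent=2,
                    )
                    + "\n",
                    encoding="utf-8",
                )
                record(stage, cons_path)
    except PasmatchError as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        for p in written:
            manifest["outputs"][p.name] = f"stale:{manifest['outputs'][p.name]}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
        raise PasmatchError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
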