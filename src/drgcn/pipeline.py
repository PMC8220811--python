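"""End-to-end pipeline: label -> diffuse -> features -> cross-validate.

Each stage writes its artifacts plus a JSON manifest (stage seed, input
hashes, output hashes) so a rerun with the same config is verifiably
identical.  A single user-facing seed fans out to per-stage seeds through a
stable hash of the stage name, keeping stages independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import features as feat
from . import network as net
from .errors import ConfigurationError
from .evaluate import CVResult, cross_validate, export_results
from .nn import CNNConfig

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    network_path: str
    gene_cancer_path: str
    expression_path: str
    clinical_path: str
    outdir: str
    n_layers: int = 2
    norm_mode: str = "in"
    activation: str = "identity"
    retention_fraction: float = 0.70
    log2_expression: bool = False
    folds: int = 10
    seed: int = 0
    cnn: CNNConfig = field(default_factory=CNNConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cnn_raw = raw.pop("cnn", None)
        cfg = cls(**raw)
        if cnn_raw:
            cfg.cnn = CNNConfig.from_dict(cnn_raw)
        return cfg

    def validate(self) -> None:
        for name in ("network_path", "gene_cancer_path", "expression_path",
                     "clinical_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigurationError(f"{name} does not exist: {p}")


def _digest(value: Path | str) -> str:
    # precomputed digests pass through; paths are hashed by content
    return value if isinstance(value, str) else _file_sha256(Path(value))


def _write_manifest(outdir: Path, stage: str, seed: int,
                    inputs: dict[str, Path | str],
                    outputs: dict[str, Path | str]) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": {k: _digest(v) for k, v in inputs.items()},
        "outputs": {k: _digest(v) for k, v in outputs.items()},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> CVResult:
    """Execute labeling, diffusion, feature building and cross-validation.

    Stage order and artifacts:

    1. ``label``   -- clinical table -> labeled cohort + exclusion report;
    2. ``diffuse`` -- network + gene-cancer matrix -> diffused weights
       (label-free, so running it before the CV split leaks nothing);
    3. ``features`` -- expression x weights -> (m, 1, G, K) tensor restricted
       to labeled cases;
    4. ``evaluate`` -- k-fold CV of the CNN, metrics and curves exported.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- label ---------------------------------------------------------
    records = clin.parse_clinical_table(config.clinical_path)
    cohort = clin.label_cohort(records, config.retention_fraction)
    labels_path = outdir / "labels.tsv"
    report_path = outdir / "exclusions.tsv"
    clin.write_labeled_cohort(cohort, labels_path)
    clin.write_exclusion_report(cohort, report_path)
    _write_manifest(
        outdir, "label", stage_seed(config.seed, "label"),
        {"clinical": Path(config.clinical_path)},
        {"labels": labels_path, "exclusions": report_path},
    )
    logger.info("labeled %d cases, excluded %d", len(cohort.entries), len(cohort.excluded))

    # --- diffuse -------------------------------------------------------
    network = net.read_edge_list(config.network_path)
    gene_cancer = net.read_gene_cancer(config.gene_cancer_path)
    expr = feat.read_expression(config.expression_path)
    genes = feat.intersect_genes(expr.genes, network.genes, gene_cancer.genes)
    gc_index = {g: i for i, g in enumerate(gene_cancer.genes)}
    net_index = {g: i for i, g in enumerate(network.genes)}
    rows = [net_index[g] for g in genes]
    sub_network = net.RegulationNetwork(
        genes, network.adjacency[np.ix_(rows, rows)], network.directed
    )
    sub_gc = net.GeneCancerWeights(
        genes, gene_cancer.cancers,
        gene_cancer.values[[gc_index[g] for g in genes]],
    )
    prop = net.PropagationConfig(
        n_layers=config.n_layers,
        activation=config.activation,  # type: ignore[arg-type]
        norm_mode=config.norm_mode,  # type: ignore[arg-type]
    )
    diffused = net.extract_weights(sub_network, sub_gc, prop)
    weights_path = outdir / "weights.tsv"
    net.write_gene_cancer(diffused, weights_path)
    _write_manifest(
        outdir, "diffuse", stage_seed(config.seed, "diffuse"),
        {"network": Path(config.network_path),
         "gene_cancer": Path(config.gene_cancer_path)},
        {"weights": weights_path},
    )

    # --- features ------------------------------------------------------
    labeled_ids = [e.case_id for e in cohort.entries if e.case_id in set(expr.samples)]
    if not labeled_ids:
        raise ConfigurationError(
            "no labeled case has an expression column; check case ids"
        )
    expr_sub = expr.subset_genes(genes).subset_samples(labeled_ids)
    if config.log2_expression:
        expr_sub = expr_sub.log2_transformed()
    tensor = feat.weight_expression(expr_sub, diffused)
    tensor_path = outdir / "features.npz"
    tensor.save(tensor_path)
    # hash the tensor content, not the container (zip timestamps vary)
    tensor_digest = hashlib.sha256(
        tensor.values.tobytes()
        + "\x00".join(tensor.sample_ids + tensor.gene_ids + tensor.cancer_ids).encode()
    ).hexdigest()
    _write_manifest(
        outdir, "features", stage_seed(config.seed, "features"),
        {"expression": Path(config.expression_path), "weights": weights_path},
        {"features": tensor_digest},
    )

    # --- evaluate ------------------------------------------------------
    label_of = {e.case_id: e.label for e in cohort.entries}
    y = np.array([label_of[c] for c in labeled_ids])
    result = cross_validate(
        tensor, y, config.cnn, k=config.folds,
        seed=stage_seed(config.seed, "evaluate"),
    )
    export_results(result, outdir / "results")
    _write_manifest(
        outdir, "evaluate", stage_seed(config.seed, "evaluate"),
        {"features": tensor_digest, "labels": labels_path},
        {"metrics": outdir / "results" / "metrics.tsv"},
    )
    logger.info(
        "CV complete: mean AUROC %.4f, mean AUPRC %.4f",
        result.mean_auroc, result.mean_auprc,
    )
    return result
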