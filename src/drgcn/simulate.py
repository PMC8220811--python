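"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the four real inputs -- a directed regulation
network, a sparse binary gene-cancer association matrix, an FPKM-like
expression cohort with a metastasis-dependent shift, and a TCGA-CDR-style
clinical table -- so every stage and the end-to-end run are testable without
downloads.

Expression is log-normal (baseline log-expression ~ Normal(mu=1, noise_sd),
mimicking FPKM skew).  Each cancer type has ``n_assoc_per_cancer`` seed
genes (its associated genes, the 1-entries of the gene-cancer matrix).  The
*informative* genes -- those whose log-expression metastasis samples shift
upward by the effect size delta -- are either the seed genes themselves
(``signal_routing="seed_genes"``) or the seeds' regulators, i.e. their
in-neighbors in the network excluding the seeds (``"neighbors_only"``).
The second routing separates raw from diffused weighting: the propagation
rule spreads weight from a seed to its regulators, so diffused weights cover
the informative genes while the raw association matrix gives them weight
zero.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateNetworkError, InvalidInputError
from .features import ExpressionMatrix
from .network import GeneCancerWeights, RegulationNetwork

NetworkModel = Literal["erdos_renyi", "preferential_attachment"]
SignalRouting = Literal["seed_genes", "neighbors_only"]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Defaults are sized to run the full pipeline end-to-end in minutes on one
    CPU while leaving a clearly learnable planted signal: 500 genes, 3
    cancer types of 100 samples each, 40% metastasis prevalence, mean
    out-degree 5, 10 seed genes per cancer, a +1.0 log-scale shift against
    noise SD 0.5.
    """

    n_genes: int = 500
    n_cancers: int = 3
    n_samples_per_cancer: int = 100
    metastasis_fraction: float = 0.4
    network_model: NetworkModel = "erdos_renyi"
    mean_out_degree: float | None = 5.0
    edge_density: float | None = None
    n_assoc_per_cancer: int = 10
    effect_size: float = 1.0  # delta: log-scale mean shift in metastasis samples
    noise_sd: float = 0.5
    signal_routing: SignalRouting = "seed_genes"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cancers", "n_samples_per_cancer"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not (0.0 < self.metastasis_fraction < 1.0):
            raise InvalidInputError("metastasis_fraction must be in (0, 1)")
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        if self.n_assoc_per_cancer < 0 or self.n_assoc_per_cancer > self.n_genes:
            raise InvalidInputError("n_assoc_per_cancer out of range")
        if self.network_model not in ("erdos_renyi", "preferential_attachment"):
            raise InvalidInputError(f"unknown network model {self.network_model!r}")
        if self.signal_routing not in ("seed_genes", "neighbors_only"):
            raise InvalidInputError(f"unknown signal routing {self.signal_routing!r}")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    @property
    def cancer_ids(self) -> list[str]:
        return [f"CANCER_{k}" for k in range(1, self.n_cancers + 1)]


def _edge_probability(spec: SyntheticSpec) -> float:
    if spec.edge_density is not None:
        p = float(spec.edge_density)
    elif spec.mean_out_degree is not None:
        p = float(spec.mean_out_degree) / max(spec.n_genes - 1, 1)
    else:
        raise InvalidInputError("either mean_out_degree or edge_density is required")
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(
            f"implied edge probability {p:.4f} outside [0, 1]; "
            "density would exceed G(G-1) edges"
        )
    return p


def gen_network(spec: SyntheticSpec) -> RegulationNetwork:
    """Directed random network on the spec's gene list; no raw self-loops."""
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    if spec.network_model == "erdos_renyi":
        p = _edge_probability(spec)
        adj = (rng.random((G, G)) < p).astype(np.uint8)
        np.fill_diagonal(adj, 0)
    else:
        graph = nx.scale_free_graph(G, seed=int(rng.integers(2**31)))
        adj = np.zeros((G, G), dtype=np.uint8)
        for u, v in graph.edges():
            if u != v:
                adj[u, v] = 1
    return RegulationNetwork(spec.gene_ids, adj)


def gen_gene_cancer(spec: SyntheticSpec, network: RegulationNetwork) -> GeneCancerWeights:
    """Binary G x K association matrix: per cancer, n_assoc distinct seed genes."""
    if network.genes != spec.gene_ids:
        raise InvalidInputError("network gene list does not match the spec")
    rng = np.random.default_rng(spec.seed + 1)
    values = np.zeros((spec.n_genes, spec.n_cancers), dtype=np.float64)
    for k in range(spec.n_cancers):
        seeds = rng.choice(spec.n_genes, size=spec.n_assoc_per_cancer, replace=False)
        values[seeds, k] = 1.0
    return GeneCancerWeights(spec.gene_ids, spec.cancer_ids, values)


def informative_gene_sets(
    spec: SyntheticSpec,
    network: RegulationNetwork,
    gene_cancer: GeneCancerWeights,
) -> list[np.ndarray]:
    """Per-cancer index arrays of the genes carrying the planted signal."""
    sets: list[np.ndarray] = []
    adj = network.adjacency
    all_seeds = np.flatnonzero(gene_cancer.values.sum(axis=1) > 0)
    for k in range(spec.n_cancers):
        seeds = np.flatnonzero(gene_cancer.values[:, k] == 1)
        if spec.signal_routing == "seed_genes":
            sets.append(seeds)
            continue
        # regulators of the seeds: genes with an edge into any seed gene;
        # every seed gene (any cancer) is excluded so the informative set
        # carries zero weight in the raw association matrix
        regulators = np.flatnonzero(adj[:, seeds].sum(axis=1) > 0)
        regulators = np.setdiff1d(regulators, all_seeds)
        if regulators.size == 0:
            raise DegenerateNetworkError(
                f"cancer {gene_cancer.cancers[k]!r}: no seed gene has a regulator; "
                "neighbors_only routing is impossible on this network"
            )
        sets.append(regulators)
    return sets


def gen_expression_cohort(
    spec: SyntheticSpec,
    network: RegulationNetwork,
    gene_cancer: GeneCancerWeights,
) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    """Expression matrix, binary metastasis labels and cancer assignment.

    Baseline log-expression is i.i.d. Normal(1, noise_sd); metastasis
    samples of cancer k have the informative genes of k shifted by
    +effect_size on the log scale.  Values are exponentiated, hence
    log-normal and strictly positive.
    """
    info_sets = informative_gene_sets(spec, network, gene_cancer)
    rng = np.random.default_rng(spec.seed + 2)
    n_per = spec.n_samples_per_cancer
    m = n_per * spec.n_cancers
    log_expr = rng.normal(1.0, spec.noise_sd, size=(spec.n_genes, m))
    labels = np.zeros(m, dtype=np.int64)
    cancer_assignment: list[str] = []
    sample_ids: list[str] = []
    width = len(str(m))
    for k in range(spec.n_cancers):
        start = k * n_per
        n_met = int(round(spec.metastasis_fraction * n_per))
        met_cols = np.arange(start, start + n_met)
        labels[met_cols] = 1
        if spec.effect_size > 0 and met_cols.size:
            log_expr[np.ix_(info_sets[k], met_cols)] += spec.effect_size
        cancer_assignment.extend([spec.cancer_ids[k]] * n_per)
        sample_ids.extend(
            f"S{idx + 1:0{width}d}" for idx in range(start, start + n_per)
        )
    expr = ExpressionMatrix(spec.gene_ids, sample_ids, np.exp(log_expr))
    return expr, labels, cancer_assignment


def gen_cohort_clinical(
    sample_ids: list[str],
    labels: np.ndarray,
    cancer_assignment: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical table consistent with the cohort's labels.

    Metastasis samples get an uninformative tumor_status with a Metastasis
    new-tumor event (positive rule r2); non-metastasis samples are TUMOR
    FREE with no event.  PFI times are uniform on [30, 3000] days.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for case_id, label, cancer in zip(sample_ids, labels, cancer_assignment):
        pfi = float(np.round(rng.uniform(30, 3000), 1))
        if label == 1:
            rows.append((case_id, cancer, "[Not Available]", "Metastasis", "Lung", pfi))
        else:
            rows.append((case_id, cancer, "TUMOR FREE", "NA", "NA", pfi))
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "cancer_type", "tumor_status",
            "new_tumor_event_type", "new_tumor_event_site", "PFI.time",
        ],
    )


#: The eight labeling branches exercised by the clinical fixture, with the
#: expected outcome of labeling + retention for each.
CLINICAL_BRANCHES = (
    ("r1_status_vocab", "METASTASIS", "NA", "NA", "label_1"),
    ("r2_event_metastasis", "[Not Available]", "Metastasis", "NA", "label_1"),
    ("r3_site_only", "NOT CLEAR", "NA", "Liver", "label_1"),
    ("neg_tumor_free", "TUMOR FREE", "NA", "NA", "label_0"),
    ("excl_not_clear", "NOT CLEAR", "NA", "NA", "excluded:unclear_tumor_status"),
    ("excl_status_na", "NA", "NA", "NA", "excluded:unclear_tumor_status"),
    ("excl_ambiguous", "WITH TUMOR", "Recurrence", "NA",
     "excluded:ambiguous_non_metastasis"),
    ("neg_missing_pfi", "TUMOR FREE", "NA", "NA", "excluded:missing_pfi"),
)


def gen_clinical_table(
    n_per_branch: int = 1, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical fixture covering every labeling branch, plus ground truth.

    Returns ``(table, truth)`` where ``truth`` maps each case_id to the
    outcome expected from label assignment plus missing-PFI screening, i.e.
    retention with fraction 1.0 (``label_0`` / ``label_1`` /
    ``excluded:<reason>``).  The fractional PFI cut is exercised separately
    so that the truth column stays independent of the branch counts.  PFI
    times are uniform on [30, 3000] days; the ``neg_missing_pfi`` branch has
    no PFI and is dropped at the missing-PFI screen.
    """
    if n_per_branch < 1:
        raise InvalidInputError("n_per_branch must be >= 1")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for branch, status, event, site, outcome in CLINICAL_BRANCHES:
        for i in range(n_per_branch):
            case_id = f"{branch}_{i + 1}"
            pfi = (
                "NA"
                if branch == "neg_missing_pfi"
                else f"{rng.uniform(30, 3000):.1f}"
            )
            rows.append((case_id, "CANCER_1", status, event, site, pfi))
            truth_rows.append((case_id, outcome))
    table = pd.DataFrame(
        rows,
        columns=[
            "case_id", "cancer_type", "tumor_status",
            "new_tumor_event_type", "new_tumor_event_site", "PFI.time",
        ],
    )
    truth = pd.DataFrame(truth_rows, columns=["case_id", "expected"])
    return table, truth


def write_synthetic_dataset(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic dataset to a directory.

    Writes network.tsv, gene_cancer.tsv, expr.tsv, clinical.tsv, labels.tsv
    and ground-truth files under ``truth/``; returns the path map.
    """
    from .features import write_expression
    from .network import write_edge_list, write_gene_cancer

    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    network = gen_network(spec)
    gene_cancer = gen_gene_cancer(spec, network)
    expr, labels, cancers = gen_expression_cohort(spec, network, gene_cancer)
    clinical = gen_cohort_clinical(expr.samples, labels, cancers, seed=spec.seed + 3)
    branch_table, branch_truth = gen_clinical_table(seed=spec.seed + 4)

    paths = {
        "network": outdir / "network.tsv",
        "gene_cancer": outdir / "gene_cancer.tsv",
        "expr": outdir / "expr.tsv",
        "clinical": outdir / "clinical.tsv",
        "labels": outdir / "truth" / "labels.tsv",
        "branch_clinical": outdir / "truth" / "branch_clinical.tsv",
        "branch_truth": outdir / "truth" / "branch_truth.tsv",
    }
    write_edge_list(network, paths["network"])
    write_gene_cancer(gene_cancer, paths["gene_cancer"])
    write_expression(expr, paths["expr"])
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    pd.DataFrame(
        {"case_id": expr.samples, "label": labels, "cancer_type": cancers}
    ).to_csv(paths["labels"], sep="\t", index=False)
    branch_table.to_csv(paths["branch_clinical"], sep="\t", index=False)
    branch_truth.to_csv(paths["branch_truth"], sep="\t", index=False)
    return paths
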