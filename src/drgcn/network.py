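"""Directed gene-regulation networks and random-walk feature diffusion.

A gene-regulation network is a directed graph on an ordered gene list: an
edge ``i -> j`` means gene *i* regulates gene *j*, recorded as a binary
adjacency matrix ``A`` with ``A[i, j] = 1``.  The diffusion operator used
throughout this package is the degree-normalized propagation

    H_{l+1} = sigma( D~^{-1} A~ H_l W_l )

where ``A~ = A + I`` (self-loop augmentation, saturating at 1), ``D~`` is a
diagonal degree operator built from ``A~``, and ``W_l`` defaults to the
identity (all genes weighted equally).  On directed graphs the degree used
for normalization is the in-degree by default, so that a node's aggregated
feature -- a sum over the genes it regulates -- is scaled by how strongly the
node itself is regulated.  Aggregation runs over rows of ``A~`` (a node pulls
features from its targets), hence an initial one-hot weight spreads to the
*regulators* of the hot gene, one reverse-edge hop per layer.

For raw, non-augmented networks a node can have degree zero; the degree
operator then falls back to ``-1/|E|`` on that node so the diagonal stays
full rank.  After augmentation every degree is at least 1 and the fallback is
unreachable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateNetworkError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

NormMode = Literal["in", "out"]
Activation = Literal["identity", "relu"]


def _check_binary_square(adjacency: np.ndarray) -> np.ndarray:
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise InvalidInputError(
            f"adjacency must be square, got shape {adjacency.shape}"
        )
    bad = np.argwhere((adjacency != 0) & (adjacency != 1))
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"adjacency must be binary; entry ({i}, {j}) = {adjacency[i, j]!r}"
        )
    return adjacency.astype(np.uint8)


@dataclass
class RegulationNetwork:
    """Directed binary regulation network over an ordered gene list.

    ``adjacency[i, j] = 1`` means ``genes[i]`` regulates ``genes[j]``.
    """

    genes: list[str]
    adjacency: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))
            raise InvalidInputError(f"duplicate gene identifier {dup!r}")
        self.adjacency = _check_binary_square(self.adjacency)
        if self.adjacency.shape[0] != len(self.genes):
            raise InvalidInputError(
                f"adjacency is {self.adjacency.shape[0]}x{self.adjacency.shape[1]} "
                f"but gene list has length {len(self.genes)}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def has_all_self_loops(self) -> bool:
        return bool(np.all(np.diag(self.adjacency) == 1))

    def edge_list(self) -> list[tuple[str, str]]:
        src, dst = np.nonzero(self.adjacency)
        return [(self.genes[i], self.genes[j]) for i, j in zip(src, dst)]


@dataclass
class DegreeOperator:
    """Diagonal normalization operator ``D~^{-1}`` with a full-rank guarantee."""

    diag_values: np.ndarray
    mode: NormMode
    built_on_selfloops: bool

    def __post_init__(self) -> None:
        self.diag_values = np.asarray(self.diag_values, dtype=np.float64)
        if np.any(self.diag_values == 0.0):
            raise InvalidInputError("degree operator has a zero diagonal entry")


@dataclass
class PropagationConfig:
    """Settings for L-layer diffusion of gene features.

    ``layer_weights`` are optional K-by-K per-layer mixing matrices; the
    default (None) is the identity on every layer, i.e. all genes/cancer
    columns weighted equally.
    """

    n_layers: int = 2
    activation: Activation = "identity"
    norm_mode: NormMode = "in"
    layer_weights: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise InvalidInputError(f"n_layers must be >= 0, got {self.n_layers}")
        if self.activation not in ("identity", "relu"):
            raise InvalidInputError(f"unknown activation {self.activation!r}")
        if self.norm_mode not in ("in", "out"):
            raise InvalidInputError(f"unknown norm_mode {self.norm_mode!r}")
        if self.layer_weights is not None and len(self.layer_weights) != self.n_layers:
            raise InvalidInputError(
                f"layer_weights has {len(self.layer_weights)} entries "
                f"but n_layers = {self.n_layers}"
            )


@dataclass
class GeneCancerWeights:
    """G x K gene-by-cancer weight matrix aligned to an ordered gene list.

    Holds both the initial binary association matrix H0 (``w[g, k] = 1`` means
    gene g is associated with cancer type k) and, after diffusion, the real-
    valued diffused weights W-hat.
    """

    genes: list[str]
    cancers: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cancers = [str(c) for c in self.cancers]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.cancers)):
            raise InvalidInputError(
                f"weight matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cancers)} cancers"
            )


def add_self_loops(network: RegulationNetwork) -> RegulationNetwork:
    """Return the self-loop-augmented network ``A~ = max(A, I)``.

    Augmentation saturates: a pre-existing self-loop stays 1, preserving the
    binary invariant.  Off-diagonal entries are unchanged.
    """
    aug = np.maximum(network.adjacency, np.eye(network.n_genes, dtype=np.uint8))
    return RegulationNetwork(list(network.genes), aug, directed=network.directed)


def build_degree_operator(
    network: RegulationNetwork,
    mode: NormMode = "in",
    *,
    allow_raw: bool = False,
    global_norm: bool = False,
) -> DegreeOperator:
    """Build the diagonal normalization operator from a network's degrees.

    Each diagonal entry is ``1 / deg(i)`` where ``deg`` is the in-degree
    (``mode="in"``, the default) or out-degree (``mode="out"``) counted on the
    network's adjacency, self-loops included.  On an augmented network every
    degree is >= 1 so all entries are positive.  With ``allow_raw`` the
    operator may be built on a non-augmented network: a zero-degree node then
    receives the signed fallback ``-1/|E|`` (|E| = total edge count), which
    keeps the diagonal full rank.  ``global_norm`` replaces the per-node
    reciprocal by ``1 / sum(deg)`` (a sensitivity-analysis variant).
    """
    if mode not in ("in", "out"):
        raise InvalidInputError(f"unknown degree mode {mode!r}")
    if not allow_raw and not network.has_all_self_loops:
        raise InvalidInputError(
            "network lacks self-loops; call add_self_loops first or pass allow_raw=True"
        )
    adj = network.adjacency
    deg = adj.sum(axis=0) if mode == "in" else adj.sum(axis=1)
    deg = deg.astype(np.float64)
    n_edges = int(adj.sum())
    pos = deg > 0
    if not np.all(pos) and n_edges == 0:
        raise DegenerateNetworkError(
            "network has no edges at all; degree operator undefined"
        )
    diag = np.empty(network.n_genes, dtype=np.float64)
    if global_norm:
        diag[pos] = 1.0 / deg.sum()
    else:
        diag[pos] = 1.0 / deg[pos]
    diag[~pos] = -1.0 / n_edges if n_edges else 0.0
    return DegreeOperator(
        diag_values=diag, mode=mode, built_on_selfloops=network.has_all_self_loops
    )


def _apply_activation(x: np.ndarray, activation: Activation) -> np.ndarray:
    if activation == "identity":
        return x
    if activation == "relu":
        return np.maximum(x, 0.0)
    raise InvalidInputError(f"unknown activation {activation!r}")


def propagate_layer(
    features: np.ndarray,
    network: RegulationNetwork,
    degree: DegreeOperator,
    activation: Activation = "identity",
    layer_weight: np.ndarray | None = None,
) -> np.ndarray:
    """One diffusion layer: ``sigma(D~^{-1} A~ H W)``.

    Row ``i`` of the output is the degree-scaled sum of the feature rows of
    the genes that ``i`` regulates (its out-neighbors, self included after
    augmentation).
    """
    features = np.asarray(features, dtype=np.float64)
    G = network.n_genes
    if features.ndim != 2 or features.shape[0] != G:
        raise InvalidInputError(
            f"feature matrix must be ({G}, K); got shape {features.shape}"
        )
    if degree.diag_values.shape[0] != G:
        raise InvalidInputError(
            f"degree operator has {degree.diag_values.shape[0]} entries, expected {G}"
        )
    out = degree.diag_values[:, None] * (network.adjacency.astype(np.float64) @ features)
    if layer_weight is not None:
        layer_weight = np.asarray(layer_weight, dtype=np.float64)
        K = features.shape[1]
        if layer_weight.shape != (K, K):
            raise InvalidInputError(
                f"layer weight must be ({K}, {K}); got {layer_weight.shape}"
            )
        out = out @ layer_weight
    return _apply_activation(out, activation)


def extract_weights(
    network: RegulationNetwork,
    initial: GeneCancerWeights | np.ndarray,
    config: PropagationConfig | None = None,
) -> GeneCancerWeights | np.ndarray:
    """Diffuse initial gene-cancer weights over the network for L layers.

    Augments the network with self-loops, builds the degree operator, then
    applies the propagation rule ``config.n_layers`` times.  With zero layers
    the initial weights are returned unchanged.  If ``initial`` is a
    :class:`GeneCancerWeights`, its gene ordering must match the network's
    exactly, and a :class:`GeneCancerWeights` is returned; a bare array input
    yields a bare array.
    """
    if config is None:
        config = PropagationConfig()
    if isinstance(initial, GeneCancerWeights):
        if initial.genes != network.genes:
            mism = next(
                (i for i, (a, b) in enumerate(zip(network.genes, initial.genes)) if a != b),
                min(len(network.genes), len(initial.genes)),
            )
            net_g = network.genes[mism] if mism < len(network.genes) else "<missing>"
            w_g = initial.genes[mism] if mism < len(initial.genes) else "<missing>"
            raise AlignmentError(
                f"gene order mismatch at position {mism}: network has {net_g!r}, "
                f"weights have {w_g!r}"
            )
        values = initial.values
    else:
        values = np.asarray(initial, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != network.n_genes:
        raise InvalidInputError(
            f"initial weights must be ({network.n_genes}, K); got shape {values.shape}"
        )

    h = values.astype(np.float64)
    if config.n_layers > 0:
        aug = add_self_loops(network)
        degree = build_degree_operator(aug, mode=config.norm_mode)
        for layer in range(config.n_layers):
            w_l = config.layer_weights[layer] if config.layer_weights else None
            h = propagate_layer(h, aug, degree, config.activation, w_l)
    if isinstance(initial, GeneCancerWeights):
        return GeneCancerWeights(list(initial.genes), list(initial.cancers), h)
    return h


# ---------------------------------------------------------------------------
# IO: edge lists and gene-cancer matrices (plain TSV)
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"source", "target", "source_gene", "target_gene", "from", "to"}


def read_edge_list(path: str | Path, genes: Sequence[str] | None = None) -> RegulationNetwork:
    """Read a directed network from a 2-column TSV (source_gene, target_gene).

    A header row is optional and detected by name; lines starting with ``#``
    are skipped; duplicate edges are collapsed with a warning.  The gene
    universe defaults to the sorted union of all endpoint identifiers unless
    an explicit ordered ``genes`` list is given.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected 2 tab-separated columns")
    df = df.iloc[:, :2]
    if df.iloc[0].str.lower().isin(_HEADER_TOKENS).all():
        df = df.iloc[1:]
    edges = list(df.itertuples(index=False, name=None))
    if len(set(edges)) != len(edges):
        logger.warning(
            "%s: %d duplicate edges collapsed", path, len(edges) - len(set(edges))
        )
        edges = list(dict.fromkeys(edges))
    if genes is None:
        genes = sorted({g for e in edges for g in e})
    index = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)), dtype=np.uint8)
    for s, t in edges:
        if s not in index or t not in index:
            raise AlignmentError(f"edge ({s!r}, {t!r}) references a gene not in the gene list")
        adj[index[s], index[t]] = 1
    return RegulationNetwork(list(genes), adj)


def write_edge_list(network: RegulationNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_gene\ttarget_gene\n")
        for s, t in network.edge_list():
            fh.write(f"{s}\t{t}\n")


def read_gene_cancer(path: str | Path, binary: bool = True) -> GeneCancerWeights:
    """Read a gene-cancer weight TSV: first column gene id, remaining columns
    one per cancer type.  With ``binary=True`` (associations, H0) entries
    must be 0/1; ``binary=False`` accepts real diffused weights."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected a gene column plus >=1 cancer column")
    genes = df.iloc[:, 0].astype(str).tolist()
    cancers = list(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    bad = np.argwhere((values != 0) & (values != 1)) if binary else np.empty((0,))
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"{path}: gene-cancer entries must be 0/1; row {genes[i]!r} "
            f"column {cancers[j]!r} = {values[i, j]}"
        )
    return GeneCancerWeights(genes, cancers, values)


def write_gene_cancer(weights: GeneCancerWeights, path: str | Path) -> None:
    df = pd.DataFrame(weights.values, columns=weights.cancers)
    df.insert(0, "gene", weights.genes)
    df.to_csv(path, sep="\t", index=False)
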