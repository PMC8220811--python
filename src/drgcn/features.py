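"""Expression loading, gene-list alignment and feature-tensor construction.

The classifier input is a rank-4 tensor shaped ``(m, 1, G, K)``: for each of
the *m* samples, a single-channel G-by-K "image" whose entry ``(g, k)`` is
the sample's expression of gene *g* multiplied by the (diffused) weight of
gene *g* for cancer type *k*.  The product is a per-gene broadcast -- each
sample's expression vector is replicated across the K weight columns -- which
is the only product consistent with that output shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidInputError
from .network import GeneCancerWeights

__all__ = [
    "ExpressionMatrix",
    "SampleFeatureTensor",
    "read_expression",
    "intersect_genes",
    "weight_expression",
]


@dataclass
class ExpressionMatrix:
    """Genes-by-samples matrix of nonnegative FPKM-like values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # (G, m)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise InvalidInputError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise InvalidInputError("duplicate gene identifiers in expression matrix")
        if np.isnan(self.values).any():
            g, s = np.argwhere(np.isnan(self.values))[0]
            raise InvalidInputError(
                f"missing expression value for gene {self.genes[g]!r}, "
                f"sample {self.samples[s]!r} (imputation is not performed)"
            )
        if (self.values < 0).any():
            raise InvalidInputError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Reorder/restrict rows to the given ordered gene list."""
        index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} requested genes absent from expression matrix, "
                f"first: {missing[0]!r}"
            )
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.samples), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} requested samples absent from expression matrix, "
                f"first: {missing[0]!r}"
            )
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.genes), list(samples), self.values[:, cols])

    def log2_transformed(self) -> "ExpressionMatrix":
        """Return log2(x + 1)-transformed copy (optional preprocessing)."""
        return ExpressionMatrix(
            list(self.genes), list(self.samples), np.log2(self.values + 1.0)
        )


@dataclass
class SampleFeatureTensor:
    """Rank-4 classifier input ``(m, 1, G, K)`` with aligned id lists."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    cancer_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (
            len(self.sample_ids), 1, len(self.gene_ids), len(self.cancer_ids),
        )
        if self.values.shape != expected:
            raise InvalidInputError(
                f"tensor shape {self.values.shape} does not match id lists {expected}"
            )
        if not np.isfinite(self.values).all():
            raise InvalidInputError("feature tensor contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def save(self, path: str | Path) -> None:
        """Write to an .npz container with id lists embedded."""
        np.savez_compressed(
            path,
            values=self.values,
            sample_ids=np.array(self.sample_ids, dtype=object),
            gene_ids=np.array(self.gene_ids, dtype=object),
            cancer_ids=np.array(self.cancer_ids, dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SampleFeatureTensor":
        with np.load(path, allow_pickle=True) as data:
            return cls(
                values=data["values"],
                sample_ids=[str(s) for s in data["sample_ids"]],
                gene_ids=[str(g) for g in data["gene_ids"]],
                cancer_ids=[str(c) for c in data["cancer_ids"]],
            )


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-by-samples TSV: first column gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected a gene column plus >=1 sample column")
    genes = df.iloc[:, 0].astype(str).tolist()
    samples = list(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return ExpressionMatrix(genes, samples, values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.samples)
    df.insert(0, "gene", expr.genes)
    df.to_csv(path, sep="\t", index=False)


def intersect_genes(
    expr_genes: Sequence[str],
    network_genes: Sequence[str],
    gc_genes: Sequence[str],
) -> list[str]:
    """Sorted intersection of the three gene universes.

    The lexicographic order is the canonical alignment used by every
    downstream matrix.  An empty intersection raises an error reporting the
    pairwise overlap counts, which usually pinpoints the offending input.
    """
    e, n, g = set(expr_genes), set(network_genes), set(gc_genes)
    if not (e and n and g):
        raise InvalidInputError("all three gene lists must be nonempty")
    common = e & n & g
    if not common:
        raise InvalidInputError(
            "empty three-way gene intersection "
            f"(expr∩network={len(e & n)}, expr∩gene-cancer={len(e & g)}, "
            f"network∩gene-cancer={len(n & g)}); check identifier conventions"
        )
    return sorted(common)


def weight_expression(
    expr: ExpressionMatrix, weights: GeneCancerWeights | np.ndarray
) -> SampleFeatureTensor:
    """Build the (m, 1, G, K) tensor: expression broadcast across weight columns.

    ``values[s, 0, g, k] = expr[g, s] * weights[g, k]``.  Gene lists must
    already be aligned (same genes, same order).
    """
    if isinstance(weights, GeneCancerWeights):
        if weights.genes != expr.genes:
            mism = next(
                (i for i, (a, b) in enumerate(zip(expr.genes, weights.genes)) if a != b),
                min(len(expr.genes), len(weights.genes)),
            )
            raise AlignmentError(
                f"gene order mismatch between expression and weights at position {mism}"
            )
        w = weights.values
        cancer_ids = list(weights.cancers)
    else:
        w = np.asarray(weights, dtype=np.float64)
        cancer_ids = [f"C{k}" for k in range(w.shape[1])]
    if w.shape[0] != expr.n_genes:
        raise AlignmentError(
            f"weights have {w.shape[0]} genes, expression has {expr.n_genes}"
        )
    # (m, G, K) = expr.T[:, :, None] * w[None, :, :], then add the channel axis
    tensor = expr.values.T[:, :, None] * w[None, :, :]
    return SampleFeatureTensor(
        values=tensor[:, None, :, :],
        sample_ids=list(expr.samples),
        gene_ids=list(expr.genes),
        cancer_ids=cancer_ids,
    )
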