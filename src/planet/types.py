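"""Core domain objects: regulatory networks and expression matrices.

A :class:`GRN` is a directed binary adjacency over named genes in which
every edge runs from a transcription factor (TF) to a target gene; a
:class:`ExpressionMatrix` is a cells x genes nonnegative matrix whose
column order matches a paired network.  Both validate their invariants
on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a configuration cannot produce a valid object."""


class AlignmentError(ValueError):
    """Raised when gene orders/universes of paired objects disagree."""


@dataclass
class GRN:
    """Directed gene regulatory network with TF roles.

    ``adjacency[i, j] == 1`` means gene ``i`` regulates gene ``j``.
    """

    genes: list[str]
    tf_mask: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.tf_mask = np.asarray(self.tf_mask, dtype=bool)
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValueError("duplicate gene names")
        if self.tf_mask.shape != (n,):
            raise ValueError("tf_mask length must equal gene count")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be n x n")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = self.adjacency.astype(np.int8)
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-regulatory edges are not allowed")
        bad = np.nonzero(self.adjacency.sum(axis=1) * (~self.tf_mask))[0]
        if bad.size:
            raise ValueError(
                f"edges must originate at TFs; offending genes: "
                f"{[self.genes[i] for i in bad[:5]]}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def candidate_mask(self) -> np.ndarray:
        """Boolean n x n mask of ordered pairs a regulatory edge may occupy.

        Candidates are TF-source, non-diagonal ordered pairs; everything
        the diffusion process, the loss and the metrics touch is
        restricted to this universe.
        """
        n = self.n_genes
        mask = np.repeat(self.tf_mask[:, None], n, axis=1)
        np.fill_diagonal(mask, False)
        return mask

    def edge_list(self) -> list[tuple[str, str]]:
        return [(self.genes[i], self.genes[j])
                for i, j in zip(*np.nonzero(self.adjacency))]


@dataclass
class ExpressionMatrix:
    """Cells x genes nonnegative expression values with gene names."""

    values: np.ndarray
    genes: list[str]
    cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.genes = list(self.genes)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        if self.values.shape[1] != len(self.genes):
            raise ValueError("column count must equal gene count")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if not self.cells:
            self.cells = [f"cell{i}" for i in range(self.values.shape[0])]
        elif len(self.cells) != self.values.shape[0]:
            raise ValueError("cell name count must equal row count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def reorder(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy with columns permuted to ``genes``."""
        if set(genes) != set(self.genes):
            raise AlignmentError("gene universes differ")
        idx = [self.genes.index(g) for g in genes]
        return ExpressionMatrix(self.values[:, idx], list(genes), list(self.cells))


def check_paired(grn: GRN, expr: ExpressionMatrix) -> None:
    if grn.genes != expr.genes:
        raise AlignmentError("GRN and expression gene orders differ")
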