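"""Typed containers for the four input data layers.

The analysis operates on two gene × cell-line matrices (CRISPR gene-effect
dependency scores and gene expression), a collection of named gene sets
(pathways), and a publication → gene annotation of a literature corpus.
Matrices are stored as pandas DataFrames with genes as the index and cell
lines as columns; missing dependency measurements are ``NaN`` and are always
distinguished from an observed 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DependencyMatrix",
    "ExpressionMatrix",
    "GeneSetCollection",
    "CorpusAnnotation",
    "FilterReport",
]


def _check_unique(labels, what: str) -> None:
    seen = set()
    for x in labels:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class DependencyMatrix:
    """Gene × cell-line matrix of CRISPR gene-effect (dependency) scores.

    Strongly negative entries mean the gene is essential in that cell line.
    ``data`` is a float DataFrame indexed by gene symbol with cell-line
    identifiers as columns; NaN marks a missing measurement.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene symbol")
        _check_unique(self.data.columns, "cell-line identifier")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def coverage(self) -> pd.Series:
        """Number of non-missing cell lines per gene."""
        return self.data.notna().sum(axis=1)

    def profile(self, gene: str) -> pd.Series:
        if gene not in self.data.index:
            raise KeyError(f"gene not found: {gene!r}")
        return self.data.loc[gene]

    def copy(self) -> "DependencyMatrix":
        return DependencyMatrix(self.data.copy(), self.provenance)


@dataclass
class ExpressionMatrix:
    """Gene × cell-line non-negative expression matrix.

    Used only to mask dependency entries where the gene is unexpressed;
    it never enters the correlation analysis itself.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene symbol")
        _check_unique(self.data.columns, "cell-line identifier")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named pathways mapped to (description, member genes).

    ``sets`` preserves insertion order; each member list is duplicate-free.
    """

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name!r}")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes within set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def add(self, name: str, description: str, genes: list[str]) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate pathway name: {name!r}")
        self.sets[name] = (description, list(genes))

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: self.sets[n] for n in names}, source_label=self.source_label
        )


@dataclass
class CorpusAnnotation:
    """Publication → gene-set annotation of a literature corpus."""

    memberships: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pub, genes in self.memberships.items():
            if not genes:
                raise ValueError(f"publication with empty gene set: {pub!r}")

    @property
    def n_publications(self) -> int:
        return len(self.memberships)

    def total_memberships(self) -> int:
        return sum(len(g) for g in self.memberships.values())


@dataclass
class FilterReport:
    """Record of what a quality filter removed or masked.

    ``n_pairs_masked`` counts gene × cell-line entries whose expression was
    at or below the zero tolerance (they are missing after the mask);
    ``fraction_pairs_masked`` is that count over all evaluated entries.
    ``genes_removed`` lists genes dropped by the coverage filter with the
    ``min_lines`` threshold used. ``notes`` records provenance such as
    genes/lines that could not be evaluated for lack of expression data.
    """

    n_pairs_masked: int = 0
    fraction_pairs_masked: float = 0.0
    genes_removed: list[str] = field(default_factory=list)
    min_lines: int | None = None
    notes: list[str] = field(default_factory=list)
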