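"""Literature co-publication index and per-gene publication statistics.

A strong dependency correlation between two genes is most interesting when
the pair has little published history. This module counts, for every
unordered gene pair, the number of publications whose annotated gene set
contains both genes, then normalizes the counts to a 0–100 index where 100
is the corpus-wide maximum co-occurrence. Pairs with a high |r| but an
index at or below a small cutoff are flagged as novel.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .containers import CorpusAnnotation

logger = logging.getLogger(__name__)

#: Publications annotating more genes than this are excluded from pair
#: counting: a review tagging hundreds of genes would otherwise contribute
#: O(genes²) co-occurrences and swamp the counts.
DEFAULT_MAX_GENES_PER_PUB = 500

#: Default novelty cutoff on the 0–100 index scale (inclusive).
DEFAULT_INDEX_CUTOFF = 5.0


def _pair_key(gene_a: str, gene_b: str) -> tuple[str, str]:
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


@dataclass
class CopublicationIndex:
    """Sparse unordered-pair co-occurrence counts with 0–100 normalization.

    ``counts`` holds only pairs that co-occur at least once; the index of
    any absent pair is 0. The normalized value for a pair is
    ``100 * count / max_count`` so that exactly the argmax pair(s) score
    100. The index is computed on demand rather than materialized — at
    genome scale there are ~2×10⁸ candidate pairs.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    max_count: int = 0

    def count(self, gene_a: str, gene_b: str) -> int:
        return self.counts.get(_pair_key(gene_a, gene_b), 0)

    def index(self, gene_a: str, gene_b: str) -> float:
        """Normalized co-publication index in [0, 100]."""
        if self.max_count == 0:
            return 0.0
        return 100.0 * self.count(gene_a, gene_b) / self.max_count

    def argmax_pairs(self) -> list[tuple[str, str]]:
        if self.max_count == 0:
            return []
        return sorted(p for p, c in self.counts.items() if c == self.max_count)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, c, 100.0 * c / self.max_count)
            for (a, b), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "count", "index"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_cooccurrences(
    corpus: CorpusAnnotation,
    max_genes_per_pub: int = DEFAULT_MAX_GENES_PER_PUB,
) -> CopublicationIndex:
    """Count per-pair co-occurrences across a corpus annotation.

    A publication contributes exactly 1 to every unordered pair of distinct
    genes in its annotation set, regardless of within-abstract mention
    frequency. Publications annotating more than ``max_genes_per_pub``
    genes are excluded with a warning.
    """
    if corpus.n_publications == 0:
        raise ValueError("corpus annotation is empty")
    counts: Counter[tuple[str, str]] = Counter()
    n_excluded = 0
    for pub, genes in corpus.memberships.items():
        if len(genes) > max_genes_per_pub:
            n_excluded += 1
            continue
        counts.update(combinations(sorted(genes), 2))
    if n_excluded:
        logger.warning(
            "%d publications annotating more than %d genes excluded from "
            "co-occurrence counting",
            n_excluded,
            max_genes_per_pub,
        )
    max_count = max(counts.values()) if counts else 0
    return CopublicationIndex(counts=dict(counts), max_count=max_count)


def copublication_index(
    ci: CopublicationIndex, gene_a: str, gene_b: str
) -> float:
    """Normalized 0–100 co-publication index for one pair."""
    return ci.index(gene_a, gene_b)


def novelty_flag(
    r_magnitude: float,
    copub_index: float,
    index_cutoff: float = DEFAULT_INDEX_CUTOFF,
) -> bool:
    """Whether a threshold-passing pair counts as a novel association.

    Pure predicate on the literature side: true iff ``copub_index`` is at
    or below ``index_cutoff`` (boundary inclusive). Callers apply it only
    to pairs that already passed the co-essentiality threshold, which is
    why the correlation magnitude travels alongside; the flag itself does
    not re-test it.
    """
    if not (0.0 <= copub_index <= 100.0):
        raise ValueError(f"copub_index must lie in [0, 100], got {copub_index}")
    del r_magnitude  # pre-gated upstream
    return copub_index <= index_cutoff


def gene_publication_counts(corpus: CorpusAnnotation) -> Counter:
    """Publications mentioning each gene (column sums of the incidence)."""
    if corpus.n_publications == 0:
        raise ValueError("corpus annotation is empty")
    counts: Counter[str] = Counter()
    for genes in corpus.memberships.values():
        counts.update(genes)
    return counts


def bin_publication_counts(
    counts: dict[str, int], bin_edges: list[int]
) -> pd.DataFrame:
    """Histogram of genes by publication count over half-open bins.

    Bins are ``[edge_i, edge_{i+1})`` with a final open-ended bin
    ``[edge_last, ∞)``; the bin totals conserve the number of genes.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    labels = [
        f"[{a},{b})" for a, b in zip(edges, edges[1:])
    ] + [f"[{edges[-1]},inf)"]
    totals = [0] * len(labels)
    for c in counts.values():
        if c < edges[0]:
            raise ValueError(f"count {c} below the first bin edge {edges[0]}")
        idx = len(edges) - 1
        for i, (a, b) in enumerate(zip(edges, edges[1:])):
            if a <= c < b:
                idx = i
                break
        totals[idx] += 1
    return pd.DataFrame({"bin": labels, "n_genes": totals})
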