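"""Synthetic inputs with planted ground truth for every pipeline stage.

The dependency generator is a linear latent-factor model: each factor is a
standard-normal vector over cell lines, and a gene's profile is the
loading-weighted sum of its factors plus independent Gaussian noise. Genes
sharing a factor are co-essential by construction, with expected pairwise
correlation λ²/(λ² + σ²) for a common loading λ and noise σ — a planted
truth that recovery tests can score against. Expression matrices with an
exact zero fraction exercise the unexpressed-gene mask; a power-law
publication corpus with a designated maximum pair exercises the 0–100
co-publication index; and a respiratory-chain-style fixture (four complexes
on one factor, one on another) exercises clustering and unique-association
detection end to end. All generators are reproducible bit-for-bit from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CorpusAnnotation,
    DependencyMatrix,
    ExpressionMatrix,
    GeneSetCollection,
)


@dataclass
class FactorSpec:
    """One latent factor and the genes loading on it."""

    factor_id: str
    genes: list[str]
    loading_mean: float = 1.0
    loading_spread: float = 0.0


@dataclass
class LatentFactorDesign:
    """Design of a latent-factor dependency simulation.

    Gene lists may overlap across factors; genes named in
    ``background_genes`` get pure noise profiles. ``declared_genes``
    optionally fixes the gene universe and its order; every declared gene
    must then appear in a factor or the background.
    """

    n_cell_lines: int
    factors: list[FactorSpec]
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    background_genes: list[str] = field(default_factory=list)
    declared_genes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for f in self.factors:
            if f.loading_spread < 0:
                raise ValueError("loading_spread must be non-negative")

    def gene_ids(self) -> list[str]:
        if self.declared_genes is not None:
            return list(self.declared_genes)
        seen: dict[str, None] = {}
        for f in self.factors:
            for g in f.genes:
                seen.setdefault(g)
        for g in self.background_genes:
            seen.setdefault(g)
        return list(seen)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    module_assignments: dict[str, list[str]] = field(default_factory=dict)
    pathway_factor_map: dict[str, str] = field(default_factory=dict)
    designated_max_pair: tuple[str, str] | None = None
    group_pathways: list[str] = field(default_factory=list)
    reference_pathways: list[str] = field(default_factory=list)


def simulate_dependency(
    design: LatentFactorDesign,
) -> tuple[DependencyMatrix, GroundTruth]:
    """Draw a dependency matrix from a latent-factor design."""
    genes = design.gene_ids()
    if not genes:
        raise ValueError("design names no genes")
    rng = np.random.default_rng(design.seed)
    n = design.n_cell_lines
    values = np.zeros((len(genes), n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    assignments: dict[str, list[str]] = {g: [] for g in genes}
    for spec in design.factors:
        factor = rng.standard_normal(n)
        loadings = rng.normal(
            spec.loading_mean, spec.loading_spread, size=len(spec.genes)
        )
        for g, lam in zip(spec.genes, loadings):
            if g not in gene_pos:
                raise ValueError(
                    f"factor {spec.factor_id!r} names undeclared gene {g!r}"
                )
            values[gene_pos[g]] += lam * factor
            assignments[g].append(spec.factor_id)
    for g in genes:
        if not assignments[g] and g not in set(design.background_genes):
            raise ValueError(f"gene {g!r} assigned to no factor and not background")
    values += rng.normal(0.0, design.noise_sd, size=values.shape)
    if design.missing_rate > 0:
        mask = rng.random(values.shape) < design.missing_rate
        values[mask] = np.nan
    frame = pd.DataFrame(
        values, index=genes, columns=[f"CL{j:04d}" for j in range(n)]
    )
    dep = DependencyMatrix(frame, provenance=f"latent-factor sim seed={design.seed}")
    return dep, GroundTruth(module_assignments=assignments)


def expected_within_factor_r(loading: float, noise_sd: float) -> float:
    """Expected Pearson r of two genes sharing one factor with equal loading."""
    lam2 = loading * loading
    return lam2 / (lam2 + noise_sd * noise_sd)


def simulate_expression(
    dep: DependencyMatrix, zero_fraction: float, seed: int = 0
) -> ExpressionMatrix:
    """Matched-shape expression matrix with an exact fraction of zeros.

    Exactly ``round(zero_fraction × entries)`` entries are zero, placed
    uniformly at random; the rest are log-normal.
    """
    if not (0.0 <= zero_fraction < 1.0):
        raise ValueError("zero_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = dep.shape
    size = shape[0] * shape[1]
    flat = rng.lognormal(mean=1.0, sigma=1.0, size=size)
    n_zero = round(zero_fraction * size)
    zero_at = rng.choice(size, size=n_zero, replace=False)
    flat[zero_at] = 0.0
    frame = pd.DataFrame(
        flat.reshape(shape), index=dep.gene_ids, columns=dep.cell_line_ids
    )
    return ExpressionMatrix(frame)


def simulate_corpus(
    genes: list[str],
    n_publications: int,
    popularity_exponent: float = 1.2,
    designated_max_pair: tuple[str, str] | None = None,
    seed: int = 0,
    mean_genes_per_pub: float = 2.0,
) -> CorpusAnnotation:
    """Power-law publication corpus, optionally with a designated top pair.

    Gene popularity follows a Zipf-style law (weight ∝ rank^−exponent over
    the given gene order), so a few genes dominate the corpus the way a
    handful of famous genes dominate the literature. Each publication
    annotates 1 + Poisson(mean − 1) genes sampled without replacement by
    popularity. When ``designated_max_pair`` is given, both genes are
    injected into as many publications as needed for the pair to attain
    the strict maximum co-occurrence count.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    if n_publications < 1:
        raise ValueError("need at least 1 publication")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, len(genes) + 1, dtype=float)
    weights = ranks**-popularity_exponent
    weights /= weights.sum()
    memberships: dict[str, set[str]] = {}
    for i in range(n_publications):
        size = 1 + rng.poisson(max(mean_genes_per_pub - 1.0, 0.0))
        size = min(size, len(genes))
        chosen = rng.choice(len(genes), size=size, replace=False, p=weights)
        memberships[f"PMID{i:07d}"] = {genes[j] for j in chosen}

    if designated_max_pair is not None:
        a, b = designated_max_pair
        if a == b or a not in genes or b not in genes:
            raise ValueError("designated_max_pair must be two distinct known genes")
        pub_ids = list(memberships)
        extra = 0
        while True:
            counts = _pair_counts(memberships)
            ab = counts.get((min(a, b), max(a, b)), 0)
            others = [c for p, c in counts.items() if p != (min(a, b), max(a, b))]
            if ab > (max(others) if others else 0):
                break
            # inject into the next publication not yet containing both
            target = next(
                (p for p in pub_ids if not {a, b} <= memberships[p]), None
            )
            if target is None:
                memberships[f"PMIDX{extra:05d}"] = {a, b}
                extra += 1
            else:
                memberships[target] |= {a, b}
                pub_ids.remove(target)
    return CorpusAnnotation(memberships)


def _pair_counts(memberships: dict[str, set[str]]) -> dict[tuple[str, str], int]:
    from collections import Counter
    from itertools import combinations

    counts: Counter[tuple[str, str]] = Counter()
    for gs in memberships.values():
        counts.update(combinations(sorted(gs), 2))
    return dict(counts)


def make_etc_fixture(
    seed: int = 0,
    n_cell_lines: int = 300,
    genes_per_set: int = 8,
    noise_sd: float = 0.5,
    loading_mean: float = 1.0,
    loading_spread: float = 0.2,
    missing_rate: float = 0.0,
) -> tuple[DependencyMatrix, GeneSetCollection, GroundTruth]:
    """Respiratory-chain-style fixture with a planted odd-one-out complex.

    Five "complex" gene sets: four load on factor F1 (they co-cluster, as
    super-complex-forming respiratory complexes do), one — the succinate
    dehydrogenase analog — loads on factor F2. The reference collection
    holds 3 pathways on F2 (the planted unique associations of the odd
    complex), 6 on F1, and 5 on independent factors. The returned
    collection contains both the complexes (names starting ``COMPLEX_``)
    and the reference pathways (``REF_``); ground truth records which is
    which and the factor behind each.
    """
    complexes = ["COMPLEX_I", "COMPLEX_II", "COMPLEX_III", "COMPLEX_IV", "COMPLEX_V"]
    refs_f2 = [f"REF_F2_{i}" for i in range(1, 4)]
    refs_f1 = [f"REF_F1_{i}" for i in range(1, 7)]
    refs_ind = [f"REF_IND_{i}" for i in range(1, 6)]

    def genes_for(prefix: str) -> list[str]:
        return [f"{prefix}_G{j}" for j in range(genes_per_set)]

    factor_of = {}
    for name in complexes:
        factor_of[name] = "F2" if name == "COMPLEX_II" else "F1"
    for name in refs_f2:
        factor_of[name] = "F2"
    for name in refs_f1:
        factor_of[name] = "F1"
    for i, name in enumerate(refs_ind):
        factor_of[name] = f"F{3 + i}"

    members = {name: genes_for(name) for name in factor_of}
    factor_genes: dict[str, list[str]] = {}
    for name, fid in factor_of.items():
        factor_genes.setdefault(fid, []).extend(members[name])
    design = LatentFactorDesign(
        n_cell_lines=n_cell_lines,
        factors=[
            FactorSpec(fid, genes, loading_mean, loading_spread)
            for fid, genes in factor_genes.items()
        ],
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    dep, truth = simulate_dependency(design)
    collection = GeneSetCollection(source_label=f"etc-fixture seed={seed}")
    for name in [*complexes, *refs_f2, *refs_f1, *refs_ind]:
        collection.add(name, f"synthetic set on {factor_of[name]}", members[name])
    truth.pathway_factor_map = factor_of
    truth.group_pathways = complexes
    truth.reference_pathways = [*refs_f2, *refs_f1, *refs_ind]
    return dep, collection, truth
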