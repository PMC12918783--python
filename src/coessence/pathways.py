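"""Pathway-level co-essentiality: PCA signatures linked by CCA.

Instead of interpreting ~2×10⁸ individual gene pairs, each pathway is
summarized by the leading principal components of its member genes'
dependency profiles (cell lines as observations, genes as variables).
Two pathways are then associated by the first canonical correlation
between their component-score blocks: the largest correlation achievable
between any linear combination of one pathway's components and any linear
combination of the other's, a single score in [0, 1] per pathway pair.
Downstream, the pathway × pathway score matrix feeds hierarchical
clustering and a unique-association report that asks which reference
pathways associate with exactly one member of a group (the analysis that
singles out succinate dehydrogenase among the respiratory complexes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import DependencyMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_MIN_GENES = 3
#: Cumulative variance at which component selection stops early.
VARIANCE_TARGET = 0.80
#: Relative singular-value cutoff below which a block direction is treated
#: as rank-deficient and truncated.
RANK_TOL = 1e-9


@dataclass
class PathwaySignature:
    """Principal-component summary of one pathway's dependency submatrix.

    ``component_scores`` is cell line × k with zero-mean, mutually
    orthogonal columns; ``variance_explained`` is the per-component share
    of the submatrix variance, non-increasing.
    """

    pathway_name: str
    component_scores: pd.DataFrame
    variance_explained: np.ndarray
    n_genes_used: int

    @property
    def k(self) -> int:
        return self.component_scores.shape[1]

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.component_scores.index)


@dataclass
class PathwayAssociationMatrix:
    """Symmetric pathway × pathway matrix of first canonical correlations."""

    pathway_names: list[str]
    scores: np.ndarray
    k_used: int
    skipped: dict[str, str] = field(default_factory=dict)
    overlap: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.pathway_names, columns=self.pathway_names
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)

    def score(self, a: str, b: str) -> float:
        ia = self.pathway_names.index(a)
        ib = self.pathway_names.index(b)
        return float(self.scores[ia, ib])


@dataclass
class UniqueAssociationReport:
    """Reference pathways associated with one group member and no other."""

    focal_member: str
    group_members: list[str]
    unique_pathways: list[tuple[str, float]]
    assoc_cutoff: float


@dataclass
class ClusterResult:
    """Agglomerative clustering of a pathway association matrix."""

    linkage: np.ndarray
    leaf_order: list[str]
    pathway_names: list[str]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.pathway_names)
        return str(tree).strip()

    def joins_last(self) -> str | None:
        """Name of the pathway merged as a singleton in the final merge.

        None when the last merge joins two multi-pathway clusters.
        """
        n = len(self.pathway_names)
        last = self.linkage[-1]
        for side in (int(last[0]), int(last[1])):
            if side < n:
                return self.pathway_names[side]
        return None


def pathway_signature(
    dep: DependencyMatrix,
    gene_set: list[str],
    k: int = DEFAULT_K,
    min_genes: int = DEFAULT_MIN_GENES,
    pathway_name: str = "",
    variance_target: float = VARIANCE_TARGET,
) -> PathwaySignature:
    """Leading principal components of a pathway's dependency submatrix.

    The submatrix (cell lines × member genes present in ``dep``) is
    centered per gene; missing entries are mean-imputed (zero after
    centering) so every cell line contributes. The number of components
    kept is ``min(k, #genes − 1, rank)``, reduced further to the fewest
    components reaching ``variance_target`` cumulative variance when that
    is smaller. Component signs are fixed so the largest-magnitude gene
    loading of each component is positive.
    """
    present = [g for g in gene_set if g in dep.data.index]
    if len(present) < min_genes:
        raise ValueError(
            f"pathway below min_genes: {len(present)} of {len(gene_set)} "
            f"member genes present (need {min_genes})"
        )
    sub = dep.data.loc[present].to_numpy().T  # cell lines × genes
    if np.isnan(sub).all():
        raise ValueError("pathway submatrix is entirely missing")
    col_means = np.nanmean(sub, axis=0)
    centered = np.where(np.isnan(sub), 0.0, sub - col_means)

    k_max = max(1, min(k, len(present) - 1, centered.shape[0] - 1))
    pca = PCA(n_components=k_max, svd_solver="full")
    scores = pca.fit_transform(centered)
    ratio = pca.explained_variance_ratio_
    # drop numerically-null components (rank deficiency)
    keep = ratio > 1e-12
    scores, ratio = scores[:, keep], ratio[keep]
    loadings = pca.components_[keep]
    cum = np.cumsum(ratio)
    k_used = scores.shape[1]
    reached = np.nonzero(cum >= variance_target)[0]
    if reached.size:
        k_used = min(k_used, int(reached[0]) + 1)
    scores, ratio, loadings = scores[:, :k_used], ratio[:k_used], loadings[:k_used]

    for j in range(k_used):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            scores[:, j] = -scores[:, j]
            loadings[j] = -loadings[j]

    return PathwaySignature(
        pathway_name=pathway_name,
        component_scores=pd.DataFrame(
            scores,
            index=dep.cell_line_ids,
            columns=[f"PC{j + 1}" for j in range(k_used)],
        ),
        variance_explained=ratio,
        n_genes_used=len(present),
    )


def first_canonical_correlation(
    x: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> float:
    """First canonical correlation between two centered blocks in [0, 1].

    Computed from the singular values of the product of the blocks'
    orthonormal bases (the numerically stable QR/SVD formulation).
    Directions with singular value below ``RANK_TOL`` of the leading one
    are truncated, which regularizes rank-deficient blocks without biasing
    full-rank ones. A positive ``ridge`` instead shrinks each block's
    covariance toward the identity before whitening.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must share the same observations")
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    if ridge > 0.0:
        n = x.shape[0]
        cxx = x.T @ x / n + ridge * np.eye(x.shape[1])
        cyy = y.T @ y / n + ridge * np.eye(y.shape[1])
        cxy = x.T @ y / n
        wx = np.linalg.inv(np.linalg.cholesky(cxx))
        wy = np.linalg.inv(np.linalg.cholesky(cyy))
        s = np.linalg.svd(wx @ cxy @ wy.T, compute_uv=False)
        return float(min(s[0], 1.0)) if s.size else 0.0
    ux = _orthonormal_basis(x)
    uy = _orthonormal_basis(y)
    if ux.shape[1] == 0 or uy.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(ux.T @ uy, compute_uv=False)
    return float(min(s[0], 1.0))


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return u[:, :0]
    return u[:, s > RANK_TOL * s[0]]


def pathway_cca(
    sig_a: PathwaySignature, sig_b: PathwaySignature, ridge: float = 0.0
) -> float:
    """First canonical correlation between two pathway signatures."""
    if sig_a.cell_line_ids != sig_b.cell_line_ids:
        raise ValueError("signatures computed over different cell-line sets")
    return first_canonical_correlation(
        sig_a.component_scores.to_numpy(),
        sig_b.component_scores.to_numpy(),
        ridge=ridge,
    )


class PathwayAssociation(BaseEstimator):
    """All-pairs pathway association over a gene-set collection.

    ``fit`` extracts a PCA signature per eligible pathway and fills a
    symmetric matrix of first canonical correlations with unit diagonal.
    Pathways with fewer than ``min_genes`` member genes present in the
    dependency matrix are skipped and listed in ``skipped_``. The member
    overlap (Jaccard) of each pathway pair is recorded alongside so users
    can judge score inflation from shared genes.
    """

    def __init__(
        self,
        k: int = DEFAULT_K,
        min_genes: int = DEFAULT_MIN_GENES,
        ridge: float = 0.0,
    ):
        self.k = k
        self.min_genes = min_genes
        self.ridge = ridge

    def fit(self, X: DependencyMatrix, collection: GeneSetCollection):
        signatures: dict[str, PathwaySignature] = {}
        skipped: dict[str, str] = {}
        for name in collection.names():
            try:
                signatures[name] = pathway_signature(
                    X,
                    collection.genes(name),
                    k=self.k,
                    min_genes=self.min_genes,
                    pathway_name=name,
                )
            except ValueError as exc:
                skipped[name] = str(exc)
        if len(signatures) < 2:
            raise ValueError(
                f"fewer than 2 eligible pathways ({len(signatures)} of "
                f"{len(collection)}); cannot build an association matrix"
            )
        names = list(signatures)
        m = len(names)
        scores = np.eye(m)
        overlap = np.eye(m)
        gene_sets = {n: set(collection.genes(n)) for n in names}
        for i in range(m):
            for j in range(i + 1, m):
                scores[i, j] = scores[j, i] = pathway_cca(
                    signatures[names[i]], signatures[names[j]], ridge=self.ridge
                )
                inter = len(gene_sets[names[i]] & gene_sets[names[j]])
                union = len(gene_sets[names[i]] | gene_sets[names[j]])
                overlap[i, j] = overlap[j, i] = inter / union if union else 0.0
        if skipped:
            logger.info("skipped %d ineligible pathways: %s", len(skipped), skipped)
        self.pathway_names_ = names
        self.scores_ = scores
        self.overlap_ = overlap
        self.signatures_ = signatures
        self.skipped_ = skipped
        return self

    def association_matrix(self) -> PathwayAssociationMatrix:
        return PathwayAssociationMatrix(
            pathway_names=self.pathway_names_,
            scores=self.scores_,
            k_used=self.k,
            skipped=self.skipped_,
            overlap=self.overlap_,
        )


def association_matrix(
    dep: DependencyMatrix,
    collection: GeneSetCollection,
    k: int = DEFAULT_K,
    min_genes: int = DEFAULT_MIN_GENES,
    ridge: float = 0.0,
) -> PathwayAssociationMatrix:
    """Functional wrapper over :class:`PathwayAssociation`."""
    est = PathwayAssociation(k=k, min_genes=min_genes, ridge=ridge)
    est.fit(dep, collection)
    return est.association_matrix()


def cluster_pathways(
    mat: PathwayAssociationMatrix, linkage_method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of pathways on distance 1 − score."""
    scores = np.asarray(mat.scores, float)
    if not np.isfinite(scores).all():
        raise ValueError("association matrix contains non-finite entries")
    if len(mat.pathway_names) < 2:
        raise ValueError("need at least 2 pathways to cluster")
    dist = 1.0 - scores
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [mat.pathway_names[i] for i in hierarchy.leaves_list(link)]
    return ClusterResult(linkage=link, leaf_order=order, pathway_names=mat.pathway_names)


def unique_associations(
    dep: DependencyMatrix,
    group: GeneSetCollection,
    reference_collection: GeneSetCollection,
    assoc_cutoff: float = 0.5,
    k: int = DEFAULT_K,
    min_genes: int = DEFAULT_MIN_GENES,
    ridge: float = 0.0,
) -> list[UniqueAssociationReport]:
    """Reference pathways tied to exactly one member of a group.

    For each group member, lists the reference pathways whose association
    score reaches ``assoc_cutoff`` with that member and stays below it for
    every other member. Ineligible members are excluded with a warning;
    fewer than two eligible members is an error.
    """
    if not (0.0 < assoc_cutoff < 1.0):
        raise ValueError("assoc_cutoff must lie in (0, 1)")
    member_sigs: dict[str, PathwaySignature] = {}
    for name in group.names():
        try:
            member_sigs[name] = pathway_signature(
                dep, group.genes(name), k=k, min_genes=min_genes, pathway_name=name
            )
        except ValueError as exc:
            logger.warning("group member %r excluded: %s", name, exc)
    if len(member_sigs) < 2:
        raise ValueError(
            f"fewer than 2 eligible group members ({len(member_sigs)})"
        )
    ref_sigs: dict[str, PathwaySignature] = {}
    for name in reference_collection.names():
        try:
            ref_sigs[name] = pathway_signature(
                dep,
                reference_collection.genes(name),
                k=k,
                min_genes=min_genes,
                pathway_name=name,
            )
        except ValueError as exc:
            logger.warning("reference pathway %r skipped: %s", name, exc)

    members = list(member_sigs)
    scores = {
        (m, p): pathway_cca(member_sigs[m], ref_sigs[p], ridge=ridge)
        for m in members
        for p in ref_sigs
    }
    reports = []
    for m in members:
        unique = [
            (p, scores[(m, p)])
            for p in ref_sigs
            if scores[(m, p)] >= assoc_cutoff
            and all(scores[(o, p)] < assoc_cutoff for o in members if o != m)
        ]
        unique.sort(key=lambda t: (-t[1], t[0]))
        reports.append(
            UniqueAssociationReport(
                focal_member=m,
                group_members=members,
                unique_pathways=unique,
                assoc_cutoff=assoc_cutoff,
            )
        )
    return reports
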