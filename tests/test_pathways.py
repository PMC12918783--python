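"""Pathway PCA signatures, canonical-correlation association, clustering."""

import numpy as np
import pandas as pd
import pytest

from coessence import (
    DependencyMatrix,
    FactorSpec,
    GeneSetCollection,
    LatentFactorDesign,
    PathwayAssociation,
    association_matrix,
    cluster_pathways,
    first_canonical_correlation,
    make_etc_fixture,
    pathway_cca,
    pathway_signature,
    simulate_dependency,
    unique_associations,
)

from conftest import random_dependency


def two_factor_dep(n=300, seed=0, noise_sd=0.4, genes_per=8):
    """Two disjoint 8-gene pathways on independent latent factors."""
    pa = [f"A{i}" for i in range(genes_per)]
    pb = [f"B{i}" for i in range(genes_per)]
    design = LatentFactorDesign(
        n_cell_lines=n,
        factors=[FactorSpec("FA", pa), FactorSpec("FB", pb)],
        noise_sd=noise_sd,
        seed=seed,
    )
    dep, _ = simulate_dependency(design)
    return dep, pa, pb


class TestPathwaySignature:
    def test_duplicated_profile_pair_is_rank_one(self):
        rng = np.random.default_rng(0)
        profile = rng.standard_normal(50)
        dep = DependencyMatrix(
            pd.DataFrame(
                [profile, profile.copy()],
                index=["G1", "G1copy"],
                columns=[f"CL{j}" for j in range(50)],
            )
        )
        sig = pathway_signature(dep, ["G1", "G1copy"], min_genes=2)
        assert sig.k == 1
        assert sig.variance_explained[0] == pytest.approx(1.0)

    def test_isotropic_noise_first_component_share(self):
        # independent equal-variance genes: leading share ~ 1/g plus
        # Marchenko–Pastur spread ~ (1 + sqrt(g/n))^2 / g
        g, n = 10, 2000
        dep = random_dependency(g, n, seed=1)
        sig = pathway_signature(dep, dep.gene_ids, k=3)
        upper = (1 + np.sqrt(g / n)) ** 2 / g
        assert 1 / g * 0.8 < sig.variance_explained[0] < upper * 1.2

    def test_scores_match_direct_eigendecomposition(self):
        dep = random_dependency(4, 40, seed=2)
        sig = pathway_signature(dep, dep.gene_ids, k=3)
        x = dep.values.T
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert sig.variance_explained == pytest.approx(
            evals[:3] / evals.sum(), abs=1e-10
        )
        scores = xc @ evecs[:, :3]
        for j in range(3):
            dot = np.abs(
                scores[:, j] @ sig.component_scores.to_numpy()[:, j]
            )
            norms = np.linalg.norm(scores[:, j]) * np.linalg.norm(
                sig.component_scores.to_numpy()[:, j]
            )
            assert dot == pytest.approx(norms, rel=1e-10)

    def test_component_scores_centered_and_orthogonal(self):
        dep = random_dependency(6, 80, seed=3, missing_rate=0.05)
        sig = pathway_signature(dep, dep.gene_ids, k=4)
        s = sig.component_scores.to_numpy()
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-10)
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        assert np.all(np.diff(sig.variance_explained) <= 1e-12)

    def test_variance_target_truncates_components(self):
        dep, pa, _ = two_factor_dep(seed=4)
        sig = pathway_signature(dep, pa, k=4)
        # one strong shared factor: 80% reached by the first component
        assert sig.k == 1

    def test_sign_convention_is_deterministic(self):
        dep = random_dependency(5, 60, seed=5)
        a = pathway_signature(dep, dep.gene_ids, k=2)
        b = pathway_signature(dep, dep.gene_ids, k=2)
        assert np.array_equal(
            a.component_scores.to_numpy(), b.component_scores.to_numpy()
        )

    def test_below_min_genes_is_error(self, toy_dep):
        with pytest.raises(ValueError, match="min_genes"):
            pathway_signature(toy_dep, ["G1", "G2", "ABSENT"], min_genes=3)

    def test_all_missing_submatrix_is_error(self):
        dep = DependencyMatrix(
            pd.DataFrame(
                np.full((3, 5), np.nan),
                index=["A", "B", "C"],
                columns=[f"CL{j}" for j in range(5)],
            )
        )
        with pytest.raises(ValueError, match="missing"):
            pathway_signature(dep, ["A", "B", "C"])


class TestPathwayCCA:
    def test_self_association_is_one(self):
        dep = random_dependency(6, 100, seed=6)
        sig = pathway_signature(dep, dep.gene_ids, k=3)
        assert pathway_cca(sig, sig) == pytest.approx(1.0, abs=1e-9)

    def test_one_component_cca_equals_abs_pearson(self):
        dep, pa, pb = two_factor_dep(seed=7)
        sa = pathway_signature(dep, pa, k=1)
        sb = pathway_signature(dep, pb, k=1)
        score = pathway_cca(sa, sb)
        r = np.corrcoef(
            sa.component_scores.iloc[:, 0], sb.component_scores.iloc[:, 0]
        )[0, 1]
        assert score == pytest.approx(abs(r), abs=1e-9)

    def test_symmetric_to_machine_precision(self):
        dep, pa, pb = two_factor_dep(seed=8)
        sa = pathway_signature(dep, pa, k=4)
        sb = pathway_signature(dep, pb, k=4)
        assert pathway_cca(sa, sb) == pytest.approx(pathway_cca(sb, sa), abs=1e-12)

    def test_independent_factors_score_near_zero(self):
        dep, pa, pb = two_factor_dep(n=500, seed=9)
        sa = pathway_signature(dep, pa)
        sb = pathway_signature(dep, pb)
        assert pathway_cca(sa, sb) < 0.15

    def test_mismatched_cell_lines_is_error(self):
        dep_a = random_dependency(4, 30, seed=10)
        dep_b = DependencyMatrix(
            dep_a.data.rename(columns=lambda c: c + "_x")
        )
        sa = pathway_signature(dep_a, dep_a.gene_ids)
        sb = pathway_signature(dep_b, dep_b.gene_ids)
        with pytest.raises(ValueError, match="cell-line"):
            pathway_cca(sa, sb)

    def test_rank_deficient_block_handled(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((50, 2))
        x_dup = np.column_stack([x, x[:, 0]])  # exactly collinear column
        y = rng.standard_normal((50, 2))
        score = first_canonical_correlation(x_dup, y)
        assert 0.0 <= score <= 1.0

    def test_ridge_variant_close_to_exact(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((200, 3))
        y = x @ rng.standard_normal((3, 3)) + 0.5 * rng.standard_normal((200, 3))
        exact = first_canonical_correlation(x, y)
        ridged = first_canonical_correlation(x, y, ridge=1e-6)
        assert ridged == pytest.approx(exact, abs=1e-4)


class TestAssociationMatrix:
    def test_duplicate_sets_score_one_off_diagonal(self):
        dep = random_dependency(6, 80, seed=13)
        coll = GeneSetCollection()
        coll.add("P1", "d", dep.gene_ids[:4])
        coll.add("P2", "same genes", dep.gene_ids[:4])
        mat = association_matrix(dep, coll)
        assert mat.score("P1", "P2") == pytest.approx(1.0, abs=1e-9)

    def test_shared_factor_pair_beats_cross_factor(self):
        dep, pa, pb = two_factor_dep(seed=14)
        coll = GeneSetCollection()
        coll.add("A1", "on FA", pa[:4])
        coll.add("A2", "on FA", pa[4:])
        coll.add("B1", "on FB", pb[:4])
        mat = association_matrix(dep, coll)
        assert mat.score("A1", "A2") > mat.score("A1", "B1")
        assert mat.score("A1", "A2") > mat.score("A2", "B1")

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        dep = random_dependency(12, 60, seed=15)
        coll = GeneSetCollection()
        for i in range(3):
            coll.add(f"P{i}", "d", dep.gene_ids[4 * i : 4 * i + 4])
        mat = association_matrix(dep, coll)
        assert np.abs(mat.scores - mat.scores.T).max() < 1e-12
        assert np.allclose(np.diag(mat.scores), 1.0)
        assert ((mat.scores >= 0) & (mat.scores <= 1)).all()

    def test_ineligible_pathways_skipped_and_listed(self):
        dep = random_dependency(6, 50, seed=16)
        coll = GeneSetCollection()
        coll.add("OK1", "d", dep.gene_ids[:3])
        coll.add("OK2", "d", dep.gene_ids[3:])
        coll.add("TINY", "d", ["NOT_THERE", "ALSO_NOT", "NOPE"])
        est = PathwayAssociation().fit(dep, coll)
        assert set(est.pathway_names_) == {"OK1", "OK2"}
        assert "TINY" in est.skipped_

    def test_fewer_than_two_eligible_is_error(self):
        dep = random_dependency(4, 30, seed=17)
        coll = GeneSetCollection()
        coll.add("ONLY", "d", dep.gene_ids)
        with pytest.raises(ValueError, match="2 eligible"):
            association_matrix(dep, coll)

    def test_invariant_under_cell_line_permutation(self):
        dep, pa, pb = two_factor_dep(seed=18)
        coll = GeneSetCollection()
        coll.add("PA", "d", pa)
        coll.add("PB", "d", pb)
        base = association_matrix(dep, coll)
        perm = np.random.default_rng(18).permutation(dep.cell_line_ids)
        shuffled = DependencyMatrix(dep.data.loc[:, perm])
        mat = association_matrix(shuffled, coll)
        assert mat.score("PA", "PB") == pytest.approx(
            base.score("PA", "PB"), abs=1e-9
        )


class TestClustering:
    def test_duplicate_pathways_merge_first(self):
        dep = random_dependency(9, 70, seed=19)
        coll = GeneSetCollection()
        coll.add("DUP1", "d", dep.gene_ids[:4])
        coll.add("DUP2", "d", dep.gene_ids[:4])
        coll.add("OTHER", "d", dep.gene_ids[4:])
        mat = association_matrix(dep, coll)
        result = cluster_pathways(mat)
        first = result.linkage[0]
        merged = {result.pathway_names[int(first[0])],
                  result.pathway_names[int(first[1])]}
        assert merged == {"DUP1", "DUP2"}

    def test_planted_outlier_joins_last(self):
        dep, coll, truth = make_etc_fixture(seed=20)
        mat = association_matrix(dep, coll.subset(truth.group_pathways))
        result = cluster_pathways(mat)
        assert result.joins_last() == "COMPLEX_II"

    def test_leaf_order_is_deterministic(self):
        dep, coll, truth = make_etc_fixture(seed=21)
        mat = association_matrix(dep, coll.subset(truth.group_pathways))
        assert (
            cluster_pathways(mat).leaf_order == cluster_pathways(mat).leaf_order
        )

    def test_newick_export_parses_with_all_leaves(self):
        import io

        from skbio.tree import TreeNode

        dep, coll, truth = make_etc_fixture(seed=22)
        mat = association_matrix(dep, coll.subset(truth.group_pathways))
        newick = cluster_pathways(mat).to_newick()
        tree = TreeNode.read(io.StringIO(newick))
        assert {t.name for t in tree.tips()} == set(truth.group_pathways)

    def test_non_finite_scores_rejected(self):
        from coessence.pathways import PathwayAssociationMatrix

        mat = PathwayAssociationMatrix(
            ["A", "B"], np.array([[1.0, np.nan], [np.nan, 1.0]]), 4
        )
        with pytest.raises(ValueError, match="non-finite"):
            cluster_pathways(mat)


class TestUniqueAssociations:
    def test_identical_members_have_empty_unique_lists(self):
        dep = random_dependency(8, 60, seed=23)
        group = GeneSetCollection()
        group.add("M1", "d", dep.gene_ids[:4])
        group.add("M2", "same", dep.gene_ids[:4])
        refs = GeneSetCollection()
        refs.add("R1", "d", dep.gene_ids[4:])
        reports = unique_associations(dep, group, refs, assoc_cutoff=0.5)
        assert all(rep.unique_pathways == [] for rep in reports)

    def test_planted_unique_pathways_recovered_exactly(self):
        dep, coll, truth = make_etc_fixture(seed=24)
        reports = unique_associations(
            dep,
            coll.subset(truth.group_pathways),
            coll.subset(truth.reference_pathways),
            assoc_cutoff=0.5,
        )
        by_member = {rep.focal_member: rep for rep in reports}
        planted = {p for p, f in truth.pathway_factor_map.items()
                   if f == "F2" and p.startswith("REF_")}
        assert {p for p, _ in by_member["COMPLEX_II"].unique_pathways} == planted
        for m, rep in by_member.items():
            if m != "COMPLEX_II":
                assert not planted & {p for p, _ in rep.unique_pathways}

    def test_raising_cutoff_never_grows_unique_lists(self):
        dep, coll, truth = make_etc_fixture(seed=25)
        group = coll.subset(truth.group_pathways)
        refs = coll.subset(truth.reference_pathways)
        low = unique_associations(dep, group, refs, assoc_cutoff=0.4)
        high = unique_associations(dep, group, refs, assoc_cutoff=0.7)
        low_by = {r.focal_member: {p for p, _ in r.unique_pathways} for r in low}
        high_by = {r.focal_member: {p for p, _ in r.unique_pathways} for r in high}
        for m in low_by:
            # raising the bar can remove a member's unique pathways; a
            # pathway may only *appear* if it stops hitting a second member
            newly = high_by[m] - low_by[m]
            assert not newly

    def test_invalid_cutoff_rejected(self):
        dep = random_dependency(6, 40, seed=26)
        group = GeneSetCollection()
        group.add("M1", "d", dep.gene_ids[:3])
        group.add("M2", "d", dep.gene_ids[3:])
        with pytest.raises(ValueError, match="assoc_cutoff"):
            unique_associations(dep, group, group, assoc_cutoff=1.5)

    def test_fewer_than_two_eligible_members_is_error(self):
        dep = random_dependency(6, 40, seed=27)
        group = GeneSetCollection()
        group.add("M1", "d", dep.gene_ids[:3])
        group.add("GHOST", "d", ["X1", "X2", "X3"])
        refs = GeneSetCollection()
        refs.add("R1", "d", dep.gene_ids[3:])
        with pytest.raises(ValueError, match="eligible group members"):
            unique_associations(dep, group, refs)
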