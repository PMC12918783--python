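"""Quality filters applied to the dependency matrix before correlation.

Two filters mirror the platform's preprocessing: dependency entries for
unexpressed gene/cell-line pairs are masked out (a zero-expression gene
cannot carry a real knockout phenotype, so its score is noise), and genes
measured in too few cell lines are dropped outright because their
correlations would rest on unstable sample sizes.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DependencyMatrix, ExpressionMatrix, FilterReport

logger = logging.getLogger(__name__)

#: Coverage threshold: genes observed in fewer cell lines are removed.
DEFAULT_MIN_LINES = 108


def apply_expression_mask(
    dep: DependencyMatrix,
    expr: ExpressionMatrix,
    zero_tol: float = 0.0,
) -> tuple[DependencyMatrix, FilterReport]:
    """Mask dependency entries whose matched expression is ≤ ``zero_tol``.

    Only the intersection of genes and cell lines present in both matrices
    is evaluated; dependency entries without expression data are left
    untouched (and noted in the report). The reported fraction is over
    evaluated entries, counting every entry at or below the tolerance
    whether or not it was already missing.
    """
    genes = [g for g in dep.gene_ids if g in set(expr.gene_ids)]
    lines = [c for c in dep.cell_line_ids if c in set(expr.cell_line_ids)]
    if not genes or not lines:
        raise ValueError(
            "empty gene or cell-line intersection between dependency and "
            "expression matrices"
        )
    masked_frame = dep.data.copy()
    expr_block = expr.data.loc[genes, lines].to_numpy()
    zero_mask = expr_block <= zero_tol
    block = masked_frame.loc[genes, lines].to_numpy()
    block[zero_mask] = np.nan
    masked_frame.loc[genes, lines] = block

    n_masked = int(zero_mask.sum())
    n_eval = zero_mask.size
    report = FilterReport(
        n_pairs_masked=n_masked,
        fraction_pairs_masked=n_masked / n_eval,
    )
    n_genes_skipped = len(dep.gene_ids) - len(genes)
    n_lines_skipped = len(dep.cell_line_ids) - len(lines)
    if n_genes_skipped or n_lines_skipped:
        report.notes.append(
            f"{n_genes_skipped} genes and {n_lines_skipped} cell lines lack "
            "expression data and were not evaluated by the mask"
        )
    report.notes.append(f"expression mask zero_tol={zero_tol}")
    logger.info(
        "expression mask: %d/%d evaluated pairs masked (%.3f)",
        n_masked,
        n_eval,
        report.fraction_pairs_masked,
    )
    return DependencyMatrix(masked_frame, dep.provenance), report


def filter_low_coverage_genes(
    dep: DependencyMatrix, min_lines: int = DEFAULT_MIN_LINES
) -> tuple[DependencyMatrix, FilterReport]:
    """Drop genes observed (non-missing) in fewer than ``min_lines`` lines.

    The threshold is strict: a gene with exactly ``min_lines`` observations
    is retained. Surviving gene order is preserved.
    """
    if min_lines < 2:
        raise ValueError("min_lines must be at least 2")
    coverage = dep.coverage()
    keep = coverage >= min_lines
    removed = [g for g, ok in zip(dep.gene_ids, keep) if not ok]
    if len(removed) == len(dep.gene_ids):
        raise ValueError(
            f"coverage filter removed all {len(removed)} genes at "
            f"min_lines={min_lines}; review the threshold against the "
            "matrix's missingness"
        )
    report = FilterReport(genes_removed=removed, min_lines=min_lines)
    if removed:
        logger.info(
            "coverage filter: removed %d genes with < %d observed lines",
            len(removed),
            min_lines,
        )
    return DependencyMatrix(dep.data.loc[keep], dep.provenance), report


def preprocess(
    dep: DependencyMatrix,
    expr: ExpressionMatrix | None = None,
    zero_tol: float = 0.0,
    min_lines: int = DEFAULT_MIN_LINES,
) -> tuple[DependencyMatrix, list[FilterReport]]:
    """Expression mask followed by the coverage filter.

    Masking runs first, so coverage counts reflect post-mask missingness.
    """
    reports: list[FilterReport] = []
    if expr is not None:
        dep, rep = apply_expression_mask(dep, expr, zero_tol=zero_tol)
        rep.notes.append("mask applied before coverage filter")
        reports.append(rep)
    dep, rep = filter_low_coverage_genes(dep, min_lines=min_lines)
    reports.append(rep)
    return dep, reports
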