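"""Gene annotation of significant windows and gene-set algebra."""

from __future__ import annotations

import logging

from .datatypes import GeneHit, GeneInterval, WindowRecord

logger = logging.getLogger(__name__)


def overlap_genes(
    windows: list[WindowRecord],
    genes: list[GeneInterval],
    comparison: str = "focal-vs-ref",
    method: str = "xpehh",
    flank: int = 0,
    significant_only: bool = True,
) -> list[GeneHit]:
    """Genes whose interval intersects at least one significant window.

    Intervals are 0-based half-open; overlap requires start < other.end and
    other.start < end after widening the gene by ``flank`` bp on each side.
    Each gene appears once with all supporting windows listed.
    """
    sig = [w for w in windows if w.significant or not significant_only]
    window_chroms = {w.chrom for w in sig}
    hits: list[GeneHit] = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        if gene.chrom not in window_chroms:
            logger.debug("gene %s: chromosome %s has no windows", gene.gene_id, gene.chrom)
            continue
        support = [
            (w.start, w.end)
            for w in sig
            if w.chrom == gene.chrom
            and gene.start - flank < w.end
            and w.start < gene.end + flank
        ]
        if support:
            hits.append(
                GeneHit(
                    gene_id=gene.gene_id,
                    comparison=comparison,
                    method=method,
                    windows=sorted(support),
                )
            )
    return hits


def gene_sets(hits: list[GeneHit]) -> dict[tuple[str, str], set[str]]:
    """Group hit gene ids by (comparison, method) label."""
    sets: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        sets.setdefault((h.comparison, h.method), set()).add(h.gene_id)
    return sets


def intersect_gene_sets(
    sets: dict[str, set[str]] | dict[tuple[str, str], set[str]],
    expression: list,
) -> list[str]:
    """Evaluate a set-algebra expression over named gene sets.

    ``expression`` is a nested prefix list: ["and", A, B], ["or", A, B],
    ["diff", A, B], where A/B are set names (keys of ``sets``) or nested
    expressions. Returns the sorted resulting gene list.
    """

    def ev(node) -> set[str]:
        if isinstance(node, list):
            if len(node) != 3:
                raise ValueError(f"expression node must be [op, lhs, rhs]: {node!r}")
            op, lhs, rhs = node
            left, right = ev(lhs), ev(rhs)
            if op in ("and", "intersect"):
                return left & right
            if op in ("or", "union"):
                return left | right
            if op in ("diff", "minus"):
                return left - right
            raise ValueError(f"unknown set operation {op!r}")
        if node not in sets:
            raise ValueError(f"unknown gene set {node!r}")
        return set(sets[node])

    return sorted(ev(expression))
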