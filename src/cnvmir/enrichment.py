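"""miRNA-target fractions, hypergeometric over-representation, brain report.

Over-representation of a gene set in a query follows the standard
hypergeometric upper tail: with a universe of ``M`` genes of which ``n``
belong to the set, and a query of ``N`` genes showing ``k`` in the set,

    p = P(X >= k),  X ~ Hypergeom(M, n, N)

Raw p-values are Benjamini-Hochberg adjusted across all tested sets,
filtered at adjP < 0.05 and ranked ascending by adjP (ties broken by raw p
then set name), keeping the top 10 — mirroring the two-stage procedure of
first selecting miRNA-target gene groups and then testing pathway sets
over the genes that pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .io_formats import GeneSet, MirnaAnnotation, TargetMap
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "TargetedGeneReport",
    "EnrichmentResult",
    "BrainFractionReport",
    "targeted_genes",
    "hypergeometric_enrichment",
    "mirnas_targeting",
    "brain_fraction_report",
    "two_stage_enrichment",
]


@dataclass(frozen=True)
class TargetedGeneReport:
    """Per-subgroup count of CNV genes that are miRNA targets."""

    subgroup: str
    n_genes: int
    targeted: frozenset[str]

    @property
    def n_targeted(self) -> int:
        return len(self.targeted)

    @property
    def percent_targeted(self) -> float:
        return 100.0 * self.n_targeted / self.n_genes if self.n_genes else 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: frozenset[str]
    raw_p: float
    adj_p: float
    rank: int = 0

    @property
    def n_overlap(self) -> int:
        return len(self.overlap)


@dataclass(frozen=True)
class BrainFractionReport:
    """Brain-related miRNA counts for one subgroup (Table-2 convention:
    the percentage is over miRNAs with expression data only)."""

    subgroup: str
    n_mirnas: int
    n_with_data: int
    n_brain: int

    @property
    def percent_brain(self) -> float:
        return 100.0 * self.n_brain / self.n_with_data if self.n_with_data else 0.0


def targeted_genes(
    subgroup: str, genes: set[str], target_map: TargetMap
) -> TargetedGeneReport:
    """Which of a subgroup's CNV genes appear in any miRNA's target set."""
    genes = {g.upper() for g in genes}
    all_targets = target_map.all_targets()
    return TargetedGeneReport(subgroup, len(genes), frozenset(genes & all_targets))


def hypergeometric_enrichment(
    query: set[str],
    sets: Sequence[GeneSet],
    universe: set[str],
    adjp_threshold: float | None = 0.05,
    top_k: int | None = 10,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of each set in the query.

    Every set is intersected with the universe before testing; the query
    must be a subset of the universe.  With ``adjp_threshold=None`` and
    ``top_k=None`` the full ranked list is returned.
    """
    query = {g.upper() for g in query}
    universe = {g.upper() for g in universe}
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    m_total = len(universe)
    n_query = len(query)
    tested: list[tuple[GeneSet, frozenset[str], float]] = []
    for gs in sets:
        members = gs.genes & universe
        if not members:
            continue
        overlap = frozenset(query & members)
        # P(X >= k) = sf(k - 1)
        raw_p = float(hypergeom.sf(len(overlap) - 1, m_total, len(members), n_query))
        tested.append((gs, overlap, min(1.0, raw_p)))
    if not tested:
        return []
    adj = bh_adjust([t[2] for t in tested])
    results = [
        EnrichmentResult(gs.name, overlap, raw_p, adj_p)
        for (gs, overlap, raw_p), adj_p in zip(tested, adj)
    ]
    results.sort(key=lambda r: (r.adj_p, r.raw_p, r.set_name))
    if adjp_threshold is not None:
        results = [r for r in results if r.adj_p < adjp_threshold]
    if top_k is not None:
        results = results[:top_k]
    return [
        EnrichmentResult(r.set_name, r.overlap, r.raw_p, r.adj_p, rank=i + 1)
        for i, r in enumerate(results)
    ]


def mirnas_targeting(genes: set[str], target_map: TargetMap) -> set[str]:
    """Every miRNA whose target set intersects the given genes."""
    genes = {g.upper() for g in genes}
    return {m for m, targets in target_map.items() if targets & genes}


def brain_fraction_report(
    subgroup: str,
    mirna_ids: Iterable[str],
    annotations: Sequence[MirnaAnnotation],
) -> BrainFractionReport:
    """Count miRNAs with expression data and brain relation in a subgroup.

    miRNAs absent from the annotation table count as "no data" (logged).
    """
    by_id = {a.mirna_id: a for a in annotations}
    ids = list(mirna_ids)
    missing = [m for m in ids if m not in by_id]
    if missing:
        logger.info("%s: %d miRNAs lack annotation; counted as no-data",
                    subgroup, len(missing))
    with_data = [m for m in ids if m in by_id and by_id[m].has_expression]
    brain = [m for m in with_data if by_id[m].brain_related]
    return BrainFractionReport(subgroup, len(ids), len(with_data), len(brain))


def two_stage_enrichment(
    cnv_genes: set[str],
    target_map: TargetMap,
    pathway_sets: Sequence[GeneSet],
    universe: set[str],
    adjp_threshold: float = 0.05,
    top_k: int = 10,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Two sequential over-representation passes.

    Stage 1 tests each miRNA's target set (restricted to the universe)
    against the subgroup's CNV genes; stage 2 tests pathway sets over the
    union of target genes from the stage-1 sets passing adjP < threshold.
    """
    target_sets = [
        GeneSet(m, "miRNA target set", genes & frozenset(universe))
        for m, genes in target_map.items()
        if genes & frozenset(universe)
    ]
    stage1 = hypergeometric_enrichment(
        cnv_genes & universe, target_sets, universe, adjp_threshold, top_k
    )
    passing_genes: set[str] = set()
    for r in stage1:
        passing_genes |= set(r.overlap)
    if not passing_genes:
        return stage1, []
    stage2 = hypergeometric_enrichment(
        passing_genes, pathway_sets, universe, adjp_threshold, top_k
    )
    return stage1, stage2


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path, provenance: str = ""
) -> None:
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("rank\tset_name\tn_overlap\traw_p\tadj_p\toverlap_genes\n")
        for r in results:
            fh.write(
                f"{r.rank}\t{r.set_name}\t{r.n_overlap}\t{r.raw_p:.4g}\t"
                f"{r.adj_p:.4g}\t{','.join(sorted(r.overlap))}\n"
            )
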