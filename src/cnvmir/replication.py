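"""Reproduce published summary ratios from printed group totals.

The study's subgroup table prints, per CNV subgroup, the CNV/CNVR counts,
the total CNVR span in Mb, the distinct miRNA count, and the derived
ratios (miRNA per Mb, miRNA per CNVR).  Given only the printed totals,
these helpers build a minimal synthetic realization — disjoint CNVRs with
exactly the requested total span and a miRNA track with exactly the
requested number of distinct loci inside them — and push it through the
ordinary summarization path, so the derived ratios are recomputed by the
same code that handles real data, not by ad-hoc division.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import FeatureTrack, GroupSummary, summarize_cnvr, summarize_group
from .genome import CNVR, GenomicInterval
from .io_formats import AnnotationFeature

__all__ = ["PublishedGroupTotals", "realize_group_summary", "PUBLISHED_GROUPS"]


@dataclass(frozen=True)
class PublishedGroupTotals:
    """Printed totals for one CNV subgroup."""

    label: str
    n_cnvs: int
    n_cnvrs: int
    total_mb: float
    n_mirnas: int


#: the five subgroups' printed totals (CNVs, CNVRs, total Mb, miRNAs)
PUBLISHED_GROUPS: dict[str, PublishedGroupTotals] = {
    "de_novo": PublishedGroupTotals("de_novo", 24, 22, 70.5, 84),
    "familial": PublishedGroupTotals("familial", 46, 46, 29.5, 14),
    "common_case": PublishedGroupTotals("common_case", 216, 210, 105.2, 67),
    "common_control": PublishedGroupTotals("common_control", 67, 61, 34.1, 30),
    "decipher": PublishedGroupTotals("decipher", 35, 30, 100.1, 90),
}

_MIR_LEN = 22


def realize_group_summary(totals: PublishedGroupTotals) -> GroupSummary:
    """Build disjoint CNVRs realizing the printed totals and summarize them.

    The realization places ``n_cnvrs`` equal-length regions (the remainder
    goes to the first) separated by fixed gaps on one synthetic
    chromosome, and drops ``n_mirnas`` distinct miRNA loci inside the
    first region(s).  Only the group-level identities (counts, span,
    derived ratios) are constrained — per-CNVR structure is arbitrary, as
    the printed ratios depend on totals alone.
    """
    total_bp = int(round(totals.total_mb * 1e6))
    if totals.n_cnvrs <= 0 or total_bp <= 0:
        raise ValueError("need positive CNVR count and span")
    base = total_bp // totals.n_cnvrs
    lengths = [base] * totals.n_cnvrs
    lengths[0] += total_bp - base * totals.n_cnvrs
    gap = 50_000
    cnvrs: list[CNVR] = []
    pos = 0
    for i, length in enumerate(lengths):
        cnvrs.append(CNVR(GenomicInterval("synthetic_chr", pos, pos + length),
                          frozenset({f"cnv{i}"}), totals.label))
        pos += length + gap

    mirnas: list[AnnotationFeature] = []
    slot = 0
    for m in range(totals.n_mirnas):
        # walk through CNVRs so every locus lands inside some region
        region = cnvrs[slot % len(cnvrs)].interval
        offset = (slot // len(cnvrs)) * (_MIR_LEN + 8)
        if offset + _MIR_LEN > region.length:
            raise ValueError("regions too small to host the miRNA count")
        start = region.start + offset
        mirnas.append(AnnotationFeature(
            GenomicInterval("synthetic_chr", start, start + _MIR_LEN),
            f"mir-{m + 1}", "mirna"))
        slot += 1
    mirna_track = FeatureTrack(mirnas)
    gene_track = FeatureTrack([])
    summaries = [summarize_cnvr(r, mirna_track, gene_track) for r in cnvrs]
    return summarize_group(totals.label, totals.n_cnvs, cnvrs, summaries)
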