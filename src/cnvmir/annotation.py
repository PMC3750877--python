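"""miRNA / protein-coding-gene content of CNVRs and group summaries.

A feature belongs to a region when it overlaps it by at least one base —
features straddling a region boundary count ("within or covering" the
region).  Densities divide counts by exact base-pair length / 1e6, never by
pre-rounded megabases, so printed two-decimal densities are reproducible
from the printed totals.  Rounding happens only at the reporting layer,
half away from zero: two decimals for densities, one decimal for per-CNVR
averages.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import CNVR, CNVCall, GenomicInterval
from .io_formats import AnnotationFeature
from .stats import WeightedSample, weighted_median

__all__ = [
    "FeatureTrack",
    "ContentSummary",
    "GroupSummary",
    "features_in_region",
    "summarize_cnvr",
    "summarize_group",
    "round_half_away",
    "write_cnvr_content_table",
    "write_group_summary_table",
]

GROUP_LABELS = ("de_novo", "familial", "common_case", "common_control", "decipher")


class FeatureTrack:
    """Indexed annotation track (one feature class) for overlap queries."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self.features = list(features)
        classes = {f.feature_class for f in self.features}
        if len(classes) > 1:
            raise ValueError(f"mixed feature classes in one track: {sorted(classes)}")
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids in track")
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in self.features:
            self._trees[f.interval.chrom].addi(f.interval.start, f.interval.end, f.feature_id)
        # sorted-array mirror for bulk counting (start-sorted per chromosome)
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, f in enumerate(self.features):
            by_chrom[f.interval.chrom].append(i)
        for chrom, idx in by_chrom.items():
            starts = np.array([self.features[i].interval.start for i in idx])
            order = np.argsort(starts, kind="stable")
            idx_arr = np.array(idx)[order]
            starts = starts[order]
            ends = np.array([self.features[i].interval.end for i in idx_arr])
            max_len = int((ends - starts).max()) if len(idx_arr) else 0
            self._arrays[chrom] = (starts, ends, idx_arr, max_len)

    def __len__(self) -> int:
        return len(self.features)

    def overlapping(self, region: GenomicInterval) -> set[str]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(region.start, region.end)}

    def count_distinct_overlapping(self, regions: Sequence[GenomicInterval]) -> int:
        """Number of distinct features hit by any region (bulk fast path)."""
        hit_chunks: list[np.ndarray] = []
        for region in regions:
            entry = self._arrays.get(region.chrom)
            if entry is None:
                continue
            starts, ends, idx_arr, max_len = entry
            lo = int(np.searchsorted(starts, region.start - max_len, side="left"))
            hi = int(np.searchsorted(starts, region.end, side="left"))
            if hi <= lo:
                continue
            window = slice(lo, hi)
            mask = ends[window] > region.start
            if mask.any():
                hit_chunks.append(idx_arr[window][mask])
        if not hit_chunks:
            return 0
        return int(np.unique(np.concatenate(hit_chunks)).size)


@dataclass(frozen=True)
class ContentSummary:
    """miRNA and gene content of one CNVR."""

    cnvr: CNVR
    mirna_ids: frozenset[str]
    gene_ids: frozenset[str]

    @property
    def size_mb(self) -> float:
        return self.cnvr.size_mb

    @property
    def mirna_density(self) -> float:
        return len(self.mirna_ids) / self.size_mb

    @property
    def gene_density(self) -> float:
        return len(self.gene_ids) / self.size_mb


@dataclass(frozen=True)
class GroupSummary:
    """One row of the per-subgroup content report.

    Totals count *distinct* feature ids across the group's CNVRs; since
    CNVRs within a subgroup are disjoint after merging, the distinction
    from summed per-CNVR counts only matters for malformed input.
    """

    label: str
    n_cnvs: int
    n_cnvrs: int
    total_mb: float
    mean_cnvr_size_mb: float
    n_mirnas: int
    mirna_per_mb: float
    mirna_per_cnvr: float
    weighted_median_mirna_per_mb: float
    unweighted_median_mirna_per_mb: float
    n_genes: int
    gene_per_mb: float
    gene_per_cnvr: float
    weighted_median_gene_per_mb: float
    unweighted_median_gene_per_mb: float


def features_in_region(region: GenomicInterval, track: FeatureTrack) -> set[str]:
    """Ids of track features overlapping the region by >= 1 bp."""
    return track.overlapping(region)


def summarize_cnvr(
    cnvr: CNVR, mirna_track: FeatureTrack, gene_track: FeatureTrack
) -> ContentSummary:
    return ContentSummary(
        cnvr=cnvr,
        mirna_ids=frozenset(features_in_region(cnvr.interval, mirna_track)),
        gene_ids=frozenset(features_in_region(cnvr.interval, gene_track)),
    )


def summarize_group(
    label: str,
    cnvs: Sequence[CNVCall] | int,
    cnvrs: Sequence[CNVR],
    summaries: Sequence[ContentSummary],
) -> GroupSummary:
    """Aggregate per-CNVR content into a group summary row.

    ``cnvs`` may be the call list or a bare count (for pre-aggregated
    inputs).  ``summaries`` must cover exactly the group's CNVRs.
    """
    n_cnvs = cnvs if isinstance(cnvs, int) else len(cnvs)
    if len(summaries) != len(cnvrs):
        raise ValueError("summaries must cover exactly the group's CNVRs")
    n_cnvrs = len(cnvrs)
    total_bp = sum(r.length for r in cnvrs)
    total_mb = total_bp / 1e6
    mirnas: set[str] = set()
    genes: set[str] = set()
    for s in summaries:
        mirnas |= s.mirna_ids
        genes |= s.gene_ids
    if summaries:
        mirna_sample = WeightedSample(
            tuple(s.mirna_density for s in summaries),
            tuple(s.size_mb for s in summaries),
        )
        gene_sample = WeightedSample(
            tuple(s.gene_density for s in summaries),
            tuple(s.size_mb for s in summaries),
        )
        wmed_mirna = weighted_median(mirna_sample)
        wmed_gene = weighted_median(gene_sample)
        umed_mirna = weighted_median(
            WeightedSample(mirna_sample.values, (1.0,) * len(summaries)))
        umed_gene = weighted_median(
            WeightedSample(gene_sample.values, (1.0,) * len(summaries)))
    else:
        wmed_mirna = wmed_gene = umed_mirna = umed_gene = float("nan")
    return GroupSummary(
        label=label,
        n_cnvs=n_cnvs,
        n_cnvrs=n_cnvrs,
        total_mb=total_mb,
        mean_cnvr_size_mb=total_mb / n_cnvrs if n_cnvrs else float("nan"),
        n_mirnas=len(mirnas),
        mirna_per_mb=len(mirnas) / total_mb if total_mb else float("nan"),
        mirna_per_cnvr=len(mirnas) / n_cnvrs if n_cnvrs else float("nan"),
        weighted_median_mirna_per_mb=wmed_mirna,
        unweighted_median_mirna_per_mb=umed_mirna,
        n_genes=len(genes),
        gene_per_mb=len(genes) / total_mb if total_mb else float("nan"),
        gene_per_cnvr=len(genes) / n_cnvrs if n_cnvrs else float("nan"),
        weighted_median_gene_per_mb=wmed_gene,
        unweighted_median_gene_per_mb=umed_gene,
    )


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention)."""
    if math.isnan(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def write_cnvr_content_table(
    summaries: Iterable[ContentSummary], path: str | Path, provenance: str = ""
) -> None:
    """Per-CNVR report: coordinates, size, miRNA list, gene counts."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("subgroup\tchrom\tstart\tend\tsize_mb\tn_mirnas\tmirna_ids\t"
                 "n_genes\tmirna_per_mb\tgene_per_mb\n")
        for s in summaries:
            iv = s.cnvr.interval
            fh.write(
                f"{s.cnvr.subgroup}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{s.size_mb:.6f}\t{len(s.mirna_ids)}\t{','.join(sorted(s.mirna_ids))}\t"
                f"{len(s.gene_ids)}\t{s.mirna_density:.6g}\t{s.gene_density:.6g}\n"
            )


def write_group_summary_table(
    rows: Iterable[GroupSummary], path: str | Path, provenance: str = ""
) -> None:
    """Group summary with report rounding (densities 2 dp, per-CNVR 1 dp)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("subgroup\tn_cnvs\tn_cnvrs\ttotal_mb\tmean_cnvr_size_mb\t"
                 "n_mirnas\tmirna_per_mb\tmirna_per_cnvr\tweighted_median_mirna_per_mb\t"
                 "n_genes\tgene_per_mb\tgene_per_cnvr\tweighted_median_gene_per_mb\n")
        for g in rows:
            fh.write(
                f"{g.label}\t{g.n_cnvs}\t{g.n_cnvrs}\t"
                f"{round_half_away(g.total_mb, 1):.1f}\t"
                f"{round_half_away(g.mean_cnvr_size_mb, 2):.2f}\t"
                f"{g.n_mirnas}\t"
                f"{round_half_away(g.mirna_per_mb, 2):.2f}\t"
                f"{round_half_away(g.mirna_per_cnvr, 1):.1f}\t"
                f"{round_half_away(g.weighted_median_mirna_per_mb, 1):.1f}\t"
                f"{g.n_genes}\t"
                f"{round_half_away(g.gene_per_mb, 2):.2f}\t"
                f"{round_half_away(g.gene_per_cnvr, 1):.1f}\t"
                f"{round_half_away(g.weighted_median_gene_per_mb, 1):.1f}\n"
            )
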