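"""Genome model, interval algebra, and CNVR merging.

All coordinates inside the package are 0-based, half-open ``[start, end)``.
Readers convert from the file format's convention on input and writers
convert back on output, so off-by-one arithmetic lives only at the I/O
boundary.  Strand is ignored throughout: every intersection in the pipeline
is a strandless region overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "CNVCall",
    "CNVR",
    "interval_overlap_bp",
    "merge_to_cnvrs",
    "total_span_mb",
]

CNV_STATES = frozenset({"gain", "loss"})
INHERITANCE = frozenset({"de_novo", "maternal", "paternal", "unknown"})
COHORTS = frozenset({"case", "control", "decipher"})


class GenomeBuild:
    """Chromosome names and lengths for one assembly.

    Parameters
    ----------
    sizes
        Mapping of chromosome name to length in base pairs.  Names must be
        unique (guaranteed by the mapping) and every length positive.
    """

    def __init__(self, sizes: Mapping[str, int]):
        clean: dict[str, int] = {}
        for name, length in sizes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            clean[str(name)] = length
        if not clean:
            raise ValueError("genome build has no chromosomes")
        self._sizes = clean

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self._sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeBuild) and self._sizes == other._sizes

    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeBuild({len(self._sizes)} chromosomes, {self.total_length()} bp)"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def validate(self, genome: GenomeBuild) -> "GenomicInterval":
        """Check the interval fits its chromosome; return self for chaining."""
        if self.chrom not in genome:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > genome[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome[self.chrom]}"
            )
        return self

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return interval_overlap_bp(self, other) > 0


@dataclass(frozen=True)
class CNVCall:
    """One sample-level copy-number call (single copy gain or loss)."""

    interval: GenomicInterval
    sample_id: str
    state: str
    inheritance: str
    cohort: str
    cnv_id: str = ""

    def __post_init__(self):
        if self.state not in CNV_STATES:
            raise ValueError(f"state must be one of {sorted(CNV_STATES)}, got {self.state!r}")
        if self.inheritance not in INHERITANCE:
            raise ValueError(
                f"inheritance must be one of {sorted(INHERITANCE)}, got {self.inheritance!r}"
            )
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {sorted(COHORTS)}, got {self.cohort!r}")
        if not self.cnv_id:
            object.__setattr__(
                self,
                "cnv_id",
                f"{self.sample_id}|{self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}|{self.state}",
            )


@dataclass(frozen=True)
class CNVR:
    """A merged copy-number variant region within one subgroup."""

    interval: GenomicInterval
    member_ids: frozenset[str]
    subgroup: str

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def size_mb(self) -> float:
        return self.interval.length / 1e6


def interval_overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_to_cnvrs(cnvs: Iterable[CNVCall], subgroup: str) -> list[CNVR]:
    """Merge overlapping CNVs of one subgroup into CNVRs.

    The output regions are the connected components of the overlap graph:
    two calls belong to the same CNVR iff they are linked by a chain of
    pairwise overlaps of at least one shared base.  Book-ended calls
    (``a.end == b.start``) share no base under the half-open convention and
    are *not* merged.  Output is sorted by chromosome name then start.
    """
    calls = sorted(cnvs, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    regions: list[CNVR] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_members: set[str] = set()

    def flush():
        if cur_members:
            regions.append(
                CNVR(
                    interval=GenomicInterval(cur_chrom, cur_start, cur_end),
                    member_ids=frozenset(cur_members),
                    subgroup=subgroup,
                )
            )

    for call in calls:
        iv = call.interval
        if cur_chrom == iv.chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            cur_members.add(call.cnv_id)
        else:
            flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_members = {call.cnv_id}
    flush()
    return regions


def total_span_mb(cnvrs: Iterable[CNVR]) -> float:
    """Total length of pairwise non-overlapping regions, in megabases.

    Raises ``ValueError`` if any two regions overlap: overlapping input
    means merging was skipped, and summing lengths would double count.
    """
    ivs = sorted((r.interval for r in cnvrs), key=lambda i: (i.chrom, i.start))
    total = 0
    for prev, cur in zip(ivs, ivs[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError(
                f"overlapping regions {prev.chrom}:{prev.start}-{prev.end} and "
                f"{cur.chrom}:{cur.start}-{cur.end}; merge before measuring span"
            )
    for iv in ivs:
        total += iv.length
    return total / 1e6
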