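"""Clinical classification of CNVs: common, de novo, familial.

A CNV is *common* when it is completely covered by population variants
reported in at least two distinct studies (DGV-style database, optionally
augmented with internal controls).  A CNV overlapping known variants over
less than half of its length — or not at all — is *rare*, and splits into
*de novo* (absent from both parents) or *familial* (inherited) by its
inheritance label.  Coverage between the rare ceiling and the common floor,
or full coverage supported by a single study, is not assigned by these
rules; such CNVs are classed *ambiguous* and excluded by default.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome import CNVCall
from .io_formats import KnownVariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationConfig",
    "ClassifiedCNV",
    "KnownVariantIndex",
    "covered_fraction",
    "classify_cnv",
    "partition_cohort",
    "write_classification_report",
    "INTERNAL_CONTROL_STUDY",
]

#: reserved study id under which internal-control CNVs enter the known-variant list
INTERNAL_CONTROL_STUDY = "__internal_controls__"

SUBGROUPS = ("de_novo", "familial", "common_case", "common_control", "decipher")


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the classification rules.

    ``min_studies``: distinct studies required for a common call (default 2).
    ``rare_overlap_ceiling``: coverage below this fraction is rare (default 0.5).
    ``common_overlap_floor``: coverage at or above this is common, given
    enough studies (default 1.0, i.e. complete overlap).
    ``ambiguous_policy``: ``"exclude"`` or ``"treat_as_rare"``.
    """

    min_studies: int = 2
    rare_overlap_ceiling: float = 0.50
    common_overlap_floor: float = 1.0
    ambiguous_policy: str = "exclude"

    def __post_init__(self):
        if not (0.0 <= self.rare_overlap_ceiling <= self.common_overlap_floor <= 1.0):
            raise ValueError("require 0 <= rare ceiling <= common floor <= 1")
        if self.min_studies < 1:
            raise ValueError("min_studies must be >= 1")
        if self.ambiguous_policy not in ("exclude", "treat_as_rare"):
            raise ValueError(f"unknown ambiguous policy {self.ambiguous_policy!r}")


@dataclass(frozen=True)
class ClassifiedCNV:
    cnv: CNVCall
    cnv_class: str  # common | de_novo | familial | rare | ambiguous
    covered_fraction: float
    supporting_studies: int


class KnownVariantIndex:
    """Per-chromosome interval index over known variants."""

    def __init__(self, records: Iterable[KnownVariantRecord]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for rec in records:
            iv = rec.interval
            self._trees[iv.chrom].addi(iv.start, iv.end, rec)

    def overlapping(self, cnv: CNVCall) -> list[KnownVariantRecord]:
        iv = cnv.interval
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def covered_fraction(
    cnv: CNVCall, known: Sequence[KnownVariantRecord] | KnownVariantIndex
) -> tuple[float, int]:
    """Fraction of the CNV covered by the union of known variants.

    Returns ``(fraction, n_distinct_studies)`` where the study count is
    over the distinct study ids of variants overlapping the CNV by >= 1 bp.
    """
    index = known if isinstance(known, KnownVariantIndex) else KnownVariantIndex(known)
    hits = index.overlapping(cnv)
    if not hits:
        return 0.0, 0
    start, end = cnv.interval.start, cnv.interval.end
    segments = sorted(
        (max(start, r.interval.start), min(end, r.interval.end)) for r in hits
    )
    covered = 0
    cur_s, cur_e = segments[0]
    for s, e in segments[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    studies = {r.study_id for r in hits}
    return covered / cnv.interval.length, len(studies)


def classify_cnv(
    cnv: CNVCall,
    known: Sequence[KnownVariantRecord] | KnownVariantIndex,
    config: ClassificationConfig = ClassificationConfig(),
    split_rare: bool = True,
) -> ClassifiedCNV:
    """Classify one CNV against the known-variant database.

    With ``split_rare=True`` (the default) rare CNVs are split into
    de novo / familial by inheritance, and a rare CNV with unknown
    inheritance is an error.  Cohorts where inheritance is never recorded
    (controls) pass ``split_rare=False`` to receive the plain ``rare``
    class instead.
    """
    fraction, studies = covered_fraction(cnv, known)
    if fraction >= config.common_overlap_floor and studies >= config.min_studies:
        cls = "common"
    elif fraction < config.rare_overlap_ceiling:
        cls = "rare"
    else:
        cls = "ambiguous"
        if config.ambiguous_policy == "treat_as_rare":
            cls = "rare"
    if cls == "rare" and split_rare:
        if cnv.inheritance == "de_novo":
            cls = "de_novo"
        elif cnv.inheritance in ("maternal", "paternal"):
            cls = "familial"
        else:
            raise ValueError(
                f"rare CNV {cnv.cnv_id} has unknown inheritance; cannot split "
                "into de novo / familial"
            )
    return ClassifiedCNV(cnv, cls, fraction, studies)


def partition_cohort(
    cnvs: Iterable[CNVCall],
    known: Sequence[KnownVariantRecord] | KnownVariantIndex,
    config: ClassificationConfig = ClassificationConfig(),
) -> dict[str, list[CNVCall]]:
    """Partition a mixed cohort into the five standard subgroups.

    DECIPHER-cohort CNVs bypass classification (they are curated pathogenic
    regions).  Case-cohort CNVs classify into de novo / familial /
    common-from-cases; control-cohort CNVs into common-from-controls, with
    rare control CNVs reported under ``"rare_control"`` with a warning
    (they belong to no standard subgroup).  Ambiguous CNVs land under
    ``"ambiguous"`` when the policy excludes them.
    """
    index = known if isinstance(known, KnownVariantIndex) else KnownVariantIndex(known)
    groups: dict[str, list[CNVCall]] = {label: [] for label in SUBGROUPS}
    groups["ambiguous"] = []
    groups["rare_control"] = []

    for cnv in cnvs:
        if cnv.cohort == "decipher":
            groups["decipher"].append(cnv)
            continue
        classified = classify_cnv(cnv, index, config, split_rare=(cnv.cohort == "case"))
        cls = classified.cnv_class
        if cnv.cohort == "case":
            if cls == "common":
                groups["common_case"].append(cnv)
            elif cls in ("de_novo", "familial"):
                groups[cls].append(cnv)
            else:  # ambiguous under the exclude policy
                groups["ambiguous"].append(cnv)
        else:  # control cohort
            if cls == "common":
                groups["common_control"].append(cnv)
            elif cls == "ambiguous":
                groups["ambiguous"].append(cnv)
            else:
                groups["rare_control"].append(cnv)

    if groups["rare_control"]:
        logger.warning(
            "%d control-cohort CNVs classified rare; reported separately, "
            "outside the five standard subgroups", len(groups["rare_control"])
        )
    for label in SUBGROUPS:
        logger.info("subgroup %s: %d CNVs", label, len(groups[label]))
    return groups


def write_classification_report(
    classified: Iterable[ClassifiedCNV], path: str | Path, provenance: str = ""
) -> None:
    """One row per CNV: class, covered fraction, supporting studies."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance)
        fh.write("cnv_id\tchrom\tstart\tend\tcohort\tclass\tcovered_fraction\tsupporting_studies\n")
        for c in classified:
            iv = c.cnv.interval
            fh.write(
                f"{c.cnv.cnv_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cnv.cohort}\t"
                f"{c.cnv_class}\t{c.covered_fraction:.6g}\t{c.supporting_studies}\n"
            )
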