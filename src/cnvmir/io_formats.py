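"""Readers and writers for every external file the pipeline touches.

Formats
-------
- chromosome sizes: two-column TSV (name, length)
- CNV calls: TSV with header (chrom, start, end, sample, state, inheritance,
  cohort[, id]); coordinate convention declared by the caller, default
  1-based inclusive as is conventional for clinical CNV tables
- known variants (DGV-style): TSV with chrom, start, end, study_id,
  variant_id; extra columns ignored (DGV dialects vary across releases)
- miRNA loci: GFF3, 1-based inclusive (miRBase dialect)
- protein-coding genes: BED, 0-based half-open, name column = gene symbol
- gene sets: GMT (name, description, member genes)
- miRNA -> target gene map: two-column TSV
- miRNA expression/brain annotation: TSV

Everything is converted to the internal 0-based half-open convention on
read and converted back on write.  Readers preserve input order; sorting is
an explicit downstream step.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .genome import CNVCall, GenomeBuild, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "KnownVariantRecord",
    "AnnotationFeature",
    "TargetMap",
    "GeneSet",
    "MirnaAnnotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_cnv_table",
    "write_cnv_table",
    "read_gff3_mirnas",
    "write_gff3_mirnas",
    "read_bed_genes",
    "write_bed_genes",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "read_known_variants",
    "write_known_variants",
    "read_mirna_annotation",
    "write_mirna_annotation",
]


# ---------------------------------------------------------------------------
# domain types owned by this module


@dataclass(frozen=True)
class KnownVariantRecord:
    """A population variant from a DGV-style database, tagged by study."""

    interval: GenomicInterval
    study_id: str
    variant_id: str

    def __post_init__(self):
        if not self.study_id:
            raise ValueError("known variant requires a non-empty study id")


@dataclass(frozen=True)
class AnnotationFeature:
    """A located miRNA or protein-coding gene with a stable identifier."""

    interval: GenomicInterval
    feature_id: str
    feature_class: str  # "mirna" | "pcg"

    def __post_init__(self):
        if self.feature_class not in ("mirna", "pcg"):
            raise ValueError(f"feature class must be mirna or pcg, got {self.feature_class!r}")


class TargetMap:
    """Mapping from miRNA id to its set of target gene symbols.

    Empty target sets are never stored; gene symbols are upper-cased.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {}
        if mapping:
            for mirna, genes in mapping.items():
                genes = frozenset(g.upper() for g in genes)
                if genes:
                    self._map[mirna] = genes

    def targets(self, mirna: str) -> frozenset[str]:
        return self._map.get(mirna, frozenset())

    def mirnas(self) -> list[str]:
        return list(self._map)

    def items(self):
        return self._map.items()

    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._map.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self._map

    def __eq__(self, other) -> bool:
        return isinstance(other, TargetMap) and self._map == other._map


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG pathway)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class MirnaAnnotation:
    """Curated expression/brain-function annotation for one miRNA.

    ``brain_related`` may only be set when expression data exists: the
    brain call is made from expression or functional evidence, so a miRNA
    without any data cannot be called brain-related.
    """

    mirna_id: str
    has_expression: bool
    brain_related: bool
    note: str = ""

    def __post_init__(self):
        if self.brain_related and not self.has_expression:
            raise ValueError(
                f"{self.mirna_id}: brain_related requires has_expression"
            )


# ---------------------------------------------------------------------------
# helpers


def _open_rows(path: str | Path):
    """Yield (line_number, row-list) for non-comment, non-blank TSV lines."""
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped.split("\t")


def _as_bool(token: str, lineno: int, path) -> bool:
    t = token.strip().lower()
    if t in ("1", "true", "yes", "y"):
        return True
    if t in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"{path}:{lineno}: cannot interpret {token!r} as a flag")


def provenance_block(**fields: object) -> str:
    """Commented provenance header for report files."""
    lines = [f"# {key}: {value}" for key, value in fields.items()]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    sizes: dict[str, int] = {}
    for lineno, row in _open_rows(path):
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns (name, length)")
        name = row[0]
        if name in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        sizes[name] = int(row[1])
    return GenomeBuild(sizes)


def write_chrom_sizes(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f"{name}\t{genome[name]}\n")


# ---------------------------------------------------------------------------
# CNV call table

_CNV_COLUMNS = ["chrom", "start", "end", "sample", "state", "inheritance", "cohort"]


def read_cnv_table(
    path: str | Path,
    genome: GenomeBuild,
    coords: str = "1-based",
) -> list[CNVCall]:
    """Read a CNV call table.

    ``coords`` declares the file's convention: ``"1-based"`` (inclusive,
    the clinical default) or ``"0-based"`` (half-open).  Rows on
    chromosomes absent from ``genome`` are dropped with a logged count.
    """
    if coords not in ("1-based", "0-based"):
        raise ValueError(f"coords must be '1-based' or '0-based', got {coords!r}")
    offset = 1 if coords == "1-based" else 0

    rows = _open_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty CNV table (no header)")
    colidx = {name: i for i, name in enumerate(header)}
    missing = [c for c in _CNV_COLUMNS if c not in colidx]
    if missing:
        raise ValueError(f"{path}:{header_lineno}: missing columns {missing}")

    calls: list[CNVCall] = []
    skipped = 0
    for lineno, row in rows:
        chrom = row[colidx["chrom"]]
        if chrom not in genome:
            skipped += 1
            continue
        start = int(row[colidx["start"]]) - offset
        end = int(row[colidx["end"]])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start + offset}, {end})")
        try:
            interval = GenomicInterval(chrom, start, end).validate(genome)
            call = CNVCall(
                interval=interval,
                sample_id=row[colidx["sample"]],
                state=row[colidx["state"]],
                inheritance=row[colidx["inheritance"]],
                cohort=row[colidx["cohort"]],
                cnv_id=row[colidx["id"]] if "id" in colidx else "",
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        calls.append(call)
    if skipped:
        logger.warning("%s: dropped %d rows on chromosomes absent from the genome build",
                       path, skipped)
    return calls


def write_cnv_table(calls: Iterable[CNVCall], path: str | Path,
                    coords: str = "1-based") -> None:
    offset = 1 if coords == "1-based" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(_CNV_COLUMNS + ["id"]) + "\n")
        for c in calls:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start + offset}\t{c.interval.end}\t"
                f"{c.sample_id}\t{c.state}\t{c.inheritance}\t{c.cohort}\t{c.cnv_id}\n"
            )


# ---------------------------------------------------------------------------
# miRNA GFF3 (miRBase dialect, 1-based inclusive)


def read_gff3_mirnas(
    path: str | Path,
    genome: GenomeBuild,
    id_attribute: str = "Name",
    feature_types: set[str] | None = None,
) -> list[AnnotationFeature]:
    """Read miRNA loci from a miRBase-style GFF3 file.

    ``feature_types`` optionally restricts to given GFF3 type-column values
    (e.g. ``{"miRNA"}`` for mature records only); ``None`` keeps every
    feature line.  Identifiers come from ``id_attribute`` in column 9.
    """
    features: list[AnnotationFeature] = []
    seen: set[str] = set()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feature_types is not None and feat.featuretype not in feature_types:
                continue
            if feat.seqid not in genome:
                skipped += 1
                continue
            if id_attribute not in feat.attributes:
                raise ValueError(
                    f"{path}:{lineno}: attribute {id_attribute!r} missing"
                )
            fid = feat.attributes[id_attribute][0]
            if fid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate miRNA id {fid!r}")
            seen.add(fid)
            # GFF3 is 1-based inclusive
            interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end).validate(genome)
            features.append(AnnotationFeature(interval, fid, "mirna"))
    if skipped:
        logger.warning("%s: dropped %d features on unknown chromosomes", path, skipped)
    return features


def write_gff3_mirnas(features: Iterable[AnnotationFeature], path: str | Path,
                      feature_type: str = "miRNA") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.interval.chrom}\t.\t{feature_type}\t"
                f"{f.interval.start + 1}\t{f.interval.end}\t.\t+\t.\t"
                f"ID={f.feature_id};Name={f.feature_id}\n"
            )


# ---------------------------------------------------------------------------
# protein-coding gene BED (0-based half-open)


def read_bed_genes(path: str | Path, genome: GenomeBuild) -> list[AnnotationFeature]:
    """Read a gene track from BED; the name column is the gene symbol.

    Symbols are upper-cased (gene identity throughout the pipeline is by
    upper-case symbol) and must be unique within the track.
    """
    features: list[AnnotationFeature] = []
    seen: set[str] = set()
    skipped = 0
    for lineno, row in _open_rows(path):
        if row and row[0] in ("track", "browser"):
            continue
        if len(row) < 4:
            raise ValueError(f"{path}:{lineno}: BED gene track needs 4+ columns")
        chrom, start, end, symbol = row[0], int(row[1]), int(row[2]), row[3].upper()
        if chrom not in genome:
            skipped += 1
            continue
        if symbol in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene symbol {symbol!r}")
        seen.add(symbol)
        try:
            interval = GenomicInterval(chrom, start, end).validate(genome)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        features.append(AnnotationFeature(interval, symbol, "pcg"))
    if skipped:
        logger.warning("%s: dropped %d genes on unknown chromosomes", path, skipped)
    return features


def write_bed_genes(features: Iterable[AnnotationFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}\t{f.feature_id}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, row in _open_rows(path):
        if len(row) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, desc = row[0], row[1]
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        seen.add(name)
        genes = frozenset(g.upper() for g in row[2:] if g)
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets.append(GeneSet(name, desc, genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# miRNA -> target gene map


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column (mirna, gene) TSV into a TargetMap.

    A header row whose first cell is ``mirna`` is skipped if present.
    """
    pairs: dict[str, set[str]] = {}
    first = True
    for lineno, row in _open_rows(path):
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected mirna<TAB>gene")
        if first:
            first = False
            if row[0].lower() in ("mirna", "mirna_id"):
                continue
        pairs.setdefault(row[0], set()).add(row[1].upper())
    return TargetMap(pairs)


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tgene\n")
        for mirna, genes in sorted(tmap.items()):
            for gene in sorted(genes):
                fh.write(f"{mirna}\t{gene}\n")


# ---------------------------------------------------------------------------
# known variants (DGV-style)

_KV_COLUMNS = ["chrom", "start", "end", "study_id", "variant_id"]


def read_known_variants(
    path: str | Path, genome: GenomeBuild, coords: str = "1-based"
) -> list[KnownVariantRecord]:
    """Read a DGV-style known-variant table; extra columns are ignored."""
    offset = 1 if coords == "1-based" else 0
    rows = _open_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty known-variant table")
    colidx = {name: i for i, name in enumerate(header)}
    missing = [c for c in _KV_COLUMNS if c not in colidx]
    if missing:
        raise ValueError(f"{path}:{header_lineno}: missing columns {missing}")
    records: list[KnownVariantRecord] = []
    skipped = 0
    for lineno, row in rows:
        chrom = row[colidx["chrom"]]
        if chrom not in genome:
            skipped += 1
            continue
        try:
            interval = GenomicInterval(
                chrom, int(row[colidx["start"]]) - offset, int(row[colidx["end"]])
            ).validate(genome)
            records.append(
                KnownVariantRecord(interval, row[colidx["study_id"]], row[colidx["variant_id"]])
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if skipped:
        logger.warning("%s: dropped %d variants on unknown chromosomes", path, skipped)
    return records


def write_known_variants(records: Iterable[KnownVariantRecord], path: str | Path,
                         coords: str = "1-based") -> None:
    offset = 1 if coords == "1-based" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(_KV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start + offset}\t{r.interval.end}\t"
                f"{r.study_id}\t{r.variant_id}\n"
            )


# ---------------------------------------------------------------------------
# miRNA expression/brain annotation


def read_mirna_annotation(path: str | Path) -> list[MirnaAnnotation]:
    rows = _open_rows(path)
    try:
        header_lineno, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: empty annotation table")
    colidx = {name: i for i, name in enumerate(header)}
    for col in ("mirna_id", "has_expression", "brain_related"):
        if col not in colidx:
            raise ValueError(f"{path}:{header_lineno}: missing column {col!r}")
    out: list[MirnaAnnotation] = []
    seen: set[str] = set()
    for lineno, row in rows:
        mid = row[colidx["mirna_id"]]
        if mid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate annotation for {mid!r}")
        seen.add(mid)
        has_expr = _as_bool(row[colidx["has_expression"]], lineno, path)
        brain = _as_bool(row[colidx["brain_related"]], lineno, path)
        note = row[colidx["note"]] if "note" in colidx and len(row) > colidx["note"] else ""
        try:
            out.append(MirnaAnnotation(mid, has_expr, brain, note))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_mirna_annotation(annotations: Iterable[MirnaAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\thas_expression\tbrain_related\tnote\n")
        for a in annotations:
            fh.write(
                f"{a.mirna_id}\t{int(a.has_expression)}\t{int(a.brain_related)}\t{a.note}\n"
            )
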