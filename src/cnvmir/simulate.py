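"""Synthetic CNV cohorts with recorded ground truth.

The generator emulates the study design the pipeline analyses: five CNV
subgroups (de novo, familial, common-from-cases, common-from-controls, and
curated pathogenic regions), a multi-study population-variant database, a
clustered miRNA track, a uniform protein-coding-gene track, a miRNA→target
map with one planted pathway, and a curated expression/brain annotation.

Construction guarantees the planted structure:

- common CNVs coincide exactly with known-variant loci reported by at
  least two studies, so classification recovers them with fraction 1.0;
- rare (de novo / familial / pathogenic) CNVs are placed with zero overlap
  to any known-variant locus, so they classify rare unambiguously;
- subgroups with a miRNA bias multiplier > 1 preferentially centre their
  CNVs on miRNA loci (a CNV is hotspot-seeded with probability
  ``1 - 1/multiplier``), enriching their miRNA content;
- CNV lengths are log-normal per subgroup, matching the heavy-tailed mix
  of multi-megabase pathogenic regions and sub-megabase common variants.

Everything is deterministic for a given seed, and every emitted file
passes the corresponding reader's validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import CNVCall, GenomeBuild, GenomicInterval
from .io_formats import (
    AnnotationFeature,
    GeneSet,
    KnownVariantRecord,
    MirnaAnnotation,
    TargetMap,
    write_bed_genes,
    write_chrom_sizes,
    write_cnv_table,
    write_gff3_mirnas,
    write_gmt,
    write_known_variants,
    write_mirna_annotation,
    write_target_map,
)

__all__ = [
    "GroupSpec",
    "SimulationSpec",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "generate_cohort",
    "spike_worked_example",
]

#: hg18-like autosome + X/Y lengths (bp), the scale of the study's assembly
DEFAULT_CHROMOSOMES: dict[str, int] = {
    "chr1": 247_249_719, "chr2": 242_951_149, "chr3": 199_501_827,
    "chr4": 191_273_063, "chr5": 180_857_866, "chr6": 170_899_992,
    "chr7": 158_821_424, "chr8": 146_274_826, "chr9": 140_273_252,
    "chr10": 135_374_737, "chr11": 134_452_384, "chr12": 132_349_534,
    "chr13": 114_142_980, "chr14": 106_368_585, "chr15": 100_338_915,
    "chr16": 88_827_254, "chr17": 78_774_742, "chr18": 76_117_153,
    "chr19": 63_811_651, "chr20": 62_435_964, "chr21": 46_944_323,
    "chr22": 49_691_432, "chrX": 154_913_754, "chrY": 57_772_954,
}


@dataclass(frozen=True)
class GroupSpec:
    """Per-subgroup CNV generation parameters."""

    n_cnvs: int
    median_bp: float
    sigma: float  # log-scale dispersion of the log-normal size distribution
    mirna_bias: float = 1.0  # > 1 seeds CNVs on miRNA loci
    brain_fraction: float = 0.0  # of annotated miRNAs, fraction brain-related

    def __post_init__(self):
        if self.n_cnvs < 0 or self.median_bp <= 0 or self.sigma < 0:
            raise ValueError("invalid group spec")
        if self.mirna_bias <= 0:
            raise ValueError("mirna_bias must be positive")


def _default_groups() -> dict[str, GroupSpec]:
    # counts are the study's five subgroups (24 / 46 / 216 / 67 / 35 CNVs);
    # medians follow the observed size profile: multi-Mb de novo and
    # pathogenic regions, ~0.5 Mb common variants
    return {
        "de_novo": GroupSpec(24, 2.5e6, 0.6, mirna_bias=5.0, brain_fraction=0.55),
        "familial": GroupSpec(46, 0.55e6, 0.6, mirna_bias=1.0, brain_fraction=0.50),
        "common_case": GroupSpec(216, 0.45e6, 0.5, mirna_bias=1.0, brain_fraction=0.25),
        "common_control": GroupSpec(67, 0.50e6, 0.5, mirna_bias=1.0, brain_fraction=0.0),
        "decipher": GroupSpec(35, 2.5e6, 0.6, mirna_bias=5.0, brain_fraction=0.46),
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of one synthetic cohort."""

    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    n_mirnas: int = 2042  # miRBase-v19-scale human mature miRNA count
    mirna_hotspot_fraction: float = 0.3
    n_mirna_clusters: int = 60
    n_genes: int = 19905  # protein-coding gene count of the study's gene track
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    n_studies: int = 6
    targets_per_mirna: int = 25
    target_map_fraction: float = 0.5  # fraction of miRNAs with known targets
    planted_pathway: str = "PLANTED_PATHWAY"
    planted_effect: float = 0.8  # fraction of pathway genes from the planted pool
    pathway_size: int = 30
    n_decoy_pathways: int = 20
    expression_fraction: float = 0.25  # miRNAs with curated expression data

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name, value in (("n_mirnas", self.n_mirnas), ("n_genes", self.n_genes)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    seed: int
    true_class: dict[str, str]  # cnv_id -> subgroup label
    enrichment_direction: dict[str, str]  # subgroup -> enriched|neutral
    planted_pathway: str
    planted_genes: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """In-memory synthetic inputs plus their ground truth."""

    genome: GenomeBuild
    cnvs: list[CNVCall]
    known_variants: list[KnownVariantRecord]
    mirnas: list[AnnotationFeature]
    genes: list[AnnotationFeature]
    target_map: TargetMap
    gene_sets: list[GeneSet]
    annotations: list[MirnaAnnotation]
    truth: GroundTruth


def _place_uniform(length: int, genome: GenomeBuild, rng: np.random.Generator,
                   names: list[str], valid_counts: np.ndarray) -> GenomicInterval:
    probs = valid_counts / valid_counts.sum()
    ci = int(rng.choice(len(names), p=probs))
    max_start = genome[names[ci]] - length
    if max_start < 0:
        raise ValueError(f"length {length} exceeds chromosome {names[ci]}")
    start = int(rng.integers(0, max_start + 1))
    return GenomicInterval(names[ci], start, start + length)


def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(
        o.chrom == iv.chrom and iv.start < o.end and o.start < iv.end for o in others
    )


def simulate_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort in memory; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    genome = GenomeBuild(spec.chromosomes)
    names = list(genome)
    lengths_arr = np.array([genome[n] for n in names], dtype=np.int64)

    # --- miRNA track: a hotspot fraction in tight clusters, rest uniform
    mirnas: list[AnnotationFeature] = []
    n_hot = int(round(spec.n_mirnas * spec.mirna_hotspot_fraction))
    cluster_centres: list[GenomicInterval] = []
    if spec.n_mirna_clusters > 0 and n_hot > 0:
        for _ in range(spec.n_mirna_clusters):
            cluster_centres.append(
                _place_uniform(1, genome, rng, names, lengths_arr))
    mir_len = 22  # mature miRNA length
    positions: list[tuple[str, int]] = []
    for i in range(spec.n_mirnas):
        if i < n_hot and cluster_centres:
            centre = cluster_centres[int(rng.integers(0, len(cluster_centres)))]
            offset = int(rng.integers(-25_000, 25_000))
            start = min(max(0, centre.start + offset), genome[centre.chrom] - mir_len)
            positions.append((centre.chrom, start))
        else:
            iv = _place_uniform(mir_len, genome, rng, names, lengths_arr - mir_len + 1)
            positions.append((iv.chrom, iv.start))
    order = np.argsort([f"{c}:{s:012d}" for c, s in positions], kind="stable")
    for rank, idx in enumerate(order):
        chrom, start = positions[idx]
        mirnas.append(AnnotationFeature(
            GenomicInterval(chrom, start, start + mir_len),
            f"syn-miR-{rank + 1}", "mirna"))

    # --- protein-coding genes: uniform, ~30 kb spans
    genes: list[AnnotationFeature] = []
    for i in range(spec.n_genes):
        glen = int(rng.integers(5_000, 60_000))
        iv = _place_uniform(glen, genome, rng, names, np.maximum(lengths_arr - glen + 1, 0))
        genes.append(AnnotationFeature(iv, f"GENE{i + 1:05d}", "pcg"))

    # --- known-variant loci (common CNV anchors), each from >= 2 studies
    n_common = (spec.groups.get("common_case", GroupSpec(0, 1e5, 0.1)).n_cnvs
                + spec.groups.get("common_control", GroupSpec(0, 1e5, 0.1)).n_cnvs)
    n_loci = max(1, n_common // 2) if n_common else 0
    known: list[KnownVariantRecord] = []
    common_loci: list[GenomicInterval] = []
    for li in range(n_loci):
        length = max(1_000, int(rng.lognormal(math.log(0.4e6), 0.5)))
        iv = _place_uniform(length, genome, rng, names,
                            np.maximum(lengths_arr - length + 1, 0))
        common_loci.append(iv)
        n_rep = int(rng.integers(2, spec.n_studies + 1))
        studies = rng.choice(spec.n_studies, size=n_rep, replace=False)
        for s in studies:
            known.append(KnownVariantRecord(iv, f"study_{int(s) + 1}", f"var_{li + 1}"))

    # --- CNVs per subgroup
    cnvs: list[CNVCall] = []
    true_class: dict[str, str] = {}
    cohort_of = {"de_novo": "case", "familial": "case", "common_case": "case",
                 "common_control": "control", "decipher": "decipher"}
    mirna_positions = [(f.interval.chrom, f.interval.start) for f in mirnas]
    for label, gspec in spec.groups.items():
        common_like = label.startswith("common")
        p_hot = 0.0 if gspec.mirna_bias <= 1 else 1.0 - 1.0 / gspec.mirna_bias
        for j in range(gspec.n_cnvs):
            length = max(10_000, int(rng.lognormal(math.log(gspec.median_bp), gspec.sigma)))
            if common_like and common_loci:
                iv = common_loci[int(rng.integers(0, len(common_loci)))]
            else:
                iv = None
                for _ in range(500):
                    if mirna_positions and rng.random() < p_hot:
                        chrom, mstart = mirna_positions[
                            int(rng.integers(0, len(mirna_positions)))]
                        start = mstart - int(rng.integers(0, max(1, length - mir_len)))
                        start = min(max(0, start), genome[chrom] - length)
                        if start < 0:
                            continue
                        cand = GenomicInterval(chrom, start, start + length)
                    else:
                        cand = _place_uniform(
                            length, genome, rng, names,
                            np.maximum(lengths_arr - length + 1, 0))
                    # rare CNVs must not touch known-variant loci
                    if not _overlaps_any(cand, common_loci):
                        iv = cand
                        break
                if iv is None:
                    raise RuntimeError(
                        f"could not place a rare CNV of {length} bp away from "
                        "known-variant loci; genome too crowded")
            if label == "de_novo":
                inheritance = "de_novo"
            elif label == "familial":
                inheritance = "maternal" if rng.random() < 0.5 else "paternal"
            else:
                inheritance = "unknown"
            state = "gain" if rng.random() < 0.5 else "loss"
            sample = (f"ctrl{j + 1:03d}" if cohort_of[label] == "control"
                      else f"case{int(rng.integers(1, 214)):03d}"
                      if cohort_of[label] == "case" else f"decipher{j + 1:03d}")
            call = CNVCall(iv, sample, state, inheritance, cohort_of[label],
                           cnv_id=f"{label}_{j + 1}")
            cnvs.append(call)
            true_class[call.cnv_id] = label

    # --- target map and pathways
    gene_ids = [g.feature_id for g in genes]
    tmap_pairs: dict[str, set[str]] = {}
    n_with_targets = int(round(len(mirnas) * spec.target_map_fraction))
    for f in mirnas[:n_with_targets]:
        k = max(1, int(rng.poisson(spec.targets_per_mirna)))
        chosen = rng.choice(len(gene_ids), size=min(k, len(gene_ids)), replace=False)
        tmap_pairs[f.feature_id] = {gene_ids[int(c)] for c in chosen}
    target_map = TargetMap(tmap_pairs)

    # planted pathway: drawn mostly from miRNA-target genes located inside
    # rare CNVs — the gene pool the enrichment stage queries
    rare_intervals = [c.interval for c in cnvs
                      if true_class[c.cnv_id] in ("de_novo", "decipher")]
    all_targets = target_map.all_targets()
    pool = {
        g.feature_id for g in genes
        if g.feature_id in all_targets and _overlaps_any(g.interval, rare_intervals)
    }
    pool_list = sorted(pool)
    n_from_pool = min(len(pool_list), int(round(spec.pathway_size * spec.planted_effect)))
    planted: set[str] = set()
    if n_from_pool:
        idx = rng.choice(len(pool_list), size=n_from_pool, replace=False)
        planted = {pool_list[int(i)] for i in idx}
    while len(planted) < spec.pathway_size and len(planted) < len(gene_ids):
        planted.add(gene_ids[int(rng.integers(0, len(gene_ids)))])
    gene_sets = [GeneSet(spec.planted_pathway, "planted", frozenset(planted))]
    for d in range(spec.n_decoy_pathways):
        idx = rng.choice(len(gene_ids), size=min(spec.pathway_size, len(gene_ids)),
                         replace=False)
        gene_sets.append(GeneSet(f"DECOY_{d + 1:02d}", "decoy",
                                 frozenset(gene_ids[int(i)] for i in idx)))

    # --- expression / brain annotation per subgroup membership
    from .annotation import FeatureTrack, features_in_region  # local to avoid cycle
    mirna_track = FeatureTrack(mirnas)
    subgroup_of_mirna: dict[str, str] = {}
    for c in cnvs:
        for mid in features_in_region(c.interval, mirna_track):
            subgroup_of_mirna.setdefault(mid, true_class[c.cnv_id])
    annotations: list[MirnaAnnotation] = []
    for f in mirnas:
        has_expr = bool(rng.random() < spec.expression_fraction)
        brain = False
        if has_expr:
            label = subgroup_of_mirna.get(f.feature_id)
            brain_frac = spec.groups[label].brain_fraction if label else 0.1
            brain = bool(rng.random() < brain_frac)
        annotations.append(MirnaAnnotation(f.feature_id, has_expr, brain))

    truth = GroundTruth(
        seed=spec.seed,
        true_class=true_class,
        enrichment_direction={
            label: ("enriched" if g.mirna_bias > 1 else "neutral")
            for label, g in spec.groups.items()
        },
        planted_pathway=spec.planted_pathway,
        planted_genes=sorted(planted),
    )
    return SyntheticCohort(genome, cnvs, known, mirnas, genes, target_map,
                           gene_sets, annotations, truth)


def generate_cohort(spec: SimulationSpec, outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a cohort and write every pipeline input file under ``outdir``.

    Returns the mapping of logical input name to path, plus the ground
    truth (also written as a JSON side-car).  Byte-identical for a fixed
    spec (including seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec)
    paths = {
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "cnv_table": outdir / "cnvs.tsv",
        "known_variants": outdir / "known_variants.tsv",
        "mirna_gff3": outdir / "mirnas.gff3",
        "gene_bed": outdir / "genes.bed",
        "target_map": outdir / "target_map.tsv",
        "gene_sets": outdir / "pathways.gmt",
        "mirna_annotation": outdir / "mirna_annotation.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_chrom_sizes(cohort.genome, paths["chrom_sizes"])
    write_cnv_table(cohort.cnvs, paths["cnv_table"])
    write_known_variants(cohort.known_variants, paths["known_variants"])
    write_gff3_mirnas(cohort.mirnas, paths["mirna_gff3"])
    write_bed_genes(cohort.genes, paths["gene_bed"])
    write_target_map(cohort.target_map, paths["target_map"])
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_mirna_annotation(cohort.annotations, paths["mirna_annotation"])
    cohort.truth.to_json(paths["ground_truth"])
    return paths, cohort.truth


# ---------------------------------------------------------------------------
# hand-checkable worked example

#: brain-related miRNA loci (1-based inclusive printed coordinates) with the
#: subgroup feature each belongs to; a documented miniature of the study's
#: curated list
WORKED_MIRNAS: list[tuple[str, int, int, str, str]] = [
    ("chr1", 1_103_258, 1_103_279, "hsa-miR-200a/b", "de_novo"),
    ("chr1", 1_104_435, 1_104_456, "hsa-miR-429", "de_novo"),
    ("chr5", 87_962_684, 87_962_705, "hsa-miR-9", "de_novo"),
    ("chr5", 179_442_361, 179_442_382, "hsa-miR-340", "de_novo"),
    ("chr7", 99_691_233, 99_691_253, "hsa-miR-25", "de_novo"),
    ("chr7", 99_691_438, 99_691_460, "hsa-miR-93", "de_novo"),
    ("chr7", 99_691_625, 99_691_646, "hsa-miR-106b", "de_novo"),
    ("chr19", 4_770_712, 4_770_734, "hsa-miR-7", "de_novo"),
    ("chr20", 61_151_558, 61_151_579, "hsa-miR-1", "de_novo"),
    ("chr20", 61_809_866, 61_809_887, "hsa-miR-124", "de_novo"),
    ("chr1", 94_312_436, 94_312_455, "hsa-miR-760", "familial"),
    ("chr15", 45_725_296, 45_725_317, "hsa-miR-147b", "familial"),
    ("chr2", 32_757_280, 32_757_298, "hsa-miR-558", "common_case"),
]


def spike_worked_example(outdir: str | Path) -> dict[str, Path]:
    """Miniature fixture with documented miRNA loci for hand-checked counts.

    Places the curated brain-related miRNA loci (printed 1-based
    coordinates) on toy chromosomes, plus three CNVs: one de novo call
    spanning chr1:1,100,000-1,110,000 (contains hsa-miR-200a/b and
    hsa-miR-429), one spanning the chr7 cluster (miR-25/93/106b), and one
    miRNA-free familial call.  Deterministic: no randomness involved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = {}
    for chrom, _s, end, _n, _g in WORKED_MIRNAS:
        sizes[chrom] = max(sizes.get(chrom, 0), end + 1_000_000)
    genome = GenomeBuild(sizes)
    mirnas = [
        AnnotationFeature(GenomicInterval(chrom, start - 1, end), name, "mirna")
        for chrom, start, end, name, _g in WORKED_MIRNAS
    ]
    cnvs = [
        CNVCall(GenomicInterval("chr1", 1_099_999, 1_110_000), "caseA", "loss",
                "de_novo", "case", cnv_id="worked_denovo_1"),
        CNVCall(GenomicInterval("chr7", 99_600_000, 99_800_000), "caseB", "gain",
                "de_novo", "case", cnv_id="worked_denovo_2"),
        CNVCall(GenomicInterval("chr2", 10_000_000, 10_500_000), "caseC", "loss",
                "maternal", "case", cnv_id="worked_familial_nomirna"),
    ]
    paths = {
        "chrom_sizes": outdir / "worked.chrom.sizes",
        "cnv_table": outdir / "worked_cnvs.tsv",
        "mirna_gff3": outdir / "worked_mirnas.gff3",
    }
    write_chrom_sizes(genome, paths["chrom_sizes"])
    write_cnv_table(cnvs, paths["cnv_table"])
    write_gff3_mirnas(mirnas, paths["mirna_gff3"])
    return paths
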