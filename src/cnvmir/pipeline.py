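"""End-to-end orchestration: classify, merge, annotate, compare, resample, enrich.

A single declarative config (YAML or a ``PipelineConfig`` built in code)
drives every stage; all thresholds (overlap fractions, study minimum,
replicate count, adjP cutoff, top-k) live in the config and are captured,
together with input checksums and the seed, in a run manifest sufficient
to re-run bit-identically.  Stages write TSV/JSON reports only under the
output directory and never mutate their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    FeatureTrack,
    GroupSummary,
    summarize_cnvr,
    summarize_group,
    write_cnvr_content_table,
    write_group_summary_table,
)
from .classification import (
    ClassificationConfig,
    classify_cnv,
    KnownVariantIndex,
    partition_cohort,
    write_classification_report,
)
from .coverage_null import NullConfig, run_coverage_null
from .enrichment import (
    brain_fraction_report,
    mirnas_targeting,
    targeted_genes,
    two_stage_enrichment,
    write_enrichment_table,
)
from .genome import merge_to_cnvrs
from .io_formats import (
    provenance_block,
    read_bed_genes,
    read_chrom_sizes,
    read_cnv_table,
    read_gff3_mirnas,
    read_gmt,
    read_known_variants,
    read_mirna_annotation,
    read_target_map,
)
from .stats import fisher_fraction_test, pairwise_density_comparisons

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

SUBGROUPS = ("de_novo", "familial", "common_case", "common_control", "decipher")


@dataclass
class PipelineConfig:
    chrom_sizes: str
    cnv_table: str
    known_variants: str
    mirna_gff3: str
    gene_bed: str
    target_map: str = ""
    gene_sets: str = ""
    mirna_annotation: str = ""
    output_dir: str = "results"
    seed: int = 0
    cnv_coords: str = "1-based"
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    replicates: int = 1000
    adjp_threshold: float = 0.05
    top_k: int = 10
    stages: tuple[str, ...] = ("classify", "merge", "annotate", "compare",
                               "shuffle", "enrich")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cc = raw.pop("classification", {})
        if isinstance(cc, dict):
            raw["classification"] = ClassificationConfig(**cc)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: input identity
        is captured by checksum in the manifest, and outputs must not
        depend on where files happen to live)."""
        params = asdict(self)
        for key in ("chrom_sizes", "cnv_table", "known_variants", "mirna_gff3",
                    "gene_bed", "target_map", "gene_sets", "mirna_annotation",
                    "output_dir"):
            params.pop(key, None)
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every enabled stage in order; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = provenance_block(
        tool=f"cnvmir {__version__}", config_hash=config.config_hash(),
        seed=config.seed,
    )
    checksums: dict[str, str] = {}
    counts: dict[str, int] = {}

    genome = read_chrom_sizes(config.chrom_sizes)
    cnvs = read_cnv_table(config.cnv_table, genome, coords=config.cnv_coords)
    known = read_known_variants(config.known_variants, genome)
    mirnas = read_gff3_mirnas(config.mirna_gff3, genome)
    genes = read_bed_genes(config.gene_bed, genome)
    for name in ("chrom_sizes", "cnv_table", "known_variants", "mirna_gff3",
                 "gene_bed", "target_map", "gene_sets", "mirna_annotation"):
        path = getattr(config, name)
        if path:
            checksums[name] = _checksum(path)
    counts["cnvs"] = len(cnvs)
    counts["known_variants"] = len(known)
    counts["mirnas"] = len(mirnas)
    counts["genes"] = len(genes)

    index = KnownVariantIndex(known)
    mirna_track = FeatureTrack(mirnas)
    gene_track = FeatureTrack(genes)

    # --- classify ---------------------------------------------------------
    groups: dict[str, list] = {label: [] for label in SUBGROUPS}
    if "classify" in config.stages:
        try:
            classified = [
                classify_cnv(c, index, config.classification,
                             split_rare=(c.cohort == "case"))
                for c in cnvs if c.cohort != "decipher"
            ]
        except ValueError as exc:
            raise RuntimeError(f"stage classify failed: {exc}") from exc
        write_classification_report(classified, outdir / "classification.tsv", prov)
        groups = partition_cohort(cnvs, index, config.classification)
        counts["classified"] = len(classified)
    else:
        for c in cnvs:  # fall back to the cohort column only
            if c.cohort == "decipher":
                groups["decipher"].append(c)

    # --- merge ------------------------------------------------------------
    cnvrs_by_group = {}
    if "merge" in config.stages:
        for label in SUBGROUPS:
            cnvrs_by_group[label] = merge_to_cnvrs(groups.get(label, []), label)
        counts["cnvrs"] = sum(len(v) for v in cnvrs_by_group.values())

    # --- annotate ---------------------------------------------------------
    summaries_by_group: dict[str, list] = {}
    group_rows: list[GroupSummary] = []
    if "annotate" in config.stages:
        all_summaries = []
        for label in SUBGROUPS:
            cnvrs = cnvrs_by_group.get(label, [])
            summaries = [summarize_cnvr(r, mirna_track, gene_track) for r in cnvrs]
            summaries_by_group[label] = summaries
            all_summaries.extend(summaries)
            if cnvrs:
                group_rows.append(
                    summarize_group(label, groups.get(label, []), cnvrs, summaries))
        write_cnvr_content_table(all_summaries, outdir / "cnvr_content.tsv", prov)
        write_group_summary_table(group_rows, outdir / "group_summary.tsv", prov)
        counts["group_rows"] = len(group_rows)

    # --- compare (pairwise density rank-sum) ------------------------------
    if "compare" in config.stages and summaries_by_group:
        samples = {
            label: [s.mirna_density for s in summ]
            for label, summ in summaries_by_group.items() if summ
        }
        comparisons = pairwise_density_comparisons(samples)
        with open(outdir / "density_comparisons.tsv", "w") as fh:
            fh.write(prov)
            fh.write("group_a\tgroup_b\tstatistic\tvalue\tp_value\tmethod\n")
            for c in comparisons:
                fh.write(f"{c.group_a}\t{c.group_b}\t{c.statistic_name}\t"
                         f"{c.statistic:.6g}\t{c.p_value:.4g}\t{c.method_note}\n")
        counts["comparisons"] = len(comparisons)

    # --- shuffle (coverage null) ------------------------------------------
    if "shuffle" in config.stages and cnvrs_by_group:
        rows = []
        for gi, label in enumerate(SUBGROUPS):
            cnvrs = cnvrs_by_group.get(label, [])
            if not cnvrs:
                continue
            for ti, track in enumerate((mirna_track, gene_track)):
                # distinct deterministic stream per subgroup x track
                sub_seed = config.seed * 100 + gi * 2 + ti
                result = run_coverage_null(
                    cnvrs, track, genome,
                    NullConfig(replicates=config.replicates, seed=sub_seed),
                    subgroup=label,
                )
                rows.append(result)
        with open(outdir / "coverage_null.tsv", "w") as fh:
            fh.write(prov)
            fh.write("subgroup\ttrack\tobserved_fraction\tnull_mean\tp_value\tseed\n")
            for r in rows:
                fh.write(f"{r.subgroup}\t{r.track_class}\t{r.observed_fraction:.6g}\t"
                         f"{r.null_mean:.6g}\t{r.p_value:.4g}\t{r.seed}\n")
        counts["null_rows"] = len(rows)

    # --- enrich ------------------------------------------------------------
    if "enrich" in config.stages and config.target_map and config.gene_sets:
        tmap = read_target_map(config.target_map)
        sets = read_gmt(config.gene_sets)
        annotations = (read_mirna_annotation(config.mirna_annotation)
                       if config.mirna_annotation else [])
        universe = {g.feature_id for g in genes}
        fractions: list[tuple[str, int, int]] = []
        with open(outdir / "targeted_genes.tsv", "w") as fh:
            fh.write(prov)
            fh.write("subgroup\tn_genes\tn_targeted\tpercent_targeted\t"
                     "n_mirnas\tn_with_data\tn_brain\tpercent_brain\ttargeting_mirnas\n")
            for label in SUBGROUPS:
                summaries = summaries_by_group.get(label, [])
                if not summaries:
                    continue
                group_genes = set().union(*(s.gene_ids for s in summaries))
                group_mirnas = set().union(*(s.mirna_ids for s in summaries))
                rep = targeted_genes(label, group_genes, tmap)
                brain = brain_fraction_report(label, sorted(group_mirnas), annotations)
                tg_mirnas = mirnas_targeting(set(rep.targeted), tmap)
                fh.write(
                    f"{label}\t{rep.n_genes}\t{rep.n_targeted}\t"
                    f"{rep.percent_targeted:.1f}\t{brain.n_mirnas}\t"
                    f"{brain.n_with_data}\t{brain.n_brain}\t"
                    f"{brain.percent_brain:.0f}\t{','.join(sorted(tg_mirnas))}\n"
                )
                fractions.append((label, rep.n_targeted, rep.n_genes))
                stage1, stage2 = two_stage_enrichment(
                    group_genes & universe, tmap, sets, universe,
                    config.adjp_threshold, config.top_k)
                write_enrichment_table(
                    stage2, outdir / f"pathways_{label}.tsv", prov)
        # pairwise Fisher comparison of targeted-gene fractions
        with open(outdir / "fraction_comparisons.tsv", "w") as fh:
            fh.write(prov)
            fh.write("group_a\tgroup_b\todds_ratio\tp_value\n")
            for i in range(len(fractions)):
                for j in range(i + 1, len(fractions)):
                    la, ka, na = fractions[i]
                    lb, kb, nb = fractions[j]
                    if na and nb:
                        res = fisher_fraction_test(ka, na, kb, nb, la, lb)
                        fh.write(f"{la}\t{lb}\t{res.statistic:.4g}\t"
                                 f"{res.p_value:.4g}\n")
        counts["enrich_groups"] = len([l for l in SUBGROUPS
                                       if summaries_by_group.get(l)])

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        input_checksums=checksums,
        stage_counts=counts,
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
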