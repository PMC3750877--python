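"""Classification rules: coverage fractions, class assignment, partition."""

import numpy as np
import pytest

from cnvmir.classification import (
    ClassificationConfig,
    KnownVariantIndex,
    classify_cnv,
    covered_fraction,
    partition_cohort,
)
from cnvmir.genome import CNVCall, GenomicInterval
from cnvmir.io_formats import KnownVariantRecord


def _cnv(start, end, inheritance="de_novo", cohort="case", chrom="chr1", cnv_id=""):
    return CNVCall(GenomicInterval(chrom, start, end), "s1", "loss",
                   inheritance, cohort, cnv_id=cnv_id)


def _kv(start, end, study, chrom="chr1", vid="v"):
    return KnownVariantRecord(GenomicInterval(chrom, start, end), study, vid)


class TestCoveredFraction:
    def test_exact_coincidence_two_studies(self):
        cnv = _cnv(100, 200)
        known = [_kv(100, 200, "S1"), _kv(100, 200, "S2")]
        assert covered_fraction(cnv, known) == (1.0, 2)

    def test_partial_single_study(self):
        cnv = _cnv(0, 1000)
        assert covered_fraction(cnv, [_kv(0, 400, "S1")]) == (0.4, 1)

    def test_no_overlap(self):
        assert covered_fraction(_cnv(0, 100), [_kv(500, 600, "S1")]) == (0.0, 0)

    def test_union_not_double_counted(self):
        cnv = _cnv(0, 100)
        known = [_kv(0, 60, "S1"), _kv(40, 100, "S2")]
        frac, studies = covered_fraction(cnv, known)
        assert frac == 1.0 and studies == 2

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            cs = int(rng.integers(0, 5_000))
            cnv = _cnv(cs, cs + int(rng.integers(50, 800)))
            known = []
            for k in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, 5_500))
                known.append(_kv(s, s + int(rng.integers(10, 600)), f"S{k % 3}"))
            frac, studies = covered_fraction(cnv, known)
            cnv_bases = set(range(cnv.interval.start, cnv.interval.end))
            union = set()
            overlapping_studies = set()
            for r in known:
                bases = set(range(r.interval.start, r.interval.end)) & cnv_bases
                if bases:
                    union |= bases
                    overlapping_studies.add(r.study_id)
            assert frac == pytest.approx(len(union) / len(cnv_bases))
            assert studies == len(overlapping_studies)


class TestClassifyCnv:
    def test_full_coverage_two_studies_is_common(self):
        cnv = _cnv(100, 200, inheritance="unknown")
        known = [_kv(100, 200, "S1"), _kv(100, 200, "S2")]
        assert classify_cnv(cnv, known, split_rare=False).cnv_class == "common"

    def test_no_overlap_de_novo(self):
        assert classify_cnv(_cnv(0, 100, "de_novo"), []).cnv_class == "de_novo"

    def test_partial_overlap_maternal_is_familial(self):
        cnv = _cnv(0, 1000, inheritance="maternal")
        res = classify_cnv(cnv, [_kv(0, 400, "S1")])
        assert res.cnv_class == "familial"
        assert res.covered_fraction == 0.4

    def test_midrange_coverage_is_ambiguous(self):
        cnv = _cnv(0, 1000, "de_novo")
        res = classify_cnv(cnv, [_kv(0, 700, "S1"), _kv(0, 700, "S2")])
        assert res.cnv_class == "ambiguous"

    def test_full_coverage_one_study_is_ambiguous(self):
        cnv = _cnv(0, 1000, "de_novo")
        res = classify_cnv(cnv, [_kv(0, 1000, "S1")])
        assert res.cnv_class == "ambiguous"

    def test_treat_as_rare_policy(self):
        cnv = _cnv(0, 1000, "de_novo")
        config = ClassificationConfig(ambiguous_policy="treat_as_rare")
        res = classify_cnv(cnv, [_kv(0, 700, "S1")], config)
        assert res.cnv_class == "de_novo"

    def test_rare_with_unknown_inheritance_errors(self):
        with pytest.raises(ValueError, match="unknown inheritance"):
            classify_cnv(_cnv(0, 100, "unknown"), [])

    def test_deterministic(self):
        cnv = _cnv(0, 1000, "maternal")
        known = [_kv(0, 300, "S1")]
        assert classify_cnv(cnv, known) == classify_cnv(cnv, known)

    def test_min_studies_monotonicity(self):
        """Raising min_studies never moves a CNV from rare to common."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = int(rng.integers(0, 1000))
            cnv = _cnv(s, s + int(rng.integers(100, 500)), "de_novo")
            known = [
                _kv(int(rng.integers(0, 1200)), int(rng.integers(1200, 2400)),
                    f"S{k}") for k in range(int(rng.integers(0, 5)))
            ]
            previous_common = None
            for ms in (1, 2, 3, 4):
                cls = classify_cnv(
                    cnv, known,
                    ClassificationConfig(min_studies=ms,
                                         ambiguous_policy="treat_as_rare"),
                ).cnv_class
                is_common = cls == "common"
                if previous_common is not None:
                    assert not (is_common and not previous_common)
                previous_common = is_common


class TestPartition:
    def test_toy_partition(self):
        known = [_kv(0, 1000, "S1"), _kv(0, 1000, "S2")]
        cnvs = [
            _cnv(0, 1000, "unknown", "case", cnv_id="c1"),     # common
            _cnv(5000, 6000, "de_novo", "case", cnv_id="c2"),  # de novo
            _cnv(7000, 8000, "paternal", "case", cnv_id="c3"), # familial
            _cnv(0, 1000, "unknown", "control", cnv_id="c4"),  # common control
            _cnv(2000, 9000, "unknown", "decipher", cnv_id="c5"),
            _cnv(9000, 9500, "unknown", "control", cnv_id="c6"),  # rare control
        ]
        groups = partition_cohort(cnvs, known)
        assert [c.cnv_id for c in groups["common_case"]] == ["c1"]
        assert [c.cnv_id for c in groups["de_novo"]] == ["c2"]
        assert [c.cnv_id for c in groups["familial"]] == ["c3"]
        assert [c.cnv_id for c in groups["common_control"]] == ["c4"]
        assert [c.cnv_id for c in groups["decipher"]] == ["c5"]
        assert [c.cnv_id for c in groups["rare_control"]] == ["c6"]

    def test_all_control_cohort(self, caplog):
        known = [_kv(0, 1000, "S1"), _kv(0, 1000, "S2")]
        cnvs = [_cnv(0, 1000, "unknown", "control", cnv_id="a"),
                _cnv(5000, 5500, "unknown", "control", cnv_id="b")]
        with caplog.at_level("WARNING"):
            groups = partition_cohort(cnvs, known)
        assert len(groups["common_control"]) == 1
        assert len(groups["rare_control"]) == 1
        assert "control-cohort CNVs classified rare" in caplog.text
        for label in ("de_novo", "familial", "common_case", "decipher"):
            assert groups[label] == []

    def test_synthetic_cohort_recovery(self, small_cohort):
        """Planted classes are recovered exactly on an unambiguous cohort."""
        groups = partition_cohort(small_cohort.cnvs, small_cohort.known_variants)
        truth = small_cohort.truth.true_class
        recovered = {}
        for label in ("de_novo", "familial", "common_case", "common_control",
                      "decipher"):
            for c in groups[label]:
                recovered[c.cnv_id] = label
        assert recovered == truth
        assert groups["ambiguous"] == [] and groups["rare_control"] == []

    def test_every_cnv_lands_in_exactly_one_class(self, small_cohort):
        groups = partition_cohort(small_cohort.cnvs, small_cohort.known_variants)
        all_ids = [c.cnv_id for members in groups.values() for c in members]
        assert sorted(all_ids) == sorted(c.cnv_id for c in small_cohort.cnvs)
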