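"""Tests for the variant retention rules and pipeline."""

import importlib.resources as resources
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cllburden.variants import (FilterConfig, MutationMatrix, VariantRecord,
                                Verdict, apply_quality_filters,
                                classify_pathogenicity, decisions_to_frame,
                                filter_polymorphisms, read_variant_tsv,
                                read_variant_vcf, records_from_frame,
                                run_filter_pipeline, write_variant_tsv,
                                write_variant_vcf)


def make_record(**kw):
    base = dict(patient_id="P1", gene="ATM", chrom="chr11", pos=100,
                ref="A", alt="T", depth=500, alt_reads=50, vaf=0.1,
                is_exonic=True, is_hotspot=False, sift_class="deleterious",
                cadd_phred=30.0, pop_maf=None, in_pop_db=False)
    base.update(kw)
    return VariantRecord(**base)


def load_fixture():
    path = resources.files("cllburden.data") / "filter_fixture.tsv"
    df = pd.read_csv(path, sep="\t")
    return df, records_from_frame(df[df.columns[:15]])


class TestQualityFilters:
    def test_stated_thresholds_pass(self):
        rec = make_record(depth=150, alt_reads=8, vaf=None)
        d = apply_quality_filters([rec])[0]
        assert d.verdict == Verdict.RETAINED and d.failed_rules == ()

    def test_depth_boundary_is_inclusive(self):
        ok = make_record(depth=100, alt_reads=5, vaf=0.05)
        bad = make_record(depth=99, alt_reads=50, vaf=None)
        assert apply_quality_filters([ok])[0].verdict == Verdict.RETAINED
        d = apply_quality_filters([bad])[0]
        assert d.verdict == Verdict.REJECTED and d.failed_rules == ("min_depth",)

    def test_vaf_boundary_is_inclusive(self):
        rec = make_record(depth=250, alt_reads=5, vaf=0.02)
        assert apply_quality_filters([rec])[0].verdict == Verdict.RETAINED

    def test_missing_fields_go_to_review(self):
        rec = make_record(depth=None, alt_reads=None, vaf=0.1)
        d = apply_quality_filters([rec])[0]
        assert d.verdict == Verdict.MANUAL_REVIEW
        assert d.failed_rules == ("missing_quality_field",)

    def test_vaf_mismatch_goes_to_review(self):
        rec = make_record(depth=100, alt_reads=50, vaf=0.1)  # 0.5 stated as 0.1
        d = apply_quality_filters([rec])[0]
        assert d.verdict == Verdict.MANUAL_REVIEW
        assert d.failed_rules == ("vaf_mismatch",)


class TestPathogenicity:
    def test_hotspot_overrides_tolerated_scores(self):
        rec = make_record(is_hotspot=True, sift_class="tolerated", cadd_phred=2.0)
        assert classify_pathogenicity(rec) == Verdict.RETAINED

    def test_tolerated_low_cadd_rejected(self):
        rec = make_record(sift_class="tolerated", cadd_phred=5.0)
        assert classify_pathogenicity(rec) == Verdict.REJECTED

    def test_no_scores_reviewed(self):
        rec = make_record(sift_class=None, cadd_phred=None)
        assert classify_pathogenicity(rec) == Verdict.MANUAL_REVIEW

    def test_cadd_alone_rescues_tolerated(self):
        rec = make_record(sift_class="tolerated", cadd_phred=28.0)
        assert classify_pathogenicity(rec) == Verdict.RETAINED


class TestPolymorphism:
    def test_common_variant_rejected(self):
        assert filter_polymorphisms(make_record(pop_maf=0.02)) == "rejected_polymorphism"

    def test_maf_cutoff_inclusive(self):
        assert filter_polymorphisms(make_record(pop_maf=0.01)) == "rejected_polymorphism"

    def test_rare_db_entry_reviewed(self):
        rec = make_record(in_pop_db=True, pop_maf=0.0005)
        assert filter_polymorphisms(rec) == "manual_review"

    def test_novel_variant_kept(self):
        assert filter_polymorphisms(make_record(in_pop_db=False)) == "kept"


class TestPipeline:
    def test_fixture_verdicts_and_failed_rules(self):
        df, recs = load_fixture()
        matrix, decisions = run_filter_pipeline(recs)
        for d, (_, row) in zip(decisions, df.iterrows()):
            expected_failed = (set() if pd.isna(row["expected_failed_rules"])
                               else set(str(row["expected_failed_rules"]).split(";")))
            assert d.verdict.value == row["expected_verdict"], d.record.key
            assert set(d.failed_rules) == expected_failed, d.record.key
        n_expected = (df["expected_verdict"] == "retained").sum()
        assert int(matrix.counts.to_numpy().sum()) == n_expected

    def test_empty_input_gives_empty_outputs(self):
        matrix, decisions = run_filter_pipeline([])
        assert matrix.counts.empty and decisions == []

    def test_duplicates_deduplicated_with_warning(self):
        rec = make_record()
        with pytest.warns(UserWarning, match="duplicate"):
            matrix, decisions = run_filter_pipeline([rec, rec])
        assert len(decisions) == 1
        assert int(matrix.counts.to_numpy().sum()) == 1

    def test_review_policy_include_keeps_reviewed_records(self):
        rec = make_record(in_pop_db=True, pop_maf=0.0001)
        m_excl, _ = run_filter_pipeline([rec], FilterConfig())
        m_incl, _ = run_filter_pipeline([rec], FilterConfig(review_policy="include"))
        assert int(m_excl.counts.to_numpy().sum()) == 0
        assert int(m_incl.counts.to_numpy().sum()) == 1

    def test_verdicts_independent_of_input_order(self):
        _, recs = load_fixture()
        _, base = run_filter_pipeline(recs)
        by_key = {d.record.key: (d.verdict, d.failed_rules) for d in base}
        shuffled = recs[:]
        random.Random(7).shuffle(shuffled)
        _, perm = run_filter_pipeline(shuffled)
        assert {d.record.key: (d.verdict, d.failed_rules) for d in perm} == by_key

    def test_rejections_name_rules_and_retained_name_none(self):
        _, recs = load_fixture()
        _, decisions = run_filter_pipeline(recs)
        for d in decisions:
            if d.verdict == Verdict.RETAINED:
                assert d.failed_rules == ()
            else:
                assert len(d.failed_rules) >= 1

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tightening_thresholds_never_retains_more(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(30):
            depth = int(rng.integers(50, 400))
            alt = int(rng.integers(1, max(2, depth // 4)))
            recs.append(make_record(
                patient_id=f"P{i % 5}", pos=100 + i, depth=depth,
                alt_reads=alt, vaf=None,
                sift_class=["deleterious", "tolerated", None][int(rng.integers(3))],
                cadd_phred=float(rng.uniform(0, 40)),
                pop_maf=float(rng.uniform(0, 0.03)) if rng.random() < 0.5 else None,
                in_pop_db=bool(rng.random() < 0.3)))
        base_cfg = FilterConfig(min_depth=100, min_alt_reads=5, min_vaf=0.02,
                                cadd_cutoff=20.0)
        base, _ = run_filter_pipeline(recs, base_cfg)
        n_base = int(base.counts.to_numpy().sum())
        for tight in (FilterConfig(min_depth=150), FilterConfig(min_alt_reads=8),
                      FilterConfig(min_vaf=0.05), FilterConfig(cadd_cutoff=30.0)):
            m, _ = run_filter_pipeline(recs, tight)
            assert int(m.counts.to_numpy().sum()) <= n_base

    def test_audit_table_has_one_row_per_record(self):
        _, recs = load_fixture()
        _, decisions = run_filter_pipeline(recs)
        audit = decisions_to_frame(decisions)
        assert len(audit) == len(recs)
        assert {"verdict", "failed_rules", "rule_trace"} <= set(audit.columns)


class TestRecordValidation:
    def test_alt_reads_cannot_exceed_depth(self):
        with pytest.raises(ValueError):
            make_record(depth=10, alt_reads=20, vaf=None)

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            make_record(pos=0)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        _, recs = load_fixture()
        path = tmp_path / "calls.tsv"
        write_variant_tsv(recs, path)
        back = read_variant_tsv(path)
        assert back == recs

    def test_vcf_round_trip(self, tmp_path):
        _, recs = load_fixture()
        path = tmp_path / "calls.vcf"
        write_variant_vcf(recs, path)
        back = read_variant_vcf(path)
        assert {r.key for r in back} == {r.key for r in recs}
        # verdicts survive the VCF detour
        m1, _ = run_filter_pipeline(recs)
        m2, _ = run_filter_pipeline(back)
        assert m1 == m2


class TestMutationMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            MutationMatrix(pd.DataFrame({"ATM": [-1]}, index=["P1"]))

    def test_binary_view_thresholds_counts(self):
        m = MutationMatrix(pd.DataFrame({"ATM": [0, 2], "TP53": [1, 0]},
                                        index=["P1", "P2"]))
        assert m.binary.to_numpy().tolist() == [[0, 1], [1, 0]]

    def test_csv_round_trip(self, tmp_path):
        m = MutationMatrix(pd.DataFrame({"ATM": [0, 2]}, index=["P1", "P2"]))
        m.to_csv(tmp_path / "m.csv")
        assert MutationMatrix.from_csv(tmp_path / "m.csv") == m
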