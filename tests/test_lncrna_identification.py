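"""Filter-cascade semantics, classification, and novelty matching."""

import dataclasses

import pandas as pd
import pytest

from lncdissect.annotation_io import ExpressionMatrix, TranscriptModel, TranscriptSet
from lncdissect.exceptions import ValidationError
from lncdissect.lncrna_identification import (
    FILTER_NAMES,
    FilterThresholds,
    ScoreRule,
    apply_filter_cascade,
    called_ids,
    classify_lncrna,
    identify_lncrnas,
    match_known,
    records_to_frame,
)
from lncdissect.synthetic_data import design_frame

from _oracles import brute_force_classify


def _expr(ids, value=10.0):
    design = design_frame()
    values = pd.DataFrame(value, index=list(ids), columns=design["sample"])
    return ExpressionMatrix(values, design)


def _noncoding_scores(ids):
    return pd.DataFrame(
        {"cnci": -1.0, "cpc": -1.0, "pfam_evalue": 1.0, "phylocsf": -100.0},
        index=list(ids),
    )


def _cascade(ts, ref=None, scores=None, expr=None, th=None):
    ref = ref if ref is not None else TranscriptSet()
    ids = [t.transcript_id for t in ts]
    scores = scores if scores is not None else _noncoding_scores(ids)
    expr = expr if expr is not None else _expr(ids)
    return apply_filter_cascade(ts, expr, scores, ref, th)


def _two_exon(tid, total_len, chrom="chr1", strand="+", start=1000):
    half = total_len // 2
    return TranscriptModel(
        tid, f"g_{tid}", chrom, strand,
        ((start, start + half), (start + half + 500, start + 500 + total_len)),
    )


class TestCascadeFilters:
    def test_mature_length_exactly_200_fails_strict_cutoff(self):
        ts = TranscriptSet([_two_exon("t200", 200), _two_exon("t201", 201)])
        records = {r.transcript_id: r for r in _cascade(ts)}
        assert not records["t200"].filter_audit["length"]
        assert not records["t200"].final_call
        assert records["t201"].filter_audit["length"]
        assert records["t201"].final_call

    def test_single_exon_transcript_rejected_even_if_long(self):
        t = TranscriptModel("mono", "g", "chr1", "+", ((0, 5000),))
        rec = _cascade(TranscriptSet([t]))[0]
        assert rec.filter_audit["length"]
        assert not rec.filter_audit["exon_count"]
        assert not rec.final_call

    def test_audit_records_every_filter_even_after_first_failure(self):
        t = TranscriptModel("mono", "g", "chr1", "+", ((0, 50),))  # fails length+exons
        rec = _cascade(TranscriptSet([t]))[0]
        assert set(rec.filter_audit) == set(FILTER_NAMES)

    def test_expression_rule_any_vs_all(self):
        ts = TranscriptSet([_two_exon("t", 400)])
        design = design_frame()
        values = pd.DataFrame(0.0, index=["t"], columns=design["sample"])
        values.iloc[0, 0] = 1.0  # expressed in one sample only
        expr = ExpressionMatrix(values, design)
        any_rec = _cascade(ts, expr=expr)[0]
        assert any_rec.filter_audit["expression"]
        all_rec = _cascade(ts, expr=expr, th=FilterThresholds(fpkm_rule="all_samples"))[0]
        assert not all_rec.filter_audit["expression"]

    def test_candidate_without_expression_row_is_validation_error(self):
        ts = TranscriptSet([_two_exon("seen", 400), _two_exon("unseen", 400, start=9000)])
        with pytest.raises(ValidationError, match="unseen"):
            apply_filter_cascade(ts, _expr(["seen"]), _noncoding_scores(["seen", "unseen"]),
                                 TranscriptSet())

    def test_same_strand_coding_overlap_excludes(self):
        cand = _two_exon("cand", 400, strand="+")
        ref = TranscriptSet([TranscriptModel("ref", "rg", "chr1", "+",
                                             ((1000, 1100),), biotype="protein_coding")])
        rec = _cascade(TranscriptSet([cand]), ref=ref)[0]
        assert not rec.filter_audit["coding_overlap"]

    def test_opposite_strand_exonic_overlap_retained_for_antisense(self):
        cand = _two_exon("cand", 400, strand="+")
        ref = TranscriptSet([TranscriptModel("ref", "rg", "chr1", "-",
                                             ((1000, 1100),), biotype="protein_coding")])
        rec = _cascade(TranscriptSet([cand]), ref=ref)[0]
        assert rec.filter_audit["coding_overlap"]
        assert rec.final_call

    def test_intronic_containment_without_exon_contact_excluded(self):
        # candidate inside the intron of an opposite-strand gene: span overlap
        # but no exonic overlap -> neither lincRNA nor antisense -> filtered
        cand = TranscriptModel("cand", "g", "chr1", "+", ((2000, 2200), (2400, 2600)))
        ref = TranscriptSet([TranscriptModel("ref", "rg", "chr1", "-",
                                             ((1000, 1500), (5000, 5500)),
                                             biotype="protein_coding")])
        rec = _cascade(TranscriptSet([cand]), ref=ref)[0]
        assert not rec.filter_audit["coding_overlap"]

    def test_small_rna_exonic_overlap_excludes(self):
        cand = _two_exon("cand", 400)
        ref = TranscriptSet([TranscriptModel("mir", "mg", "chr1", "+",
                                             ((1000, 1080),), biotype="miRNA")])
        rec = _cascade(TranscriptSet([cand]), ref=ref)[0]
        assert not rec.filter_audit["noncoding_overlap"]

    def test_missing_score_row_fails_by_default_and_passes_when_configured(self):
        ts = TranscriptSet([_two_exon("t", 400)])
        empty_scores = _noncoding_scores([])
        rec = _cascade(ts, scores=empty_scores)[0]
        assert not rec.final_call
        rec2 = _cascade(ts, scores=empty_scores,
                        th=FilterThresholds(missing_score_fails=False))[0]
        assert rec2.final_call

    def test_as_printed_preset_flips_retained_sides(self):
        th = FilterThresholds.as_printed()
        assert th.cnci.passes(0.5) and not th.cnci.passes(-0.5)
        assert th.phylocsf.passes(-10.0) and not th.phylocsf.passes(-30.0)
        default = FilterThresholds()
        assert default.cnci.passes(-0.5) and not default.cnci.passes(0.5)


class TestCascadeProperties:
    def test_monotone_under_threshold_tightening(self, dataset):
        base = FilterThresholds()
        baseline = called_ids(apply_filter_cascade(
            dataset.transcripts, dataset.expression, dataset.scores,
            dataset.truth.reference, base))
        tighter = [
            FilterThresholds(min_length_bp=400),
            FilterThresholds(min_exons=3),
            FilterThresholds(min_fpkm=5.0),
            FilterThresholds(min_fpkm=0.5, fpkm_rule="all_samples"),
            FilterThresholds(cnci=ScoreRule(-1.0, "below")),
            FilterThresholds(pfam=ScoreRule(0.1, "above")),
            FilterThresholds(phylocsf=ScoreRule(-100.0, "below")),
        ]
        for th in tighter:
            called = called_ids(apply_filter_cascade(
                dataset.transcripts, dataset.expression, dataset.scores,
                dataset.truth.reference, th))
            assert called <= baseline

    def test_called_records_partition_into_the_two_classes(self, dataset):
        records = identify_lncrnas(
            dataset.transcripts, dataset.expression, dataset.scores,
            dataset.truth.reference, dataset.truth.known_lncrnas)
        called = [r for r in records if r.final_call]
        assert all(r.lnc_class in ("lincRNA", "antisense") for r in called)
        n_linc = sum(r.lnc_class == "lincRNA" for r in called)
        n_anti = sum(r.lnc_class == "antisense" for r in called)
        assert n_linc + n_anti == len(called)
        assert all(r.novelty in ("annotated", "novel") for r in called)
        assert all(r.lnc_class == "none" and r.novelty == "n/a"
                   for r in records if not r.final_call)

    def test_final_call_is_conjunction_of_audit(self, dataset):
        records = apply_filter_cascade(
            dataset.transcripts, dataset.expression, dataset.scores,
            dataset.truth.reference)
        for rec in records:
            assert rec.final_call == all(rec.filter_audit.values())


class TestClassification:
    def test_definitional_antisense_and_lincRNA(self):
        lnc_anti = TranscriptModel("anti", "g1", "chr1", "+", ((1000, 1500), (1700, 1900)))
        lnc_far = TranscriptModel("far", "g2", "chr1", "+", ((60000, 60400), (60800, 61000)))
        ref = TranscriptSet([TranscriptModel("cod", "cg", "chr1", "-",
                                             ((1200, 1300),), biotype="protein_coding")])
        ts = TranscriptSet([lnc_anti, lnc_far])
        records = _cascade(ts, ref=ref)
        classify_lncrna(records, ts, ref)
        by_id = {r.transcript_id: r for r in records}
        assert by_id["anti"].lnc_class == "antisense"
        assert by_id["far"].lnc_class == "lincRNA"

    def test_classes_match_bruteforce_oracle_on_synthetic_run(self, dataset):
        records = identify_lncrnas(
            dataset.transcripts, dataset.expression, dataset.scores,
            dataset.truth.reference)
        coding = list(dataset.truth.reference.by_biotype("protein_coding"))
        for rec in records:
            if rec.final_call:
                assert rec.lnc_class == brute_force_classify(
                    dataset.transcripts[rec.transcript_id], coding)


class TestMatchKnown:
    def _pair(self):
        cand = TranscriptModel("cand", "g", "chr1", "+", ((1000, 1200), (1400, 1600)))
        # shares exactly the first exon: 200 of 400 mature bases
        known = TranscriptSet([TranscriptModel("k", "kg", "chr1", "+",
                                               ((1000, 1200), (5000, 5200)),
                                               biotype="known_lncRNA")])
        ts = TranscriptSet([cand])
        records = _cascade(ts)
        return records, ts, known

    def test_identical_coordinates_are_annotated(self):
        cand = TranscriptModel("cand", "g", "chr1", "+", ((1000, 1200), (1400, 1600)))
        ts = TranscriptSet([cand])
        known = TranscriptSet([TranscriptModel("k", "kg", "chr1", "+",
                                               cand.exons, biotype="known_lncRNA")])
        records = match_known(_cascade(ts), ts, known)
        assert records[0].novelty == "annotated"

    def test_absent_chromosome_is_novel(self):
        cand = _two_exon("cand", 400, chrom="chr9")
        ts = TranscriptSet([cand])
        known = TranscriptSet([TranscriptModel("k", "kg", "chr1", "+",
                                               ((0, 400),), biotype="known_lncRNA")])
        records = match_known(_cascade(ts), ts, known)
        assert records[0].novelty == "novel"

    @pytest.mark.parametrize("fraction,expected", [(0.0, "annotated"), (0.5, "annotated"),
                                                   (0.6, "novel"), (1.0, "novel")])
    def test_overlap_fraction_threshold(self, fraction, expected):
        records, ts, known = self._pair()
        match_known(records, ts, known, min_overlap_fraction=fraction)
        assert records[0].novelty == expected

    def test_novelty_matches_planted_truth(self, dataset):
        records = identify_lncrnas(
            dataset.transcripts, dataset.expression, dataset.scores,
            dataset.truth.reference, dataset.truth.known_lncrnas)
        frame = records_to_frame(records)
        truth = dataset.truth.table
        for tid in dataset.truth.lncrna_ids:
            assert frame.loc[tid, "novelty"] == truth.loc[tid, "known"]
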