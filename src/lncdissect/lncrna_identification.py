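"""Candidate-lncRNA filter cascade, lincRNA/antisense classification, novelty matching.

The cascade selects long (>200 bp mature length), multi-exonic (>=2 exons),
expressed transcripts that overlap neither known coding genes (on the same
strand) nor known housekeeping noncoding loci (pseudogenes, pre-miRNA, tRNA,
rRNA, snoRNA), and that look noncoding to all four coding-potential
predictors (CNCI, CPC, Pfam-scan, PhyloCSF).  Filters are conjunctive, so
the final call set does not depend on application order; the audit records
every filter's verdict even after the first failure.

Score-threshold sides are explicit.  The defaults follow the predictors'
own conventions (negative CNCI/CPC means noncoding, Pfam E-value above the
cutoff means no protein domain, strongly negative PhyloCSF means no
conserved coding frame).  ``FilterThresholds.as_printed()`` provides the
alternative sign convention sometimes quoted in the literature
(CNCI/CPC/PhyloCSF retained when *above* their cutoffs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import (
    SMALL_RNA_BIOTYPES,
    ExpressionMatrix,
    TranscriptModel,
    TranscriptSet,
)
from .exceptions import ClassificationError, ValidationError
from .intervals import exonic_overlap_bp, spans_overlap

FILTER_NAMES = (
    "length",
    "exon_count",
    "expression",
    "coding_overlap",
    "noncoding_overlap",
    "cnci",
    "cpc",
    "pfam",
    "phylocsf",
)

#: reference biotypes excluded as "known noncoding classes"
NONCODING_EXCLUSION_BIOTYPES = frozenset({"pseudogene"}) | SMALL_RNA_BIOTYPES


@dataclass(frozen=True)
class ScoreRule:
    """One coding-potential threshold with an explicit retained side."""

    cutoff: float
    retain: str  # 'below' or 'above'

    def __post_init__(self):
        if self.retain not in ("below", "above"):
            raise ValidationError("retain must be 'below' or 'above'")
        if not math.isfinite(self.cutoff):
            raise ValidationError("cutoff must be finite")

    def passes(self, value: float) -> bool:
        if pd.isna(value):
            return False
        return value < self.cutoff if self.retain == "below" else value > self.cutoff


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; length cutoff is exclusive (>200 bp keeps 201)."""

    min_length_bp: int = 200
    min_exons: int = 2
    min_fpkm: float = 0.5
    fpkm_rule: str = "any_sample"  # or 'all_samples'
    cnci: ScoreRule = field(default_factory=lambda: ScoreRule(0.0, "below"))
    cpc: ScoreRule = field(default_factory=lambda: ScoreRule(0.0, "below"))
    pfam: ScoreRule = field(default_factory=lambda: ScoreRule(0.001, "above"))
    phylocsf: ScoreRule = field(default_factory=lambda: ScoreRule(-20.0, "below"))
    cis_window_bp: int = 10_000
    missing_score_fails: bool = True

    def __post_init__(self):
        if self.fpkm_rule not in ("any_sample", "all_samples"):
            raise ValidationError("fpkm_rule must be 'any_sample' or 'all_samples'")

    @classmethod
    def as_printed(cls, **overrides) -> "FilterThresholds":
        """Literal sign convention: CNCI/CPC > 0, Pfam E > 0.001, PhyloCSF > -20."""
        th = cls(
            cnci=ScoreRule(0.0, "above"),
            cpc=ScoreRule(0.0, "above"),
            pfam=ScoreRule(0.001, "above"),
            phylocsf=ScoreRule(-20.0, "above"),
        )
        return replace(th, **overrides) if overrides else th


@dataclass
class LncRNARecord:
    """Per-transcript filter audit plus class and novelty annotations."""

    transcript_id: str
    filter_audit: dict[str, bool]
    final_call: bool
    lnc_class: str = "none"       # lincRNA / antisense / none
    novelty: str = "n/a"          # annotated / novel / n/a


# ---------------------------------------------------------------------------
# overlap helpers
# ---------------------------------------------------------------------------


class _OverlapIndex:
    """Per-chromosome interval tree over transcript spans for overlap queries."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            s, e = t.span
            self._trees.setdefault(t.chrom, IntervalTree()).addi(s, e, t)

    def span_hits(self, t: TranscriptModel) -> list[TranscriptModel]:
        tree = self._trees.get(t.chrom)
        if tree is None:
            return []
        s, e = t.span
        return [iv.data for iv in tree.overlap(s, e)]


def _overlap_flags(t: TranscriptModel, hits: Sequence[TranscriptModel]):
    """(same-strand exonic, opposite-strand exonic, any span overlap) vs hits."""
    same = opposite = any_span = False
    for other in hits:
        if not spans_overlap(t.span, other.span):
            continue
        any_span = True
        if exonic_overlap_bp(t.exons, other.exons) > 0:
            if other.strand == t.strand:
                same = True
            else:
                opposite = True
    return same, opposite, any_span


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def apply_filter_cascade(
    ts: TranscriptSet,
    expr: ExpressionMatrix,
    scores: pd.DataFrame,
    ref: TranscriptSet,
    thresholds: FilterThresholds | None = None,
) -> list[LncRNARecord]:
    """Run the full cascade over every transcript in *ts*.

    *ref* is the reference annotation whose ``protein_coding`` entries drive
    the coding-overlap exclusion and whose pseudogene/small-RNA entries drive
    the noncoding-class exclusion.  Every candidate must have an expression
    row; missing coding-potential rows fail (configurable).
    """
    th = thresholds or FilterThresholds()
    coding_index = _OverlapIndex(ref.by_biotype("protein_coding"))
    noncoding = [t for t in ref if t.biotype in NONCODING_EXCLUSION_BIOTYPES]
    noncoding_index = _OverlapIndex(noncoding)

    missing_expr = [t.transcript_id for t in ts if t.transcript_id not in expr.values.index]
    if missing_expr:
        raise ValidationError(
            f"candidates without expression row: {missing_expr[:5]}"
            + ("..." if len(missing_expr) > 5 else "")
        )

    score_rules = {"cnci": th.cnci, "cpc": th.cpc, "pfam": th.pfam,
                   "phylocsf": th.phylocsf}
    score_cols = {"cnci": "cnci", "cpc": "cpc", "pfam": "pfam_evalue",
                  "phylocsf": "phylocsf"}

    records = []
    for t in ts:
        audit: dict[str, bool] = {}
        audit["length"] = t.length > th.min_length_bp
        audit["exon_count"] = t.n_exons >= th.min_exons

        row = expr.values.loc[t.transcript_id]
        if th.fpkm_rule == "any_sample":
            audit["expression"] = bool((row >= th.min_fpkm).any())
        else:
            audit["expression"] = bool((row >= th.min_fpkm).all())

        same, opposite, any_span = _overlap_flags(t, coding_index.span_hits(t))
        # retained when clear of coding loci, or purely antisense-exonic;
        # same-strand exonic overlap, or intronic containment without
        # opposite-strand exon contact, is an overlap with the known gene set
        audit["coding_overlap"] = (not same) and ((not any_span) or opposite)

        nc_hits = noncoding_index.span_hits(t)
        audit["noncoding_overlap"] = all(
            exonic_overlap_bp(t.exons, o.exons) == 0 for o in nc_hits
        )

        has_scores = t.transcript_id in scores.index
        for name, rule in score_rules.items():
            if has_scores:
                audit[name] = rule.passes(scores.loc[t.transcript_id, score_cols[name]])
            else:
                audit[name] = not th.missing_score_fails

        records.append(
            LncRNARecord(
                transcript_id=t.transcript_id,
                filter_audit=audit,
                final_call=all(audit.values()),
            )
        )
    return records


def classify_lncrna(
    records: list[LncRNARecord], ts: TranscriptSet, ref_coding: TranscriptSet
) -> list[LncRNARecord]:
    """Assign lincRNA/antisense classes to called records, in place.

    antisense: >=1 bp exonic overlap with a protein-coding transcript's exons
    on the opposite strand.  lincRNA: no genomic-span overlap with any coding
    locus on either strand.  Anything else violates the cascade's contract.
    """
    index = _OverlapIndex(ref_coding.by_biotype("protein_coding"))
    for rec in records:
        if not rec.final_call:
            rec.lnc_class = "none"
            continue
        t = ts[rec.transcript_id]
        same, opposite, any_span = _overlap_flags(t, index.span_hits(t))
        if opposite and not same:
            rec.lnc_class = "antisense"
        elif not any_span:
            rec.lnc_class = "lincRNA"
        else:
            raise ClassificationError(
                f"{rec.transcript_id}: called lncRNA overlaps a coding locus in a "
                "configuration the cascade should have excluded"
            )
    return records


def match_known(
    records: list[LncRNARecord],
    ts: TranscriptSet,
    known: TranscriptSet,
    min_overlap_fraction: float = 0.5,
) -> list[LncRNARecord]:
    """Flag called records as annotated vs novel against a known-lncRNA reference.

    annotated: same-strand exonic overlap with some single known lncRNA
    covering at least *min_overlap_fraction* of the candidate's mature length
    (and at least 1 bp).
    """
    if not 0.0 <= min_overlap_fraction <= 1.0:
        raise ValidationError("min_overlap_fraction must be in [0, 1]")
    index = _OverlapIndex(known)
    for rec in records:
        if not rec.final_call:
            rec.novelty = "n/a"
            continue
        t = ts[rec.transcript_id]
        best = 0
        for other in index.span_hits(t):
            if other.strand != t.strand:
                continue
            best = max(best, exonic_overlap_bp(t.exons, other.exons))
        rec.novelty = (
            "annotated" if best > 0 and best >= min_overlap_fraction * t.length
            else "novel"
        )
    return records


def identify_lncrnas(
    ts: TranscriptSet,
    expr: ExpressionMatrix,
    scores: pd.DataFrame,
    ref: TranscriptSet,
    known: TranscriptSet | None = None,
    thresholds: FilterThresholds | None = None,
    min_overlap_fraction: float = 0.5,
) -> list[LncRNARecord]:
    """Cascade + classification (+ novelty matching when *known* given)."""
    records = apply_filter_cascade(ts, expr, scores, ref, thresholds)
    classify_lncrna(records, ts, ref)
    if known is not None:
        match_known(records, ts, known, min_overlap_fraction)
    return records


def records_to_frame(records: list[LncRNARecord]) -> pd.DataFrame:
    """Flatten records (audit columns prefixed ``pass_``) for TSV output."""
    rows = []
    for rec in records:
        row = {"transcript_id": rec.transcript_id, "final_call": rec.final_call,
               "class": rec.lnc_class, "novelty": rec.novelty}
        row.update({f"pass_{k}": v for k, v in rec.filter_audit.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def called_ids(records: list[LncRNARecord]) -> set[str]:
    return {r.transcript_id for r in records if r.final_call}
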