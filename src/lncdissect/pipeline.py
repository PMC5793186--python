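"""End-to-end orchestration: identify -> characterize -> targets -> DE -> clusters -> ORA.

This is glue over the stage modules; every step is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import ExpressionMatrix, TranscriptSet
from .characterization import FeatureSummary, summarize_features
from .differential_expression import (
    DEFAULT_COMPARISONS,
    ClusterAssignment,
    call_de_sets,
    cluster_degs,
    run_comparisons,
    venn_intersections,
)
from .enrichment_validation import (
    ddct_relative_expression,
    hypergeometric_ora,
    spearman_agreement,
)
from .exceptions import ValidationError
from .lncrna_identification import (
    FilterThresholds,
    LncRNARecord,
    _OverlapIndex,
    _overlap_flags,
    called_ids,
    identify_lncrnas,
)
from .target_prediction import CisPair, TransNetwork, predict_cis_targets, predict_trans_targets


def same_strand_coding_ids(ts: TranscriptSet, ref: TranscriptSet) -> set[str]:
    """Assembled transcripts matching a reference coding gene on the same strand
    (the pipeline's working definition of the assembly's mRNA set)."""
    index = _OverlapIndex(ref.by_biotype("protein_coding"))
    out = set()
    for t in ts:
        same, _, _ = _overlap_flags(t, index.span_hits(t))
        if same:
            out.add(t.transcript_id)
    return out


@dataclass
class PipelineConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_overlap_fraction: float = 0.5
    cis_window_bp: int = 10_000
    r_threshold: float = 0.95
    p_threshold: float = 0.05
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS
    epsilon: float = 1.0
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    k: int = 4
    kmeans_seed: int = 0
    n_init: int = 10


@dataclass
class PipelineResult:
    records: list[LncRNARecord]
    lnc_ids: set[str]
    mrna_ids: set[str]
    summary: FeatureSummary
    cis_pairs: list[CisPair]
    trans: TransNetwork
    de_tables: dict[str, pd.DataFrame]
    de_sets: dict[str, dict[str, set[str]]]
    venn_lnc: dict[tuple[str, ...], int]
    venn_mrna: dict[tuple[str, ...], int]
    clusters: ClusterAssignment | None
    ora: pd.DataFrame | None
    qpcr_agreement: pd.Series | None


def run_pipeline(
    transcripts: TranscriptSet,
    reference: TranscriptSet,
    known: TranscriptSet,
    expr: ExpressionMatrix,
    scores: pd.DataFrame,
    gene_sets: Mapping[str, set[str]] | None = None,
    qpcr_ct: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    genome: Mapping[str, str] | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()

    records = identify_lncrnas(
        transcripts, expr, scores, reference, known,
        thresholds=cfg.thresholds, min_overlap_fraction=cfg.min_overlap_fraction,
    )
    lnc_ids = called_ids(records)
    mrna_ids = same_strand_coding_ids(transcripts, reference) - lnc_ids

    summary = summarize_features(transcripts, lnc_ids, mrna_ids, genome=genome)

    cis_pairs = predict_cis_targets(
        transcripts.subset(lnc_ids), reference.by_biotype("protein_coding"),
        window_bp=cfg.cis_window_bp,
    )
    trans = predict_trans_targets(
        expr.subset(sorted(lnc_ids)), expr.subset(sorted(mrna_ids)),
        r_threshold=cfg.r_threshold, p_threshold=cfg.p_threshold,
    )

    de_tables = run_comparisons(
        expr, cfg.comparisons, epsilon=cfg.epsilon, alpha=cfg.alpha,
        lfc_threshold=cfg.lfc_threshold,
    )
    de_sets = call_de_sets(de_tables)

    def _venn(ids: set[str]) -> dict[tuple[str, ...], int]:
        sets = {name: (s["up"] | s["down"]) & ids for name, s in de_sets.items()}
        return venn_intersections(sets)

    venn_lnc = _venn(lnc_ids)
    venn_mrna = _venn(mrna_ids)

    deg_ids = set()
    for s in de_sets.values():
        deg_ids |= (s["up"] | s["down"]) & mrna_ids
    clusters = (
        cluster_degs(expr, deg_ids, k=cfg.k, seed=cfg.kmeans_seed, n_init=cfg.n_init)
        if len(deg_ids) >= cfg.k else None
    )

    ora = None
    if gene_sets is not None and deg_ids:
        ora = hypergeometric_ora(deg_ids, set(mrna_ids), gene_sets)

    qpcr_agreement = None
    if qpcr_ct is not None and len(qpcr_ct):
        samples = list(dict.fromkeys(qpcr_ct["sample"]))
        rel = ddct_relative_expression(qpcr_ct, calibrator=samples[0])
        means = expr.stage_means()
        rhos = {}
        for gene, sub in rel.groupby("target_gene"):
            if gene not in means.index:
                raise ValidationError(f"qPCR target {gene!r} has no expression row")
            sub = sub.set_index("sample").loc[samples]
            rhos[gene] = spearman_agreement(
                sub["rel_expr"].to_numpy(), means.loc[gene, samples].to_numpy()
            )
        qpcr_agreement = pd.Series(rhos, name="spearman_rho")

    return PipelineResult(
        records=records, lnc_ids=lnc_ids, mrna_ids=mrna_ids, summary=summary,
        cis_pairs=cis_pairs, trans=trans, de_tables=de_tables, de_sets=de_sets,
        venn_lnc=venn_lnc, venn_mrna=venn_mrna, clusters=clusters, ora=ora,
        qpcr_agreement=qpcr_agreement,
    )
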