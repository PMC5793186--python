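"""cis-target windows and trans co-expression networks.

cis: a protein-coding gene is a candidate cis target of an lncRNA when the
closest distance between their genomic spans is at most the window
(inclusive; default 10 kb), on the same chromosome, either strand.

trans: every lncRNA x gene pair is scored by the Pearson correlation of
expression across samples; an edge is kept when |r| strictly exceeds the
r threshold and the two-sided p-value (t distribution with n-2 df) is
strictly below the p threshold.  Zero-variance rows are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import ExpressionMatrix, TranscriptSet
from .exceptions import ConstantVectorError, ValidationError
from .intervals import span_gap, spans_overlap


@dataclass(frozen=True)
class CisPair:
    """One lncRNA / coding-gene neighbourhood pair.

    ``distance`` is the closest-end gap in bp (0 when the spans overlap);
    ``position`` locates the lncRNA relative to the gene's strand.
    """

    lnc_id: str
    gene_id: str
    distance: int
    position: str  # 'upstream' or 'downstream' of the gene


@dataclass
class TransNetwork:
    """Retained correlation edges plus bookkeeping counts."""

    edges: pd.DataFrame  # columns: lnc_id, gene_id, r, p, sign
    n_edges: int
    n_positive: int
    n_negative: int
    n_lnc: int
    n_gene: int
    n_skipped_constant: int


def _gene_spans(coding: TranscriptSet):
    """Per-gene union span, chrom and strand (first transcript's strand)."""
    out = []
    for gene_id, transcripts in coding.genes.items():
        chrom = transcripts[0].chrom
        strand = transcripts[0].strand
        start = min(t.span[0] for t in transcripts)
        end = max(t.span[1] for t in transcripts)
        out.append((gene_id, chrom, strand, (start, end)))
    return out


def predict_cis_targets(
    lnc: TranscriptSet, coding: TranscriptSet, window_bp: int = 10_000
) -> list[CisPair]:
    """All (lncRNA, coding gene) pairs within *window_bp* of each other.

    Distances are measured between genomic spans (closest ends), not TSSs;
    the bound is inclusive, so a gap of exactly ``window_bp`` pairs and a
    gap of ``window_bp + 1`` does not.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    trees: dict[str, IntervalTree] = {}
    for gene_id, chrom, strand, span in _gene_spans(coding):
        trees.setdefault(chrom, IntervalTree()).addi(
            span[0], span[1], (gene_id, strand, span))

    pairs = []
    for t in lnc:
        tree = trees.get(t.chrom)
        if tree is None:
            continue
        s, e = t.span
        # widened envelope, then exact gap check (handles the boundary)
        for iv in tree.overlap(s - window_bp - 1, e + window_bp + 1):
            gene_id, strand, span = iv.data
            gap = span_gap(t.span, span)
            if gap > window_bp:
                continue
            if spans_overlap(t.span, span):
                lnc_mid = (s + e) / 2
                gene_mid = (span[0] + span[1]) / 2
                left_of_gene = lnc_mid <= gene_mid
            else:
                left_of_gene = e <= span[0]
            position = ("upstream" if left_of_gene == (strand == "+") else "downstream")
            pairs.append(CisPair(t.transcript_id, gene_id, gap, position))
    pairs.sort(key=lambda p: (p.lnc_id, p.gene_id))
    return pairs


def cis_pairs_to_frame(pairs: Sequence[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"lnc_id": p.lnc_id, "gene_id": p.gene_id, "distance": p.distance,
          "position": p.position} for p in pairs],
        columns=["lnc_id", "gene_id", "distance", "position"],
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt(n-2)/sqrt(1-r^2), df = n-2.

    |r| at (or numerically beyond) 1 maps to the p -> 0 limit.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        t = np.where(denom > 0, r * np.sqrt((n - 2) / np.where(denom > 0, denom, 1.0)),
                     np.inf * np.sign(r))
    return np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), df=n - 2), 0.0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    p = float(_p_from_r(np.array([r]), n)[0])
    return r, p


def _as_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def predict_trans_targets(
    lnc_expr: ExpressionMatrix | pd.DataFrame,
    gene_expr: ExpressionMatrix | pd.DataFrame,
    r_threshold: float = 0.95,
    p_threshold: float = 0.05,
    stage_means: bool = False,
) -> TransNetwork:
    """Score every lncRNA x gene pair and keep |r| > r_threshold, p < p_threshold.

    By default correlations run over all individual samples; with
    ``stage_means`` each stage is first averaged to one point.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValidationError("r_threshold must be in (0, 1)")
    lf, gf = _as_frame(lnc_expr), _as_frame(gene_expr)
    if list(lf.columns) != list(gf.columns):
        raise ValidationError("lncRNA and gene matrices must share sample columns")
    if stage_means:
        if not isinstance(lnc_expr, ExpressionMatrix) or not isinstance(gene_expr, ExpressionMatrix):
            raise ValidationError("stage_means mode needs ExpressionMatrix inputs")
        lf, gf = lnc_expr.stage_means(), gene_expr.stage_means()
    n = lf.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 sample columns")

    L = lf.to_numpy(dtype=float)
    G = gf.to_numpy(dtype=float)
    l_keep = L.std(axis=1) > 0
    g_keep = G.std(axis=1) > 0
    n_skipped = int((~l_keep).sum() + (~g_keep).sum())
    L, G = L[l_keep], G[g_keep]
    lnc_ids = list(np.asarray(lf.index, dtype=object)[l_keep])
    gene_ids = list(np.asarray(gf.index, dtype=object)[g_keep])

    if len(L) and len(G):
        zl = (L - L.mean(axis=1, keepdims=True)) / L.std(axis=1, keepdims=True)
        zg = (G - G.mean(axis=1, keepdims=True)) / G.std(axis=1, keepdims=True)
        R = np.clip(zl @ zg.T / n, -1.0, 1.0)
        P = _p_from_r(R, n)
        ii, jj = np.nonzero((np.abs(R) > r_threshold) & (P < p_threshold))
    else:
        R = P = np.zeros((0, 0))
        ii = jj = np.array([], dtype=int)

    edges = pd.DataFrame(
        {
            "lnc_id": [lnc_ids[i] for i in ii],
            "gene_id": [gene_ids[j] for j in jj],
            "r": R[ii, jj] if len(ii) else np.array([], dtype=float),
            "p": P[ii, jj] if len(ii) else np.array([], dtype=float),
        }
    )
    edges["sign"] = np.where(edges["r"] > 0, "positive", "negative")
    n_pos = int((edges["sign"] == "positive").sum())
    return TransNetwork(
        edges=edges,
        n_edges=len(edges),
        n_positive=n_pos,
        n_negative=len(edges) - n_pos,
        n_lnc=edges["lnc_id"].nunique(),
        n_gene=edges["gene_id"].nunique(),
        n_skipped_constant=n_skipped,
    )
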