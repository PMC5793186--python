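"""Hypergeometric over-representation analysis and qPCR agreement.

The ORA is database-agnostic: it takes any term -> gene-set mapping
(GMT-style), intersects each set with the supplied universe, and reports the
upper-tail hypergeometric probability of the observed overlap with the
selection, BH-adjusted across terms.

qPCR relative expression follows the 2^-ddCt convention: per sample,
dCt = Ct(target) - mean Ct(references); ddCt subtracts the calibrator
sample's dCt; relative expression is 2^-ddCt (so the calibrator is 1 by
construction).  Agreement with RNA-seq is the Spearman rank correlation
between per-stage relative expression and per-stage FPKM.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError


def hypergeometric_ora(
    selected: set[str],
    universe: set[str],
    gene_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *selected* within *universe*.

    For a term with K universe members, the p-value is the probability of
    drawing at least the observed overlap in len(selected) draws without
    replacement from the universe.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    if not selected:
        raise ValidationError("selection must be non-empty")
    if not selected <= universe:
        raise ValidationError("selected ids must be a subset of the universe")
    N, n = len(universe), len(selected)
    rows = []
    for term, members in gene_sets.items():
        term_in_universe = set(members) & universe
        K = len(term_in_universe)
        k = len(term_in_universe & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term_id": term, "n_universe": N, "n_term": K,
                     "n_selected": n, "n_overlap": k, "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("term_id")
    table["p_adjust"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return table.sort_values("p")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, ids...) into a term -> id-set map."""
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            gene_sets[fields[0]] = set(fields[2:])
    return gene_sets


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def ddct_relative_expression(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Complete a tidy Ct table into 2^-ddCt relative expression.

    *ct* needs columns ``sample``, ``gene``, ``ct``, ``role`` with role in
    {target, reference}; multiple reference genes are combined by
    arithmetic-mean Ct per sample.  Returns one row per (sample, target)
    with ``delta_ct``, ``delta_delta_ct`` and ``rel_expr``.
    """
    required = {"sample", "gene", "ct", "role"}
    if not required.issubset(ct.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    samples = list(dict.fromkeys(ct["sample"]))
    if calibrator not in samples:
        raise ValidationError(f"calibrator sample {calibrator!r} not in table")

    ref_ct = (
        ct[ct["role"] == "reference"].groupby("sample")["ct"].mean()
    )
    missing_ref = [s for s in samples if s not in ref_ct.index]
    if missing_ref:
        raise ValidationError(f"samples missing reference Ct: {missing_ref}")

    targets = ct[ct["role"] == "target"]
    rows = []
    for (sample, gene), sub in targets.groupby(["sample", "gene"], sort=False):
        rows.append({"sample": sample, "target_gene": gene,
                     "delta_ct": float(sub["ct"].mean() - ref_ct[sample])})
    out = pd.DataFrame(rows)
    calib = out[out["sample"] == calibrator].set_index("target_gene")["delta_ct"]
    missing_cal = set(out["target_gene"]) - set(calib.index)
    if missing_cal:
        raise ValidationError(f"targets missing calibrator Ct: {sorted(missing_cal)}")
    out["delta_delta_ct"] = out["delta_ct"] - out["target_gene"].map(calib)
    out["rel_expr"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def spearman_agreement(qpcr: Sequence[float], rnaseq: Sequence[float]) -> float:
    """Spearman rho between per-stage qPCR relative expression and FPKM.

    Computed as Pearson on average ranks (ties averaged).
    """
    x = np.asarray(qpcr, dtype=float)
    y = np.asarray(rnaseq, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValidationError("ranks are constant; rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])
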