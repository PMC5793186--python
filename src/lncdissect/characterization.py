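"""Descriptive genomic features of lncRNA vs mRNA sets.

Transcript length is mature (spliced) length; exon counts come straight
from the models; ORF length is the longest ATG-initiated, in-frame,
stop-terminated reading frame on the sense strand of the spliced
transcript (stop codon included).  Open-ended reading frames score 0
unless ``allow_open_orf`` is set; ties are broken by the 5'-most start.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .annotation_io import TranscriptModel, TranscriptSet
from .exceptions import ValidationError

_START = "ATG"
_STOPS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGTN")


def find_longest_orf(sequence: str, allow_open_orf: bool = False) -> tuple[int, int]:
    """Return (start offset, length bp) of the longest sense-strand ORF.

    Scans the three sense-strand frames; an ORF runs from an ATG to the next
    in-frame stop, stop included.  Codons containing N match neither start
    nor stop.  Returns (-1, 0) when no ORF exists.
    """
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValidationError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    best_len, best_start = 0, -1

    def consider(start: int, length: int):
        nonlocal best_len, best_start
        if length > best_len or (length == best_len and 0 <= start < best_start):
            best_len, best_start = length, start

    for frame in range(3):
        open_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if open_start is None:
                if codon == _START:
                    open_start = i
            elif codon in _STOPS:
                consider(open_start, i + 3 - open_start)
                open_start = None
        if allow_open_orf and open_start is not None:
            length = (len(seq) - open_start) // 3 * 3
            consider(open_start, length)
    return best_start, best_len


def longest_orf(sequence: str, allow_open_orf: bool = False) -> int:
    """Length in bp of the longest sense-strand ORF (0 if none)."""
    return find_longest_orf(sequence, allow_open_orf)[1]


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Sense-strand mature sequence of a transcript from a chrom->seq mapping."""
    try:
        chrom_seq = genome[t.chrom]
    except KeyError:
        raise ValidationError(f"chromosome {t.chrom!r} absent from genome") from None
    seq = "".join(chrom_seq[s:e] for s, e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


@dataclass
class FeatureSummary:
    """Set-level descriptive statistics for the lncRNA and mRNA sets."""

    per_set: dict[str, dict[str, float]]
    chrom_counts: dict[str, dict[str, int]]
    class_proportions: dict[str, float]

    def to_json_dict(self) -> dict:
        return {"per_set": self.per_set, "chrom_counts": self.chrom_counts,
                "class_proportions": self.class_proportions}


def feature_table(
    ts: TranscriptSet, genome: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-transcript features: chrom, mature length, exon count, ORF length."""
    rows = []
    for t in ts:
        row = {"transcript_id": t.transcript_id, "chrom": t.chrom,
               "length": t.length, "n_exons": t.n_exons}
        if genome is not None:
            row["orf_length"] = longest_orf(spliced_sequence(t, genome))
        rows.append(row)
    return pd.DataFrame(rows).set_index("transcript_id")


def summarize_features(
    ts: TranscriptSet,
    lnc_ids: set[str],
    mrna_ids: set[str],
    genome: Mapping[str, str] | None = None,
) -> FeatureSummary:
    """Compute the comparative feature summary for the two sets.

    ORF statistics are populated only when a genome is supplied.
    """
    if lnc_ids & mrna_ids:
        raise ValidationError("lncRNA and mRNA id sets must be disjoint")
    per_set: dict[str, dict[str, float]] = {}
    chrom_counts: dict[str, dict[str, int]] = {}
    total = len(lnc_ids) + len(mrna_ids)
    for name, ids in (("lncRNA", lnc_ids), ("mRNA", mrna_ids)):
        sub = ts.subset(ids)  # raises for unknown ids
        table = feature_table(sub, genome)
        stats: dict[str, float] = {"n": len(table)}
        for col, label in (("length", "length"), ("n_exons", "exons"),
                           ("orf_length", "orf")):
            if col in table.columns and len(table):
                stats[f"mean_{label}"] = float(table[col].mean())
                stats[f"median_{label}"] = float(table[col].median())
            elif col != "orf_length":
                stats[f"mean_{label}"] = float("nan")
                stats[f"median_{label}"] = float("nan")
        per_set[name] = stats
        chrom_counts[name] = dict(Counter(table["chrom"])) if len(table) else {}
    class_proportions = (
        {"lncRNA": len(lnc_ids) / total, "mRNA": len(mrna_ids) / total}
        if total else {"lncRNA": float("nan"), "mRNA": float("nan")}
    )
    return FeatureSummary(per_set, chrom_counts, class_proportions)
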