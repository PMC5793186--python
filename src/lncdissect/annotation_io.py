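"""Transcript/expression data model and GTF / TSV input-output.

Coordinate conventions
----------------------
Internally every exon is a 0-based half-open ``(start, end)`` interval, so
interval arithmetic is unambiguous.  GTF files are read and written in the
standard 1-based inclusive convention.  A transcript's *length* is its mature
(spliced) length — the sum of its exon lengths; the genomic *span* from first
exon start to last exon end is a separate derived quantity.

Biotypes
--------
The biotype of a transcript is read from a configurable GTF attribute
(default ``gene_biotype``).  Assembled transcripts (Cuffmerge-style output)
carry no biotype and default to ``"candidate"``.  Canonical values used by
the pipeline: ``protein_coding``, ``pseudogene``, the small-RNA classes
(``miRNA``/``pre_miRNA``/``tRNA``/``rRNA``/``snoRNA``/``small_rna``),
``known_lncRNA`` and ``candidate``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import GtfParseError, ValidationError
from .intervals import Interval

VALID_STRANDS = ("+", "-")

#: biotypes treated as housekeeping small-RNA classes by the filter cascade
SMALL_RNA_BIOTYPES = frozenset(
    {"miRNA", "pre_miRNA", "tRNA", "rRNA", "snoRNA", "small_rna"}
)

DEFAULT_BIOTYPE_ATTR = "gene_biotype"
DEFAULT_BIOTYPE = "candidate"


@dataclass(frozen=True)
class TranscriptModel:
    """One assembled transcript: exon chain, strand and biotype.

    Exons are normalised to a sorted tuple of 0-based half-open intervals and
    validated to be non-overlapping with positive length.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    biotype: str = DEFAULT_BIOTYPE

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s},{e}) has end <= start"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def length(self) -> int:
        """Mature (spliced) length in bp: sum of exon lengths."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        """Genomic span from first exon start to last exon end."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class TranscriptSet:
    """A keyed collection of :class:`TranscriptModel` with a gene-level view."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self._transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        try:
            return self._transcripts[transcript_id]
        except KeyError:
            raise ValidationError(f"unknown transcript_id {transcript_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, TranscriptSet):
            return NotImplemented
        return self._transcripts == other._transcripts

    @property
    def ids(self) -> list[str]:
        return list(self._transcripts)

    @property
    def genes(self) -> dict[str, list[TranscriptModel]]:
        """Transcripts grouped by ``gene_id``."""
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def subset(self, transcript_ids: Iterable[str]) -> "TranscriptSet":
        return TranscriptSet(self[i] for i in transcript_ids)

    def by_biotype(self, *biotypes: str) -> "TranscriptSet":
        wanted = set(biotypes)
        return TranscriptSet(t for t in self if t.biotype in wanted)

    def by_chrom(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.chrom, []).append(t)
        return out


# ---------------------------------------------------------------------------
# GTF input / output
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(
    gtf: str | io.TextIOBase | Iterable[str],
    biotype_attr: str = DEFAULT_BIOTYPE_ATTR,
) -> TranscriptSet:
    """Parse GTF text into a :class:`TranscriptSet`.

    Only ``exon`` features are consumed; each must carry ``transcript_id``
    and ``gene_id`` attributes.  1-based inclusive coordinates are converted
    to the internal 0-based half-open convention.  The biotype is read from
    *biotype_attr* when present, otherwise ``"candidate"``.

    Parameters
    ----------
    gtf
        Either the GTF content as a single string, an open text stream,
        or an iterable of lines.
    """
    if isinstance(gtf, str):
        lines: Iterable[str] = io.StringIO(gtf)
    else:
        lines = gtf

    pending: dict[str, dict] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"expected 9 tab-separated columns, found {len(fields)}", lineno
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(
                f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
            ) from None
        if end < start:
            raise ValidationError(f"line {lineno}: end {end} < start {start}")
        if strand not in VALID_STRANDS:
            raise GtfParseError(f"strand must be '+' or '-', got {strand!r}", lineno)
        attr_map = dict(_ATTR_RE.findall(attrs))
        try:
            tid = attr_map["transcript_id"]
            gid = attr_map["gene_id"]
        except KeyError as missing:
            raise GtfParseError(f"missing attribute {missing}", lineno) from None
        biotype = attr_map.get(biotype_attr, DEFAULT_BIOTYPE)
        rec = pending.setdefault(
            tid,
            {"gene_id": gid, "chrom": chrom, "strand": strand, "biotype": biotype,
             "exons": []},
        )
        for key, value in (("gene_id", gid), ("chrom", chrom), ("strand", strand)):
            if rec[key] != value:
                raise ValidationError(
                    f"line {lineno}: transcript {tid!r} has inconsistent {key}"
                )
        rec["exons"].append((start - 1, end))  # GTF 1-based inclusive -> half-open

    ts = TranscriptSet()
    for tid, rec in pending.items():
        ts.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(rec["exons"]),
                biotype=rec["biotype"],
            )
        )
    return ts


def read_gtf(path: str | Path, biotype_attr: str = DEFAULT_BIOTYPE_ATTR) -> TranscriptSet:
    with open(path) as fh:
        return parse_gtf(fh, biotype_attr=biotype_attr)


def write_gtf(
    ts: TranscriptSet,
    biotype_attr: str = DEFAULT_BIOTYPE_ATTR,
    source: str = "lncdissect",
) -> str:
    """Serialise a :class:`TranscriptSet` as GTF text.

    One ``exon`` feature per exon, 1-based inclusive coordinates, transcripts
    ordered by (chrom, span start, transcript_id) so output is deterministic.
    """
    out = []
    for t in sorted(ts, key=lambda t: (t.chrom, t.span[0], t.transcript_id)):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'{biotype_attr} "{t.biotype}";'
        )
        for s, e in t.exons:
            out.append(
                "\t".join(
                    (t.chrom, source, "exon", str(s + 1), str(e), ".", t.strand, ".",
                     attrs)
                )
            )
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """FPKM values (transcripts x samples) with a stage/replicate design.

    Parameters
    ----------
    values
        DataFrame indexed by transcript id with one column per sample;
        all entries must be finite and non-negative.
    design
        DataFrame with columns ``sample``, ``stage``, ``replicate`` covering
        exactly the sample columns of *values*.
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame):
        required = {"sample", "stage", "replicate"}
        if not required.issubset(design.columns):
            raise ValidationError(f"design must have columns {sorted(required)}")
        if set(design["sample"]) != set(values.columns):
            raise ValidationError("design samples do not match value columns")
        if design["sample"].duplicated().any():
            raise ValidationError("duplicate sample in design")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        self.values = values
        self.design = design.set_index("sample").loc[list(values.columns)].reset_index()

    @property
    def stages(self) -> list[str]:
        """Stages in design order (first appearance)."""
        return list(dict.fromkeys(self.design["stage"]))

    def samples_of(self, stage: str) -> list[str]:
        hit = self.design.loc[self.design["stage"] == stage, "sample"]
        if hit.empty:
            raise ValidationError(f"unknown stage {stage!r}")
        return list(hit)

    def stage_means(self) -> pd.DataFrame:
        """Per-transcript mean FPKM per stage (columns in design stage order)."""
        return pd.DataFrame(
            {stage: self.values[self.samples_of(stage)].mean(axis=1)
             for stage in self.stages}
        )

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(transcript_ids)
        missing = set(ids) - set(self.values.index)
        if missing:
            raise ValidationError(f"transcripts without expression row: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[ids], self.design)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.design.equals(other.design)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, values_path: str | Path, design_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="transcript_id")
        self.design.to_csv(design_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, values_path: str | Path, design_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="transcript_id")
        design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "stage": str})
        return cls(values, design)


def fpkm_from_counts(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    library_sizes: pd.Series | Mapping[str, int],
    design: pd.DataFrame,
) -> ExpressionMatrix:
    """Convert fragment counts to FPKM.

    FPKM = count * 1e9 / (transcript length in bp * total mapped fragments),
    i.e. fragments per kilobase of exon per million mapped fragments.
    """
    lengths = pd.Series(lengths).loc[counts.index].astype(float)
    library_sizes = pd.Series(library_sizes).loc[counts.columns].astype(float)
    if (lengths <= 0).any():
        raise ValidationError("transcript lengths must be > 0")
    if (library_sizes <= 0).any():
        raise ValidationError("library sizes must be > 0")
    values = counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    return ExpressionMatrix(values, design)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a coding-potential score table (transcript_id, cnci, cpc, pfam_evalue, phylocsf)."""
    scores = pd.read_csv(path, sep="\t", index_col="transcript_id")
    required = {"cnci", "cpc", "pfam_evalue", "phylocsf"}
    missing = required - set(scores.columns)
    if missing:
        raise ValidationError(f"score table missing columns {sorted(missing)}")
    return scores


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a chrom -> sequence dict (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
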