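"""Synthetic annotation, expression, score, gene-set and qPCR inputs with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes for a 4-stage (A0/A1/A3/A5) x 3-replicate differentiation time
course: a merged transcript assembly containing mRNAs, intergenic and
antisense lncRNAs plus pseudogene/small-RNA fragments; a reference
annotation carrying biotypes; a known-lncRNA reference; coding-potential
scores on the correct side of each filter threshold by construction;
FPKM expression with four temporal archetypes (K1 decreasing, K2
late-rising, K3 early-rising, K4 peaked at A1) and multiplicative
lognormal replicate noise; planted high-|r| trans pairs; a GMT gene-set
file with one deliberately enriched term; and a qPCR Ct table consistent
with the planted expression.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.Generator`` streams; a fixed config yields byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation_io import (
    ExpressionMatrix,
    TranscriptModel,
    TranscriptSet,
    write_gtf,
)
from .exceptions import GenerationError, ValidationError

STAGES = ("A0", "A1", "A3", "A5")
N_REPLICATES = 3

#: log2-scale temporal shapes, scaled by the planted effect size.  Each shape
#: realises |log2FC| equal to the full effect size in at least one of the four
#: stage comparisons (A1 vs A0, A3 vs A1, A5 vs A3, A5 vs A0).
ARCHETYPE_SHAPES = {
    "K1": (1.0, 2 / 3, 1 / 3, 0.0),   # monotone decreasing
    "K2": (0.0, 0.0, 0.25, 1.0),      # increasing, late rise
    "K3": (0.0, 0.5, 1.0, 1.0),       # increasing, early rise
    "K4": (0.0, 1.0, 0.25, 0.0),      # peaked at A1
}

# rng stream ids, one per generator stage
_S_ANNOT, _S_EXPR, _S_SCORES, _S_SETS, _S_QPCR, _S_GENOME = range(1, 7)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the simulator.

    Defaults follow the study design: 4 stages x 3 replicates, archetype mix
    proportional to the four observed cluster shares, a majority of lncRNAs
    with a coding neighbour within the 10-kb cis window, and predominantly
    positive trans correlations.  Feature counts are desk-scale.
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 3_000_000
    n_coding_genes: int = 120
    n_linc: int = 60
    n_antisense: int = 12
    n_pseudogene: int = 6
    n_small_rna: int = 6
    cis_pair_fraction: float = 0.6
    archetype_mix: tuple[float, float, float, float] = (0.325, 0.100, 0.398, 0.177)
    de_fraction: float = 0.3
    de_log2fc: float = 2.0
    noise_sd: float = 0.1
    trans_pair_count: int = 15
    trans_positive_fraction: float = 0.74
    known_fraction: float = 0.5

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_coding_genes", "n_linc",
                     "n_antisense", "n_pseudogene", "n_small_rna",
                     "trans_pair_count"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("cis_pair_fraction", "de_fraction", "known_fraction",
                     "trans_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if len(self.archetype_mix) != 4 or abs(sum(self.archetype_mix) - 1.0) > 1e-6:
            raise ValidationError("archetype_mix must be 4 proportions summing to 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthTable:
    """Planted ground truth per merged transcript.

    ``table`` is indexed by transcript_id with columns:

    - ``true_class``: mRNA / lincRNA / antisense / pseudogene / small_rna
    - ``cis_partner``: designated coding gene_id within the cis window, or ""
    - ``known``: annotated / novel for planted lncRNAs, "" otherwise
    - ``archetype``: K1-K4 for planted temporal-pattern features, "none"
    - ``trans_partner`` / ``trans_sign``: planted co-expression partner, if any

    The companion reference annotation and known-lncRNA reference are produced
    by the same placement pass and travel on this object.
    """

    table: pd.DataFrame
    reference: TranscriptSet
    known_lncrnas: TranscriptSet
    stage_means: pd.DataFrame | None = None

    @property
    def lncrna_ids(self) -> set[str]:
        return set(self.table.index[self.table["true_class"].isin(["lincRNA", "antisense"])])

    def class_of(self, transcript_id: str) -> str:
        return self.table.loc[transcript_id, "true_class"]

    def de_ids(self, comparison: tuple[str, str],
               lfc_threshold: float = 1.0, epsilon: float = 1.0) -> set[str]:
        """Transcripts whose planted stage means differ by more than the
        fold-change threshold between the two stages (pseudocount applied),
        i.e. the ground-truth DE set for one comparison."""
        if self.stage_means is None:
            raise ValidationError("expression not generated yet")
        b, a = comparison
        lfc = np.log2(self.stage_means[b] + epsilon) - np.log2(self.stage_means[a] + epsilon)
        return set(lfc.index[lfc.abs() > lfc_threshold])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _exon_chain(rng, start, n_exons, exon_len, intron_len):
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*intron_len))
    return tuple(exons)


def generate_annotation(cfg: SimulationConfig) -> tuple[TranscriptSet, TruthTable]:
    """Place coding genes, lncRNAs, pseudogenes and small RNAs on chromosomes.

    Guarantees by construction: coding genes non-overlapping; lincRNAs
    strictly intergenic with >10 kb clearance unless designated as a cis
    partner (then placed within the 10-kb window of exactly one gene);
    antisense lncRNAs overlap a host gene's exons on the opposite strand;
    every planted lncRNA is >200 bp mature length with >=2 exons.
    """
    rng = cfg.rng(_S_ANNOT)
    merged = TranscriptSet()
    reference = TranscriptSet()
    rows = []

    n_cis = int(round(cfg.cis_pair_fraction * cfg.n_linc))
    if cfg.n_coding_genes < max(n_cis + cfg.n_antisense, 1) and (n_cis or cfg.n_antisense):
        raise GenerationError("not enough coding genes for requested cis/antisense pairs")

    gene_roles = ["plain"] * cfg.n_coding_genes
    order = rng.permutation(cfg.n_coding_genes)
    for k in order[:n_cis]:
        gene_roles[k] = "cis_host"
    for k in order[n_cis:n_cis + cfg.n_antisense]:
        gene_roles[k] = "anti_host"

    # item list: coding genes (possibly with an attached lncRNA), free lincs,
    # pseudogene and small-RNA loci
    items: list[tuple] = [("coding", gi, gene_roles[gi]) for gi in range(cfg.n_coding_genes)]
    items += [("linc", li) for li in range(n_cis, cfg.n_linc)]
    items += [("pseudogene", pi) for pi in range(cfg.n_pseudogene)]
    items += [("small_rna", si) for si in range(cfg.n_small_rna)]
    items = [items[k] for k in rng.permutation(len(items))]

    # round-robin chromosome assignment of the shuffled items
    per_chrom: list[list[tuple]] = [[] for _ in range(cfg.n_chroms)]
    for k, item in enumerate(items):
        per_chrom[k % cfg.n_chroms].append(item)

    cis_iter = iter(range(n_cis))
    anti_iter = iter(range(cfg.n_antisense))
    small_classes = ("miRNA", "tRNA", "rRNA", "snoRNA")

    def _strand():
        return "+" if rng.integers(2) == 0 else "-"

    def add_row(tid, gid, true_class, cis_partner=""):
        rows.append({"transcript_id": tid, "gene_id": gid, "true_class": true_class,
                     "cis_partner": cis_partner, "known": "",
                     "archetype": "none", "trans_partner": "", "trans_sign": ""})

    def make_linc(li, chrom, start):
        exons = _exon_chain(rng, start, int(rng.integers(2, 5)),
                            (150, 600), (200, 1500))
        tid, gid = f"TCONS_L{li:05d}", f"XLOC_L{li:05d}"
        t = TranscriptModel(tid, gid, chrom, _strand(), exons)
        merged.add(t)
        return t

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 0
        for item in per_chrom[ci]:
            cursor += 12_000 + int(rng.integers(0, 8000))
            start = cursor
            kind = item[0]
            if kind == "coding":
                gi, role = item[1], item[2]
                gid = f"GENE{gi:05d}"
                linc_t = None
                if role == "cis_host":
                    li = next(cis_iter)
                    if rng.integers(2) == 0:  # lncRNA upstream of the gene
                        linc_t = make_linc(li, chrom, start)
                        start = linc_t.span[1] + int(rng.integers(300, 9000))
                exons = _exon_chain(rng, start, int(rng.integers(4, 12)),
                                    (120, 400), (300, 2000))
                strand = _strand()
                mrna = TranscriptModel(f"TCONS_M{gi:05d}", f"XLOC_M{gi:05d}",
                                       chrom, strand, exons)
                merged.add(mrna)
                reference.add(TranscriptModel(f"REFT{gi:05d}", gid, chrom, strand,
                                              exons, biotype="protein_coding"))
                add_row(mrna.transcript_id, mrna.gene_id, "mRNA")
                cursor = mrna.span[1]
                if role == "cis_host" and linc_t is None:  # lncRNA downstream
                    linc_t = make_linc(
                        li, chrom, cursor + int(rng.integers(300, 9000)))
                    cursor = linc_t.span[1]
                if linc_t is not None:
                    add_row(linc_t.transcript_id, linc_t.gene_id, "lincRNA",
                            cis_partner=gid)
                    cursor = max(cursor, linc_t.span[1])
                if role == "anti_host":
                    ai = next(anti_iter)
                    hx0 = exons[0]
                    a1 = (hx0[0] + 5, hx0[0] + 5 + min(150, (hx0[1] - hx0[0]) - 10))
                    a2s = a1[1] + int(rng.integers(60, 200))
                    a2 = (a2s, a2s + int(rng.integers(120, 300)))
                    anti = TranscriptModel(
                        f"TCONS_A{ai:05d}", f"XLOC_A{ai:05d}", chrom,
                        "-" if strand == "+" else "+", (a1, a2))
                    merged.add(anti)
                    add_row(anti.transcript_id, anti.gene_id, "antisense",
                            cis_partner=gid)
                    cursor = max(cursor, anti.span[1])
            elif kind == "linc":
                t = make_linc(item[1], chrom, start)
                add_row(t.transcript_id, t.gene_id, "lincRNA")
                cursor = t.span[1]
            elif kind == "pseudogene":
                pi = item[1]
                ref_exons = _exon_chain(rng, start, int(rng.integers(1, 3)),
                                        (200, 400), (200, 600))
                strand = _strand()
                reference.add(TranscriptModel(f"REFP{pi:05d}", f"PSEUDO{pi:05d}",
                                              chrom, strand, ref_exons,
                                              biotype="pseudogene"))
                t = _overlapping_fragment(rng, f"TCONS_P{pi:05d}", f"XLOC_P{pi:05d}",
                                          chrom, strand, ref_exons)
                merged.add(t)
                add_row(t.transcript_id, t.gene_id, "pseudogene")
                cursor = max(ref_exons[-1][1], t.span[1])
            else:  # small_rna
                si = item[1]
                biotype = small_classes[si % len(small_classes)]
                length = int(rng.integers(70, 130))
                ref_exons = ((start, start + length),)
                strand = _strand()
                reference.add(TranscriptModel(f"REFS{si:05d}", f"SRNA{si:05d}",
                                              chrom, strand, ref_exons,
                                              biotype=biotype))
                t = _overlapping_fragment(rng, f"TCONS_S{si:05d}", f"XLOC_S{si:05d}",
                                          chrom, strand, ref_exons)
                merged.add(t)
                add_row(t.transcript_id, t.gene_id, "small_rna")
                cursor = max(ref_exons[-1][1], t.span[1])
            if cursor > cfg.chrom_length:
                raise GenerationError(
                    f"{chrom}: placement exceeded chrom_length={cfg.chrom_length}; "
                    "increase chrom_length or reduce feature counts")

    table = pd.DataFrame(rows).set_index("transcript_id")

    # known-lncRNA reference: a seeded fraction of the planted lncRNAs,
    # re-emitted with near-identical coordinates under database-style ids
    known = TranscriptSet()
    lnc_ids = sorted(table.index[table["true_class"].isin(["lincRNA", "antisense"])])
    n_known = int(round(cfg.known_fraction * len(lnc_ids)))
    known_pick = sorted(rng.permutation(len(lnc_ids))[:n_known])
    for j, idx in enumerate(known_pick):
        src = merged[lnc_ids[idx]]
        exons = list(src.exons)
        s, e = exons[0]
        exons[0] = (max(0, s - int(rng.integers(0, 40))), e)  # slight 5' extension
        known.add(TranscriptModel(f"ALDB{j:05d}", f"ALDBG{j:05d}", src.chrom,
                                  src.strand, tuple(exons), biotype="known_lncRNA"))
        table.loc[lnc_ids[idx], "known"] = "annotated"
    table.loc[(table["known"] == "") & table["true_class"].isin(["lincRNA", "antisense"]),
              "known"] = "novel"

    return merged, TruthTable(table=table, reference=reference, known_lncrnas=known)


def _overlapping_fragment(rng, tid, gid, chrom, strand, ref_exons):
    """A >200-bp, 2-exon assembled fragment sharing exonic bases with a reference locus."""
    s, e = ref_exons[0]
    a1 = (max(0, s - int(rng.integers(20, 80))), e + int(rng.integers(20, 80)))
    a2s = a1[1] + int(rng.integers(100, 400))
    a2 = (a2s, a2s + int(rng.integers(150, 400)))
    return TranscriptModel(tid, gid, chrom, strand, (a1, a2))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _sample_names() -> list[str]:
    return [f"{stage}_{r}" for stage in STAGES for r in range(1, N_REPLICATES + 1)]


def design_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample": f"{stage}_{r}", "stage": stage, "replicate": r}
         for stage in STAGES for r in range(1, N_REPLICATES + 1)]
    )


def _allocate_counts(n: int, proportions: Iterable[float]) -> list[int]:
    """Largest-remainder allocation of n items to proportions (deterministic)."""
    props = list(proportions)
    raw = [p * n for p in props]
    counts = [int(np.floor(x)) for x in raw]
    for k in sorted(range(len(props)), key=lambda k: raw[k] - counts[k], reverse=True):
        if sum(counts) == n:
            break
        counts[k] += 1
    return counts


def generate_expression(
    ts: TranscriptSet, truth: TruthTable, cfg: SimulationConfig
) -> ExpressionMatrix:
    """Plant stage-mean profiles and multiplicative lognormal replicate noise.

    DE features receive an archetype shape scaled by ``de_log2fc``; non-DE
    features are flat; planted trans pairs share (positive) or arithmetically
    mirror (negative) their partner's stage-mean profile so the sample-level
    Pearson correlation is +/-1 in the noise-free limit.  Planted lncRNAs get
    baseline FPKM >= 2 so they always clear the expression filter.  The planted
    stage means are recorded on ``truth.stage_means``.
    """
    rng = cfg.rng(_S_EXPR)
    table = truth.table
    ids = [t.transcript_id for t in ts]
    if set(ids) != set(table.index):
        raise ValidationError("transcript set and truth table disagree")

    eligible = [i for i in ids
                if table.loc[i, "true_class"] in ("mRNA", "lincRNA", "antisense")]
    n_de = int(round(cfg.de_fraction * len(eligible)))
    arch_counts = _allocate_counts(n_de, cfg.archetype_mix)
    if sum(arch_counts) != n_de:
        raise ValidationError("archetype_mix inconsistent with DE count")
    de_pick = list(rng.permutation(np.array(eligible, dtype=object))[:n_de])
    labels = [k for k, c in zip(ARCHETYPE_SHAPES, arch_counts) for _ in range(c)]
    table.loc[:, "archetype"] = "none"
    for tid, lab in zip(de_pick, labels):
        table.loc[tid, "archetype"] = lab

    # baselines
    means = pd.DataFrame(0.0, index=ids, columns=list(STAGES))
    for tid in ids:
        cls = table.loc[tid, "true_class"]
        if table.loc[tid, "archetype"] != "none":
            base = float(np.exp(rng.uniform(np.log(4.0), np.log(40.0))))
        else:
            base = float(rng.lognormal(np.log(3.0), 1.0))
            if cls in ("lincRNA", "antisense"):
                base = max(base, 2.0)
        shape = ARCHETYPE_SHAPES.get(table.loc[tid, "archetype"])
        if shape is None:
            means.loc[tid] = base
        else:
            means.loc[tid] = base * 2.0 ** (cfg.de_log2fc * np.asarray(shape))

    # trans pairs among non-DE lincRNAs x non-DE mRNAs
    free_lnc = [i for i in ids if table.loc[i, "true_class"] == "lincRNA"
                and table.loc[i, "archetype"] == "none"]
    free_gene = [i for i in ids if table.loc[i, "true_class"] == "mRNA"
                 and table.loc[i, "archetype"] == "none"]
    if cfg.trans_pair_count > min(len(free_lnc), len(free_gene)):
        raise GenerationError("not enough non-DE features to plant trans pairs")
    lnc_pick = rng.permutation(np.array(free_lnc, dtype=object))[:cfg.trans_pair_count]
    gene_pick = rng.permutation(np.array(free_gene, dtype=object))[:cfg.trans_pair_count]
    shapes = list(ARCHETYPE_SHAPES.values())
    for lnc_id, gene_id in zip(lnc_pick, gene_pick):
        prof = 2.0 ** (3.0 * np.asarray(shapes[int(rng.integers(len(shapes)))]))
        base = float(np.exp(rng.uniform(np.log(4.0), np.log(20.0))))
        lnc_means = base * prof
        scale = float(rng.uniform(0.5, 2.0))
        if rng.uniform() < cfg.trans_positive_fraction:
            gene_means, sign = scale * lnc_means, "positive"
        else:
            gene_means = scale * (lnc_means.max() + lnc_means.min() - lnc_means)
            sign = "negative"
        means.loc[lnc_id] = lnc_means
        means.loc[gene_id] = gene_means
        table.loc[lnc_id, ["trans_partner", "trans_sign"]] = [gene_id, sign]
        table.loc[gene_id, ["trans_partner", "trans_sign"]] = [lnc_id, sign]

    design = design_frame()
    values = pd.DataFrame(index=ids, columns=_sample_names(), dtype=float)
    for sample, stage in zip(design["sample"], design["stage"]):
        noise = (np.exp(rng.normal(0.0, cfg.noise_sd, size=len(ids)))
                 if cfg.noise_sd > 0 else 1.0)
        values[sample] = means[stage].to_numpy() * noise

    truth.stage_means = means
    return ExpressionMatrix(values, design)


# ---------------------------------------------------------------------------
# coding-potential scores, gene sets, qPCR
# ---------------------------------------------------------------------------


def generate_scores(truth: TruthTable, cfg: SimulationConfig) -> pd.DataFrame:
    """Coding-potential score table with every transcript on the correct
    threshold side by construction (seeded margins)."""
    rng = cfg.rng(_S_SCORES)
    rows = {}
    for tid in truth.table.index:
        noncoding = truth.table.loc[tid, "true_class"] in ("lincRNA", "antisense")
        if noncoding:
            rows[tid] = {
                "cnci": rng.uniform(-2.0, -0.1),
                "cpc": rng.uniform(-3.0, -0.2),
                "pfam_evalue": 10.0 ** rng.uniform(-1.5, 1.0),
                "phylocsf": rng.uniform(-200.0, -30.0),
            }
        else:
            rows[tid] = {
                "cnci": rng.uniform(0.1, 3.0),
                "cpc": rng.uniform(0.2, 4.0),
                "pfam_evalue": 10.0 ** rng.uniform(-30.0, -5.0),
                "phylocsf": rng.uniform(20.0, 500.0),
            }
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.index.name = "transcript_id"
    return scores


def generate_gene_sets(
    truth: TruthTable, cfg: SimulationConfig,
    n_terms: int = 15, enriched_term: str = "muscle_program",
) -> dict[str, set[str]]:
    """A GMT-like term -> gene-id map over the mRNA universe, including one
    term deliberately packed with planted-DE genes for enrichment testing."""
    rng = cfg.rng(_S_SETS)
    table = truth.table
    universe = sorted(table.index[table["true_class"] == "mRNA"])
    de = sorted(i for i in universe if table.loc[i, "archetype"] != "none")
    non_de = sorted(set(universe) - set(de))
    gene_sets: dict[str, set[str]] = {}
    n_hit = min(24, len(de))
    picked = list(rng.permutation(np.array(de, dtype=object))[:n_hit])
    picked += list(rng.permutation(np.array(non_de, dtype=object))[:6])
    gene_sets[enriched_term] = set(picked)
    for k in range(n_terms - 1):
        size = int(rng.integers(10, 40))
        members = rng.permutation(np.array(universe, dtype=object))[:size]
        gene_sets[f"TERM{k:03d}"] = set(members)
    return gene_sets


def generate_qpcr(
    truth: TruthTable, cfg: SimulationConfig, n_targets: int = 5,
    reference_genes: tuple[str, str] = ("HSP70", "ACTB"),
) -> pd.DataFrame:
    """Per-stage Ct table (sample, gene, ct, role) consistent with the planted
    stage means: Ct = 24 - log2(mean FPKM + 1) plus small seeded noise, with
    near-constant reference genes.  Targets mimic a validation panel of
    differentially expressed lncRNAs and mRNAs (flat features carry no rank
    signal to validate)."""
    if truth.stage_means is None:
        raise ValidationError("generate_expression must run before generate_qpcr")
    rng = cfg.rng(_S_QPCR)
    table = truth.table
    dynamic = (truth.stage_means.max(axis=1)
               >= 2.0 * (truth.stage_means.min(axis=1) + 1e-9))
    lnc_targets = [i for i in table.index
                   if table.loc[i, "true_class"] in ("lincRNA", "antisense")
                   and dynamic[i]][:n_targets]
    mrna_targets = [i for i in table.index
                    if table.loc[i, "true_class"] == "mRNA" and dynamic[i]][:n_targets]
    targets = lnc_targets + mrna_targets
    rows = []
    for stage in STAGES:
        for gene in targets:
            ct = 24.0 - np.log2(truth.stage_means.loc[gene, stage] + 1.0)
            rows.append({"sample": stage, "gene": gene,
                         "ct": round(float(ct + rng.normal(0, 0.05)), 4),
                         "role": "target"})
        for ref in reference_genes:
            rows.append({"sample": stage, "gene": ref,
                         "ct": round(float(18.0 + rng.normal(0, 0.05)), 4),
                         "role": "reference"})
    return pd.DataFrame(rows)


def generate_genome(cfg: SimulationConfig) -> dict[str, str]:
    """Uniform-random genome sequence covering every simulated chromosome."""
    rng = cfg.rng(_S_GENOME)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{ci + 1}": alphabet[rng.integers(0, 4, size=cfg.chrom_length)]
        .tobytes().decode("ascii")
        for ci in range(cfg.n_chroms)
    }


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    transcripts: TranscriptSet
    truth: TruthTable
    expression: ExpressionMatrix
    scores: pd.DataFrame
    gene_sets: dict[str, set[str]]
    qpcr: pd.DataFrame
    genome: dict[str, str] | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "merged.gtf").write_text(write_gtf(self.transcripts))
        (outdir / "reference.gtf").write_text(write_gtf(self.truth.reference))
        (outdir / "known_lncrna.gtf").write_text(write_gtf(self.truth.known_lncrnas))
        self.expression.to_tsv(outdir / "expression.tsv", outdir / "design.tsv")
        self.scores.to_csv(outdir / "scores.tsv", sep="\t")
        with open(outdir / "gene_sets.gmt", "w") as fh:
            for term in sorted(self.gene_sets):
                fh.write("\t".join([term, term] + sorted(self.gene_sets[term])) + "\n")
        self.qpcr.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
        self.truth.table.to_csv(outdir / "truth.tsv", sep="\t")
        if self.genome is not None:
            with open(outdir / "genome.fa", "w") as fh:
                for chrom, seq in self.genome.items():
                    fh.write(f">{chrom}\n")
                    for k in range(0, len(seq), 80):
                        fh.write(seq[k:k + 80] + "\n")


def simulate_dataset(cfg: SimulationConfig, with_genome: bool = False) -> SimulatedDataset:
    """Run every generator stage in order and bundle the results."""
    ts, truth = generate_annotation(cfg)
    expr = generate_expression(ts, truth, cfg)
    scores = generate_scores(truth, cfg)
    gene_sets = generate_gene_sets(truth, cfg)
    qpcr = generate_qpcr(truth, cfg)
    genome = generate_genome(cfg) if with_genome else None
    return SimulatedDataset(cfg, ts, truth, expr, scores, gene_sets, qpcr, genome)


# ---------------------------------------------------------------------------
# focused calibration generators (planted-null / planted-DE / archetype grids)
# ---------------------------------------------------------------------------


def simulate_null_matrix(n_features: int, noise_sd: float, seed: int) -> ExpressionMatrix:
    """Flat (no differential signal) FPKM matrix for type-I-error calibration."""
    rng = np.random.default_rng([int(seed), 101])
    ids = [f"NULL{k:05d}" for k in range(n_features)]
    base = np.exp(rng.uniform(np.log(1.0), np.log(20.0), size=n_features))
    design = design_frame()
    values = pd.DataFrame(
        {s: base * np.exp(rng.normal(0, noise_sd, size=n_features))
         for s in design["sample"]},
        index=ids,
    )
    return ExpressionMatrix(values, design)


def simulate_de_matrix(
    n_null: int, n_de: int, log2fc: float, noise_sd: float, seed: int,
    up_fraction: float = 0.5,
) -> tuple[ExpressionMatrix, set[str], set[str]]:
    """Null + planted-DE matrix for power/FDR calibration.

    DE features differ by ``log2fc`` between A5 and A0 (linear ramp across
    stages); direction split by ``up_fraction``.  Returns (matrix, up ids,
    down ids).
    """
    rng = np.random.default_rng([int(seed), 102])
    ids = [f"F{k:05d}" for k in range(n_null + n_de)]
    n_up = int(round(up_fraction * n_de))
    ramp = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    means = pd.DataFrame(index=ids, columns=list(STAGES), dtype=float)
    for k, tid in enumerate(ids):
        if k < n_null:
            means.loc[tid] = float(np.exp(rng.uniform(np.log(1.0), np.log(20.0))))
        else:
            base = float(np.exp(rng.uniform(np.log(4.0), np.log(40.0))))
            direction = 1.0 if (k - n_null) < n_up else -1.0
            means.loc[tid] = base * 2.0 ** (direction * log2fc * ramp)
    design = design_frame()
    values = pd.DataFrame(
        {s: means[stage].to_numpy() * np.exp(rng.normal(0, noise_sd, size=len(ids)))
         for s, stage in zip(design["sample"], design["stage"])},
        index=ids,
    )
    up = set(ids[n_null:n_null + n_up])
    down = set(ids[n_null + n_up:])
    return ExpressionMatrix(values, design), up, down


def simulate_archetype_profiles(
    n_per_cluster: int, noise_sd: float, seed: int, effect: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Stage-mean profiles drawn around the four archetype shapes with
    additive Gaussian noise, for clustering-recovery checks.

    Returns (profiles on the log2-offset scale, true archetype labels).
    """
    rng = np.random.default_rng([int(seed), 103])
    rows, labels, ids = [], [], []
    for lab, shape in ARCHETYPE_SHAPES.items():
        for k in range(n_per_cluster):
            rows.append(effect * np.asarray(shape) + rng.normal(0, noise_sd, 4))
            labels.append(lab)
            ids.append(f"{lab}_{k:04d}")
    profiles = pd.DataFrame(rows, index=ids, columns=list(STAGES))
    return profiles, pd.Series(labels, index=ids, name="archetype")
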