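# lncdissect

Identification and functional dissection of long non-coding RNAs (lncRNAs)
from a staged, replicated bulk RNA-seq time course — the kind of design used
to profile myoblast differentiation, where cells are sampled at four stages
(A0/A1/A3/A5 = 0/24/72/120 h after the switch to differentiation medium)
with three biological replicates each.

The package takes the *downstream products* of a standard assembly workflow
(a merged transcript GTF, a reference annotation, an FPKM expression matrix,
and precomputed coding-potential scores) and implements everything after
that point as a tested, reusable library with a thin CLI:

1. **lncRNA identification** — a conjunctive filter cascade: mature length
   > 200 bp, ≥ 2 exons, FPKM ≥ 0.5 in at least one sample, no overlap with
   known coding genes (same strand) or with pseudogene/pre-miRNA/tRNA/rRNA/
   snoRNA loci, and a noncoding verdict from all four coding-potential
   scores (CNCI, CPC, Pfam-scan E-value, PhyloCSF), with an explicit,
   auditable per-filter record.
2. **Classification and novelty** — lincRNA (no genomic-span overlap with
   any coding locus) vs antisense (≥ 1 bp exonic overlap with a coding gene
   on the opposite strand); annotated vs novel by coordinate overlap against
   a known-lncRNA reference.
3. **Target prediction** — *cis*: coding genes whose genomic span lies
   within 10 kb of an lncRNA's span; *trans*: all lncRNA × mRNA pairs with
   Pearson |r| > 0.95 and p < 0.05 across the 12 samples, where
   p = 2·P(T<sub>n−2</sub> ≥ |r|·√((n−2)/(1−r²))).
4. **Differential expression** — per stage pair, log₂FC from stage-mean
   FPKM with a pseudocount of 1 and a Welch t-test on log₂(FPKM+1)
   replicates, Benjamini–Hochberg adjusted; calls require |log₂FC| > 1 and
   q < 0.05. Multi-comparison Venn regions are computed exactly.
5. **Temporal archetypes** — K-means (Euclidean, 10 restarts) on
   standardised stage-mean profiles of the DE genes, with the k = 4
   centroids mapped to the canonical archetypes: K1 decreasing (proliferation
   program), K2 late-rising and K3 early-rising (fusion programs), K4 peaked
   at 24 h (differentiation-initiation program).
6. **Enrichment and validation** — a database-agnostic hypergeometric
   over-representation test over GMT gene sets, and qPCR agreement via the
   2<sup>−ΔΔCt</sup> method with Spearman rank correlation against FPKM.

Because raw reads for such studies are frequently unavailable, the package
ships a first-class synthetic-data generator (`lncdissect.synthetic_data`)
that emulates all inputs with planted ground truth — placed lincRNA and
antisense loci, cis neighbours within the 10-kb window, archetype expression
profiles, high-|r| trans pairs, threshold-sided coding-potential scores, an
enriched gene set, and a consistent Ct table — so every stage is testable
end to end with no downloads.

## Worked example

```python
from lncdissect import SimulationConfig, simulate_dataset, run_pipeline

ds = simulate_dataset(SimulationConfig(seed=1))
res = run_pipeline(ds.transcripts, ds.truth.reference, ds.truth.known_lncrnas,
                   ds.expression, ds.scores, gene_sets=ds.gene_sets,
                   qpcr_ct=ds.qpcr)

classes = [r.lnc_class for r in res.records if r.final_call]
print(f"lncRNAs called: {len(res.lnc_ids)} "
      f"({classes.count('lincRNA')} lincRNA, {classes.count('antisense')} antisense)")
```

Output (seed 1):

```
lncRNAs called: 72 (60 lincRNA, 12 antisense)
novelty: 36 annotated, 36 novel
cis pairs (<=10 kb): 48
trans edges (|r|>0.95, p<0.05): 460 (381 positive, 79 negative)
DE features across comparisons: 34 lncRNA, 54 mRNA
archetype sizes: {'K1': 20, 'K2': 7, 'K3': 20, 'K4': 7}
top enriched term: muscle_program (q = 1.28e-06)
mean qPCR/RNA-seq Spearman rho: 0.92
```

Reading it: the cascade recovered all 72 planted lncRNAs (60 intergenic,
12 antisense; half of them overlap the known-lncRNA reference and are
flagged "annotated"). 48 lncRNAs have a coding neighbour inside the 10-kb
cis window. The trans network retains 460 co-expression edges — the 15
planted pairs plus edges between features sharing a temporal archetype,
which is exactly what a correlation cut at |r| > 0.95 keeps. DE calling
recovers the planted dynamic features; their standardised profiles cluster
into the four archetypes; the deliberately DE-packed gene set tops the
enrichment table; and simulated qPCR tracks the FPKM profiles with mean
rank correlation 0.92.

The same steps are available from the shell:

```sh
lncdissect simulate --seed 1 --out sim/
lncdissect identify --gtf sim/merged.gtf --ref-gtf sim/reference.gtf \
    --known-gtf sim/known_lncrna.gtf --expr sim/expression.tsv \
    --design sim/design.tsv --scores sim/scores.tsv --out records.tsv
lncdissect de --expr sim/expression.tsv --design sim/design.tsv --outdir de/
```

See `lncdissect --help` for `validate-inputs`, `characterize`, `targets`,
`cluster`, `ora` and `qpcr`.

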