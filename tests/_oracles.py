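"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (quadratic loops, exhaustive scans,
textbook formulas) and shares no code with the package's fast paths.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


# -- interval / classification ------------------------------------------------


def bases_of(exons) -> set[int]:
    out = set()
    for s, e in exons:
        out.update(range(s, e))
    return out


def brute_force_classify(lnc, coding_transcripts) -> str:
    """lincRNA / antisense / excluded by exhaustive per-base comparison."""
    lnc_bases = bases_of(lnc.exons)
    span_bases = set(range(lnc.span[0], lnc.span[1]))
    same = opposite = span_overlap = False
    for t in coding_transcripts:
        if t.chrom != lnc.chrom:
            continue
        if span_bases & set(range(t.span[0], t.span[1])):
            span_overlap = True
        shared = lnc_bases & bases_of(t.exons)
        if shared:
            if t.strand == lnc.strand:
                same = True
            else:
                opposite = True
    if same:
        return "excluded"
    if opposite:
        return "antisense"
    if span_overlap:
        return "excluded"
    return "lincRNA"


def brute_force_cis(lnc_set, coding_set, window):
    """All (lnc_id, gene_id) pairs within window, by an O(n^2) distance loop."""
    genes = {}
    for t in coding_set:
        gid = t.gene_id
        if gid not in genes:
            genes[gid] = [t.chrom, t.span[0], t.span[1]]
        else:
            genes[gid][1] = min(genes[gid][1], t.span[0])
            genes[gid][2] = max(genes[gid][2], t.span[1])
    pairs = set()
    for lnc in lnc_set:
        for gid, (chrom, gs, ge) in genes.items():
            if chrom != lnc.chrom:
                continue
            ls, le = lnc.span
            if ls < ge and gs < le:
                gap = 0
            elif le <= gs:
                gap = gs - le
            else:
                gap = ls - ge
            if gap <= window:
                pairs.add((lnc.transcript_id, gid))
    return pairs


# -- statistics ---------------------------------------------------------------


def pearson_manual(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / math.sqrt((xd ** 2).sum() * (yd ** 2).sum()))


def t_pdf(t, df):
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    return np.exp(logc) * (1 + t * t / df) ** (-(df + 1) / 2)


def pearson_p_quadrature(r, n):
    """Two-sided p for Pearson r by numeric integration of the t density."""
    df = n - 2
    t = abs(r) * math.sqrt(df / (1 - r * r))
    tail, _ = quad(t_pdf, t, np.inf, args=(df,))
    return 2 * tail


def bh_stepup(pvalues):
    """Textbook Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def hypergeom_exact_tail(k, N, K, n):
    """P(overlap >= k) from the closed-form hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def hypergeom_enumerated_tail(k, universe, term, n):
    """P(overlap >= k) by exhaustive enumeration of all n-subsets (tiny N only)."""
    universe = sorted(universe)
    term = set(term)
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def spearman_manual(x, y):
    """rho = Pearson on average ranks, with hand-rolled tie-averaged ranking."""

    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    return pearson_manual(avg_ranks(x), avg_ranks(y))


# -- sequences ----------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf_exhaustive(seq):
    """Longest ATG..stop ORF by scanning every (start, stop) substring pair."""
    seq = seq.upper()
    best = 0
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) + 1 - 2, 3):
            codon = seq[j:j + 3]
            if codon in _STOPS:
                best = max(best, j + 3 - i)
                break
    return best


def venn_enumeration(sets):
    """Region counts by per-element membership enumeration."""
    names = list(sets)
    counts = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            counts[combo] = 0
    for el in set().union(*sets.values()):
        key = tuple(n for n in names if el in sets[n])
        counts[key] += 1
    return counts
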