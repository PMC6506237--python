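"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity along a code path deliberately separate
from the package implementation: a textbook O(nm) affine-gap dynamic
program, naive per-read tallies, direct probability summation for the
posterior model, and exhaustive enumeration for codons, bins and regions.
"""

from __future__ import annotations

import numpy as np

NEG = -1e18


def affine_dp_score(ref: str, read: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Semi-global alignment score (free end gaps on ``ref``), affine gaps
    costing ``gap_open + length * gap_extend``.  Textbook three-state DP."""
    n, m = len(ref), len(read)
    go = gap_open + gap_extend  # cost of a length-1 gap
    ge = gap_extend
    # H[j] = best score ending at (i, j) in any state
    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)   # gap in read (deletion from ref)
    Y = np.full(m + 1, NEG)   # gap in ref (read insertion)
    H = np.full(m + 1, NEG)
    H[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = max(H[j - 1] - go, Y[j - 1] - ge)
        H[j] = Y[j]
    best = H[m]
    for i in range(1, n + 1):
        M_new = np.full(m + 1, NEG)
        X_new = np.full(m + 1, NEG)
        Y_new = np.full(m + 1, NEG)
        H_new = np.full(m + 1, NEG)
        H_new[0] = 0.0   # free leading ref skip
        X_new[0] = max(H[0] - go, X[0] - ge)
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else -mismatch
            M_new[j] = H[j - 1] + s
            X_new[j] = max(H[j] - go, X[j] - ge)
            Y_new[j] = max(H_new[j - 1] - go, Y_new[j - 1] - ge)
            H_new[j] = max(M_new[j], X_new[j], Y_new[j])
        M, X, Y, H = M_new, X_new, Y_new, H_new
        best = max(best, H[m])  # free trailing ref skip
    return float(best)


def tally_position_table(aligned_reads, amplicon_length: int):
    """Naive per-read recount of the per-position A/C/G/T/del counts and
    insertion starts."""
    counts = np.zeros((5, amplicon_length), dtype=np.int64)
    ins = np.zeros(amplicon_length, dtype=np.int64)
    for read in aligned_reads:
        rpos, qpos = read.start, 0
        for op, n in read.ops:
            if op == "M":
                for k in range(n):
                    counts[int(read.seq[qpos + k]), rpos + k] += 1
                rpos += n
                qpos += n
            elif op == "D":
                for k in range(n):
                    counts[4, rpos + k] += 1
                rpos += n
            else:
                ins[max(rpos - 1, 0)] += 1
                qpos += n
    return counts, ins


def direct_posterior(bases, base_quals, map_quals, ref_code: int,
                     alt_code: int, prior: float, f_grid) -> float:
    """Direct (non-log) summation of the two-hypothesis posterior."""
    e = [10.0 ** (-q / 10.0) for q in base_quals]
    mm = [10.0 ** (-q / 10.0) for q in map_quals]
    def p_obs(b, true_code, ei):
        return 1.0 - ei if b == true_code else ei / 3.0
    l0 = 1.0
    for b, ei, mi in zip(bases, e, mm):
        l0 *= (1.0 - mi) * p_obs(b, ref_code, ei) + mi * 0.25
    l1 = 0.0
    for f in f_grid:
        lf = 1.0
        for b, ei, mi in zip(bases, e, mm):
            mix = (1.0 - f) * p_obs(b, ref_code, ei) + f * p_obs(b, alt_code, ei)
            lf *= (1.0 - mi) * mix + mi * 0.25
        l1 += lf / len(f_grid)
    return prior * l1 / (prior * l1 + (1.0 - prior) * l0)


def assign_bins(positions, chrom_length: int, bin_size: int):
    """Naive per-call loop assigning 1-based positions to half-open bins."""
    n_bins = (chrom_length + bin_size - 1) // bin_size
    counts = [0] * max(1, n_bins)
    for p in positions:
        counts[(p - 1) // bin_size] += 1
    return counts


def classify_position(pos1: int, transcripts, flank: int) -> str:
    """Naive per-transcript scan mirroring the documented precedence.

    ``transcripts`` yield (id, strand, exons, cds_intervals, span) where
    exons/cds_intervals are 0-based half-open lists and span is (start, end).
    """
    pos0 = pos1 - 1
    ranked = []
    order = ["CDS", "5'UTR", "3'UTR", "noncoding-transcript",
             "upstream-5kb", "downstream-5kb", "intergenic"]
    for tid, strand, exons, cds_iv, (start, end) in transcripts:
        cds_len = sum(e - s for s, e in cds_iv)
        cat = None
        if any(s <= pos0 < e for s, e in cds_iv):
            cat = "CDS"
        elif any(s <= pos0 < e for s, e in exons):
            if not cds_iv:
                cat = "noncoding-transcript"
            else:
                lo = min(s for s, _ in cds_iv)
                before = pos0 < lo
                five = before if strand == "+" else not before
                cat = "5'UTR" if five else "3'UTR"
        elif start <= pos0 < end:
            cat = "noncoding-transcript"
        elif start - flank <= pos0 < start:
            cat = "upstream-5kb" if strand == "+" else "downstream-5kb"
        elif end <= pos0 < end + flank:
            cat = "downstream-5kb" if strand == "+" else "upstream-5kb"
        if cat is not None:
            ranked.append((order.index(cat), -cds_len, tid, cat))
    if not ranked:
        return "intergenic"
    return min(ranked)[3]


CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def codon_consequences():
    """Every A-containing codon x edited position -> (before, after,
    aa_before, aa_after, synonymous), by exhaustive enumeration."""
    out = []
    for codon, aa in CODON_TABLE.items():
        for i, base in enumerate(codon):
            if base != "A":
                continue
            after = codon[:i] + "G" + codon[i + 1:]
            out.append((codon, after, aa, CODON_TABLE[after],
                        aa == CODON_TABLE[after], i))
    return out
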