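"""Amplicon deep-sequencing quantification.

Quantifies per-position base frequencies, per-adenosine A-to-I (read as
A->G) editing, protospacer-window DNA editing and nick-proximal indel
frequencies from single-end amplicon reads.

Alignment is semi-global (free end gaps on the amplicon) with affine gap
penalties, via :class:`Bio.Align.PairwiseAligner`.  A full-length read with
``k`` mismatches and no indel is accepted without running the DP whenever

    k * (match + mismatch) <= match + gap_open + gap_extend

because any alignment containing a gap aligns at most ``L - 1`` read bases
and pays at least one gap opening, so its score is bounded by
``(L-1)*match - gap_open - gap_extend`` — the gapless score wins (ties break
toward mismatches over gaps).  This keeps deep read sets fast while staying
exactly equivalent to the full dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .models import AmpliconSpec, ReadSet, codes_to_seq, seq_to_codes


class EmptyInputError(ValueError):
    pass


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring; a gap of length g costs open + g*extend."""

    match: float = 5.0
    mismatch: float = 4.0      # penalty (positive)
    gap_open: float = 20.0
    gap_extend: float = 2.0
    min_score_fraction: float = 0.6  # discard reads scoring below this * max

    def __post_init__(self) -> None:
        for name in ("match", "mismatch", "gap_open", "gap_extend"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def certified_mismatch_limit(self) -> int:
        """Largest mismatch count for which a gapless full-length alignment
        is provably optimal."""
        return int((self.match + self.gap_open + self.gap_extend)
                   // (self.match + self.mismatch))


@dataclass
class AlignedRead:
    """One read aligned to the amplicon (0-based start, M/I/D operations)."""

    qname: str
    start: int
    ops: list[tuple[str, int]]
    seq: np.ndarray     # uint8 codes, query order (M and I bases)
    quals: np.ndarray
    score: float

    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.ops)


@dataclass
class AlignmentResult:
    """Aligned amplicon reads.

    Certified gapless full-length reads are kept as matrices in
    ``gapless_seqs``/``gapless_quals``; reads that needed the full DP (or
    differ in length) are in ``detailed``.  ``n_discarded`` counts reads
    whose score fell below the configured floor.
    """

    spec: AmpliconSpec
    scoring: Scoring
    gapless_seqs: np.ndarray
    gapless_quals: np.ndarray
    detailed: list[AlignedRead] = field(default_factory=list)
    n_discarded: int = 0

    def __len__(self) -> int:
        return self.gapless_seqs.shape[0] + len(self.detailed)

    def iter_aligned(self) -> Iterator[AlignedRead]:
        L = len(self.spec)
        for i in range(self.gapless_seqs.shape[0]):
            seq = self.gapless_seqs[i]
            k = int((seq != self.spec.codes).sum())
            yield AlignedRead(
                qname=f"gapless_{i}", start=0, ops=[("M", L)],
                seq=seq, quals=self.gapless_quals[i],
                score=L * self.scoring.match
                - k * (self.scoring.match + self.scoring.mismatch))
        yield from self.detailed


def _make_aligner(scoring: Scoring):
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = -scoring.mismatch
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    # unaligned amplicon ends are free (semi-global)
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def _ops_from_alignment(aln) -> tuple[int, list[tuple[str, int]]]:
    """Convert a Biopython alignment path to (start, M/I/D operations)."""
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    start = int(t_blocks[0][0])
    if q_blocks[0][0] > 0:  # leading read overhang
        ops.append(("I", int(q_blocks[0][0])))
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            if qs > prev_q:
                ops.append(("I", int(qs - prev_q)))
            if ts > prev_t:
                ops.append(("D", int(ts - prev_t)))
        if ops and ops[-1][0] == "M":
            ops[-1] = ("M", ops[-1][1] + int(te - ts))
        else:
            ops.append(("M", int(te - ts)))
        prev_t, prev_q = te, qe
    q_len = len(aln.sequences[1])
    if q_len > prev_q:  # trailing read overhang
        ops.append(("I", int(q_len - prev_q)))
    return start, ops


def align_reads_to_amplicon(
    reads: ReadSet,
    spec: AmpliconSpec,
    scoring: Scoring = Scoring(),
) -> AlignmentResult:
    """Align every read to the amplicon (semi-global, affine gaps)."""
    if len(reads) == 0:
        raise EmptyInputError("no reads to align")
    ref = spec.codes
    ref_str = spec.sequence
    L = len(ref)
    k_limit = scoring.certified_mismatch_limit
    aligner = _make_aligner(scoring)

    gapless_seqs, gapless_quals = [], []
    detailed: list[AlignedRead] = []
    n_discarded = 0
    read_no = 0

    for block in reads.blocks:
        todo = np.arange(block.n)
        if block.length == L:
            mism = (block.seqs != ref).sum(axis=1)
            certified = mism <= k_limit
            scores = L * scoring.match - mism * (scoring.match + scoring.mismatch)
            floor = scoring.min_score_fraction * L * scoring.match
            ok = certified & (scores >= floor)
            gapless_seqs.append(block.seqs[ok])
            gapless_quals.append(block.quals[ok])
            n_discarded += int((certified & ~ok).sum())
            todo = np.flatnonzero(~certified)
        for i in todo:
            seq_codes = block.seqs[i]
            alns = aligner.align(ref_str, codes_to_seq(seq_codes))
            floor = scoring.min_score_fraction * len(seq_codes) * scoring.match
            if alns.score < floor:
                n_discarded += 1
                continue
            start, ops = _ops_from_alignment(alns[0])
            detailed.append(AlignedRead(
                qname=f"{reads.name}_{read_no + i}", start=start, ops=ops,
                seq=seq_codes, quals=block.quals[i], score=float(alns.score)))
        read_no += block.n

    seqs = (np.concatenate(gapless_seqs) if gapless_seqs
            else np.empty((0, L), dtype=np.uint8))
    quals = (np.concatenate(gapless_quals) if gapless_quals
             else np.empty((0, L), dtype=np.uint8))
    return AlignmentResult(spec=spec, scoring=scoring, gapless_seqs=seqs,
                           gapless_quals=quals, detailed=detailed,
                           n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# Per-position nucleotide table
# ---------------------------------------------------------------------------

ROW_LABELS = ["A", "C", "G", "T", "del", "ins"]


@dataclass
class PositionTable:
    """Per-position counts of A/C/G/T/deletion plus insertion starts.

    ``counts`` has shape (5, L): rows A, C, G, T, deletion.  Depth at a
    position is the column sum (reads whose alignment covers the position).
    Insertions are counted at the position preceding the inserted bases and
    are not part of depth.
    """

    counts: np.ndarray
    ins_starts: np.ndarray
    ref_codes: np.ndarray

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequency(self, base: str) -> np.ndarray:
        """Frequency of a base ('A','C','G','T','del','ins') per position."""
        depth = self.depth
        row = (self.ins_starts if base == "ins"
               else self.counts[ROW_LABELS.index(base)])
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(depth > 0, row / np.maximum(depth, 1), 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Frequencies in the layout of a per-position nucleotide percentage
        summary: rows A/C/G/T/del/ins, one column per reference position."""
        cols = [f"{codes_to_seq(np.array([c], dtype=np.uint8))}{i + 1}"
                for i, c in enumerate(self.ref_codes)]
        data = np.vstack([self.frequency(b) for b in ROW_LABELS])
        return pd.DataFrame(data, index=ROW_LABELS, columns=cols)


def nucleotide_percentage_table(result: AlignmentResult,
                                spec: AmpliconSpec) -> PositionTable:
    """Tally per-position base/deletion counts and insertion starts."""
    if len(result) == 0:
        raise EmptyInputError("no aligned reads")
    L = len(spec)
    counts = np.zeros((5, L), dtype=np.int64)
    ins_starts = np.zeros(L, dtype=np.int64)

    if result.gapless_seqs.shape[0]:
        for b in range(4):
            counts[b] += (result.gapless_seqs == b).sum(axis=0)

    for read in result.detailed:
        rpos, qpos = read.start, 0
        for op, n in read.ops:
            if op == "M":
                seg = read.seq[qpos:qpos + n]
                np.add.at(counts, (seg, np.arange(rpos, rpos + n)), 1)
                rpos += n
                qpos += n
            elif op == "D":
                counts[4, rpos:rpos + n] += 1
                rpos += n
            else:  # insertion: counted at the preceding position
                ins_starts[max(rpos - 1, 0)] += 1
                qpos += n
    return PositionTable(counts=counts, ins_starts=ins_starts,
                         ref_codes=spec.codes)


# ---------------------------------------------------------------------------
# Editing statistics
# ---------------------------------------------------------------------------

@dataclass
class AmpliconEditingSummary:
    per_adenosine: np.ndarray   # A->G frequency at each sequenced adenosine
    n_adenosines: int
    n_detectable: int
    mean_frequency: float
    threshold: float


def count_edited_adenosines(table: PositionTable, spec: AmpliconSpec,
                            threshold: float = 0.001) -> int:
    """Number of reference adenosines whose G frequency strictly exceeds
    ``threshold`` (COUNTIF ">..." semantics)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    a_pos = spec.adenosine_positions
    g_freq = table.frequency("G")[a_pos - 1]
    return int((g_freq > threshold).sum())


def mean_a_to_i_frequency(table: PositionTable, spec: AmpliconSpec) -> float:
    """Unweighted mean A->G frequency over all sequenced adenosines
    (zeros included)."""
    a_pos = spec.adenosine_positions
    if len(a_pos) == 0:
        raise UndefinedStatisticError("amplicon contains no adenosines")
    return float(table.frequency("G")[a_pos - 1].mean())


def summarize_amplicon(table: PositionTable, spec: AmpliconSpec,
                       threshold: float = 0.001) -> AmpliconEditingSummary:
    a_pos = spec.adenosine_positions
    if len(a_pos) == 0:
        raise UndefinedStatisticError("amplicon contains no adenosines")
    freqs = table.frequency("G")[a_pos - 1]
    return AmpliconEditingSummary(
        per_adenosine=freqs,
        n_adenosines=len(a_pos),
        n_detectable=int((freqs > threshold).sum()),
        mean_frequency=float(freqs.mean()),
        threshold=threshold,
    )


@dataclass
class ProtospacerEditing:
    """A->G frequencies within the protospacer editing window."""

    per_position: dict[int, float]  # protospacer position -> frequency
    efficiency: float | None        # target-A frequency (DNA editing efficiency)
    window: tuple[int, int]
    window_has_a: bool


def protospacer_editing(table: PositionTable, spec: AmpliconSpec,
                        window: tuple[int, int] = (4, 8),
                        target_position: int | None = None) -> ProtospacerEditing:
    """A->G frequency at each adenosine within the protospacer editing
    window (positions 4-8 by default, PAM = 21-23).

    The editing efficiency is the frequency at ``target_position`` if given,
    at the window's single A if unique, else at the most edited window A.
    """
    g_freq = table.frequency("G")
    per_position: dict[int, float] = {}
    for p in range(window[0], window[1] + 1):
        amp = spec.protospacer_to_amplicon(p)
        if spec.codes[amp - 1] == 0:  # reference A
            per_position[p] = float(g_freq[amp - 1])
    if not per_position:
        return ProtospacerEditing({}, None, window, window_has_a=False)
    if target_position is not None:
        if target_position not in per_position:
            raise ValueError(f"protospacer position {target_position} is not "
                             "an A inside the window")
        eff = per_position[target_position]
    elif len(per_position) == 1:
        eff = next(iter(per_position.values()))
    else:
        eff = max(per_position.values())
    return ProtospacerEditing(per_position, eff, window, window_has_a=True)


def indel_frequency(result: AlignmentResult, spec: AmpliconSpec,
                    window_width: int = 30) -> float:
    """Fraction of aligned reads carrying >=1 insertion or deletion that
    overlaps the window centred on the nick.

    For width w the window covers 1-based positions
    ``nick - w//2 .. nick - w//2 + w - 1`` (30 -> nick-15 .. nick+14).
    Substitutions are never counted.
    """
    if len(result) == 0:
        raise EmptyInputError("no aligned reads")
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    left = spec.nick_position - window_width // 2       # 1-based inclusive
    right = left + window_width - 1
    n_indel = 0
    for read in result.detailed:
        if not read.has_indel():
            continue
        rpos = read.start  # 0-based
        hit = False
        for op, n in read.ops:
            if op == "M":
                rpos += n
            elif op == "D":
                # deletion spans 1-based positions rpos+1 .. rpos+n
                if rpos + 1 <= right and rpos + n >= left:
                    hit = True
                rpos += n
            else:
                # insertion between 1-based positions rpos and rpos+1
                if left - 1 <= rpos <= right:
                    hit = True
        if hit:
            n_indel += 1
    return n_indel / len(result)


def error_corrected_frequency(frequency: float, error_rate: float) -> float:
    """Invert the uniform miscall channel: with per-base miscall rate ``e``,
    an A site with true edit rate ``r`` shows G at frequency
    ``r*(1-e) + (1-r)*e/3``; this returns ``r`` from the observed frequency."""
    if not 0.0 <= error_rate < 0.75:
        raise ValueError("error_rate must lie in [0, 0.75)")
    return max(0.0, (frequency - error_rate / 3.0) / (1.0 - 4.0 * error_rate / 3.0))
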