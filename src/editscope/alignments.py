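"""In-memory container for gapless genome alignments (a SAM subset).

Simulated RNA-seq reads are exon-contained and gapless, so the bulk of an
alignment set lives in uniform-length numpy blocks; occasional reads with
I/D CIGAR operations (e.g. parsed from a user SAM) are carried as
individual records.  Only M/I/D CIGAR operations are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import codes_to_seq


@dataclass
class ReadAln:
    """A single aligned read with an explicit CIGAR."""

    qname: str
    chrom: str
    start: int                      # 0-based leftmost reference position
    strand: str                     # '+' or '-'
    cigar: list[tuple[str, int]]    # ops over {'M','I','D'}
    seq: np.ndarray                 # uint8 base codes, query order
    quals: np.ndarray               # uint8 Phred
    mapq: int = 60

    def __post_init__(self) -> None:
        n_query = sum(n for op, n in self.cigar if op in "MI")
        if n_query != len(self.seq) or len(self.seq) != len(self.quals):
            raise ValueError(f"{self.qname}: CIGAR/sequence length mismatch")


@dataclass
class AlignmentSet:
    """Aligned reads over named references.

    ``seqs``/``quals`` hold gapless, uniform-length reads; ``extras`` holds
    any reads that do not fit the block (indels, other lengths).
    """

    chrom_names: list[str]
    seqs: np.ndarray                  # (n, L) uint8
    quals: np.ndarray                 # (n, L) uint8
    chrom_idx: np.ndarray             # (n,) int32
    starts: np.ndarray                # (n,) int64, 0-based
    minus: np.ndarray                 # (n,) bool, True for '-' strand reads
    mapq: np.ndarray                  # (n,) uint8
    extras: list[ReadAln] = field(default_factory=list)
    name: str = "aln"

    @classmethod
    def empty(cls, chrom_names: list[str], read_length: int = 0,
              name: str = "aln") -> "AlignmentSet":
        return cls(
            chrom_names=list(chrom_names),
            seqs=np.empty((0, read_length), dtype=np.uint8),
            quals=np.empty((0, read_length), dtype=np.uint8),
            chrom_idx=np.empty(0, dtype=np.int32),
            starts=np.empty(0, dtype=np.int64),
            minus=np.empty(0, dtype=bool),
            mapq=np.empty(0, dtype=np.uint8),
            name=name,
        )

    @property
    def n_block(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def __len__(self) -> int:
        return self.n_block + len(self.extras)

    def total_aligned_bases(self) -> int:
        block = int(self.n_block * self.read_length)
        extra = sum(sum(n for op, n in r.cigar if op == "M") for r in self.extras)
        return block + extra

    def take(self, indices: np.ndarray) -> "AlignmentSet":
        """Subset by indices over the combined ordering (block rows first,
        then extras); order within the subset follows the original order."""
        indices = np.sort(np.asarray(indices, dtype=np.int64))
        if len(indices) and (indices[0] < 0 or indices[-1] >= len(self)):
            raise IndexError("alignment index out of range")
        in_block = indices[indices < self.n_block]
        in_extra = indices[indices >= self.n_block] - self.n_block
        return AlignmentSet(
            chrom_names=self.chrom_names,
            seqs=self.seqs[in_block],
            quals=self.quals[in_block],
            chrom_idx=self.chrom_idx[in_block],
            starts=self.starts[in_block],
            minus=self.minus[in_block],
            mapq=self.mapq[in_block],
            extras=[self.extras[i] for i in in_extra],
            name=self.name,
        )

    def iter_sam_records(self):
        """Yield SAM fields (qname, flag, rname, pos1, mapq, cigar, seq, qual)."""
        qual_off = 33
        for i in range(self.n_block):
            flag = 16 if self.minus[i] else 0
            yield (
                f"{self.name}_{i}", flag, self.chrom_names[self.chrom_idx[i]],
                int(self.starts[i]) + 1, int(self.mapq[i]),
                f"{self.read_length}M",
                codes_to_seq(self.seqs[i]),
                (self.quals[i] + qual_off).astype(np.uint8).tobytes().decode(),
            )
        for j, r in enumerate(self.extras):
            flag = 16 if r.strand == "-" else 0
            cigar = "".join(f"{n}{op}" for op, n in r.cigar)
            yield (
                r.qname or f"{self.name}_x{j}", flag, r.chrom,
                r.start + 1, r.mapq, cigar,
                codes_to_seq(r.seq),
                (r.quals + qual_off).astype(np.uint8).tobytes().decode(),
            )

    def to_sam(self, path, chrom_lengths: dict[str, int]) -> None:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name in self.chrom_names:
                fh.write(f"@SQ\tSN:{name}\tLN:{chrom_lengths[name]}\n")
            for qname, flag, rname, pos, mapq, cigar, seq, qual in self.iter_sam_records():
                fh.write(f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t"
                         f"*\t0\t0\t{seq}\t{qual}\n")
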