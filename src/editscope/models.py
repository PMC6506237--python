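"""Core domain types shared across the simulator, quantifiers and callers.

Conventions
-----------
* Sequences are stored as plain ``str`` over ``ACGT`` or as ``uint8`` code
  arrays (A=0, C=1, G=2, T=3); :data:`BASE_TO_CODE` / :data:`CODE_TO_BASE`
  convert between the two.
* Coordinates are 0-based half-open internally.  Fields that are part of the
  public record types (``protospacer_start``, ``nick_position``, truth-table
  and pileup positions) are 1-based, matching SAM/VCF/GFF convention.
* Phred qualities follow the Sanger convention: per-base miscall probability
  ``10**(-Q/10)``, FASTQ encoding Phred+33.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        bad = chr(arr[int(np.argmax(codes == 255))])
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return CODE_TO_BASE[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Amplicon simulation inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconSpec:
    """A reference amplicon with protospacer, PAM and nick annotation.

    Protospacer positions are numbered 1-20 with the PAM occupying
    positions 21-23 (NGG for SpCas9).  ``nick_position`` is the 1-based
    amplicon coordinate of protospacer base 17; the Cas9(D10A) nick falls
    between that base and the next (3 bp 5' of the PAM).
    """

    name: str
    sequence: str
    protospacer_start: int  # 1-based amplicon coordinate of protospacer base 1
    nick_position: int      # 1-based amplicon coordinate (protospacer base 17)
    molecule: str = "DNA"   # "DNA" | "cDNA"

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set(BASES):
            raise ValueError(f"{self.name}: amplicon sequence must be over ACGT")
        if not 100 <= len(self.sequence) <= 500:
            raise ValueError(f"{self.name}: amplicon length must be 100-500 nt")
        if self.protospacer_start < 1 or self.protospacer_start + 22 > len(self.sequence):
            raise ValueError(f"{self.name}: protospacer+PAM does not fit in the amplicon")
        if not 1 <= self.nick_position <= len(self.sequence):
            raise ValueError(f"{self.name}: nick_position outside the amplicon")
        if self.molecule not in ("DNA", "cDNA"):
            raise ValueError("molecule must be 'DNA' or 'cDNA'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return seq_to_codes(self.sequence)

    @property
    def protospacer(self) -> str:
        i = self.protospacer_start - 1
        return self.sequence[i:i + 20]

    @property
    def pam(self) -> str:
        i = self.protospacer_start - 1
        return self.sequence[i + 20:i + 23]

    def protospacer_to_amplicon(self, position: int) -> int:
        """Map a 1-based protospacer position (PAM = 21-23) to a 1-based
        amplicon coordinate."""
        if not 1 <= position <= 23:
            raise ValueError("protospacer positions run 1-23 (PAM = 21-23)")
        return self.protospacer_start + position - 1

    @property
    def adenosine_positions(self) -> np.ndarray:
        """1-based positions of every reference A."""
        return np.flatnonzero(self.codes == BASE_TO_CODE["A"]) + 1


@dataclass(frozen=True)
class ProfileEntry:
    position: int       # 1-based coordinate on the amplicon / chromosome
    true_rate: float    # fraction of molecules carrying the edit
    origin: str = "editor"  # "endogenous" | "editor"
    chrom: str | None = None  # None for single-amplicon profiles

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_rate <= 1.0:
            raise ValueError("true_rate must lie in [0, 1]")
        if self.origin not in ("endogenous", "editor"):
            raise ValueError("origin must be 'endogenous' or 'editor'")


@dataclass(frozen=True)
class EditingProfile:
    """Per-adenosine ground-truth editing rates."""

    entries: tuple[ProfileEntry, ...]

    def __post_init__(self) -> None:
        keys = [(e.chrom, e.position) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("profile positions must be unique")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]],
                   origin: str = "editor",
                   chrom: str | None = None) -> "EditingProfile":
        return cls(tuple(ProfileEntry(p, r, origin, chrom) for p, r in pairs))

    def __iter__(self) -> Iterator[ProfileEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=np.int64)

    def merged_with(self, other: "EditingProfile") -> "EditingProfile":
        return EditingProfile(self.entries + other.entries)


@dataclass(frozen=True)
class QualityModel:
    """Phred qualities drawn from a truncated normal, rounded to integers.

    ``sd_q = 0`` gives constant qualities — used for the error-free and
    constant-Q study conditions.
    """

    mean_q: float = 32.0
    sd_q: float = 4.0
    min_q: int = 2
    max_q: int = 41

    def __post_init__(self) -> None:
        if self.min_q > self.max_q:
            raise ValueError("min_q must not exceed max_q")

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.sd_q == 0:
            q = np.full(shape, round(self.mean_q), dtype=np.int16)
        else:
            q = np.rint(rng.normal(self.mean_q, self.sd_q, size=shape)).astype(np.int16)
        return np.clip(q, self.min_q, self.max_q).astype(np.uint8)

    @property
    def expected_error_rate(self) -> float:
        """E[10**(-Q/10)] over the integer quality distribution."""
        if self.sd_q == 0:
            q = float(np.clip(round(self.mean_q), self.min_q, self.max_q))
            return 10.0 ** (-q / 10.0)
        from scipy.stats import norm
        grid = np.arange(self.min_q, self.max_q + 1)
        # probability that the rounded, clipped draw equals each integer
        upper = np.minimum(grid + 0.5, np.inf)
        cdf = norm.cdf((grid + 0.5 - self.mean_q) / self.sd_q)
        cdf_lo = norm.cdf((grid - 0.5 - self.mean_q) / self.sd_q)
        probs = cdf - cdf_lo
        probs[0] += cdf_lo[0]
        probs[-1] += 1.0 - cdf[-1]
        return float(np.sum(probs * 10.0 ** (-grid / 10.0)))


ERROR_FREE = QualityModel(mean_q=93, sd_q=0, min_q=93, max_q=93)
"""Quality model used to disable the error channel (Q93 ~ miscall 5e-10)."""


@dataclass(frozen=True)
class IndelSpec:
    """One programmed indel event type per run, placed relative to the nick."""

    offset: int = 0       # 0 = event starts at the base 3' of the nick
    length: int = 2
    kind: str = "del"     # "ins" | "del"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind not in ("ins", "del"):
            raise ValueError("indel kind must be 'ins' or 'del'")


@dataclass(frozen=True)
class SimConfig:
    depth: int = 10_000         # reads per amplicon, or mean per-base coverage
    read_length: int = 240
    seed: int = 0
    indel_rate: float = 0.0     # fraction of reads carrying the programmed indel
    indel_spec: IndelSpec = field(default_factory=IndelSpec)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["CHROM", "POS", "REF", "ALT", "TRUE_RATE", "ORIGIN"]


@dataclass
class TruthTable:
    """Ground truth for a simulation: one row per site with true_rate > 0.

    ``sites`` is a DataFrame with columns CHROM, POS (1-based), REF, ALT,
    TRUE_RATE, ORIGIN plus simulator bookkeeping columns (N_EDITED_READS,
    STRAND where applicable).  ``n_indel_reads`` records how many simulated
    reads carry the programmed indel.
    """

    sites: pd.DataFrame
    n_indel_reads: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"truth table missing columns: {missing}")
        key = self.sites[["CHROM", "POS"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("truth table sites must be unique")

    def __len__(self) -> int:
        return len(self.sites)

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Read sets (FASTQ-shaped, kept in numpy blocks for speed)
# ---------------------------------------------------------------------------

@dataclass
class ReadBlock:
    """A group of reads sharing one length, stored as code matrices."""

    seqs: np.ndarray    # (n, L) uint8 base codes
    quals: np.ndarray   # (n, L) uint8 Phred scores

    def __post_init__(self) -> None:
        if self.seqs.shape != self.quals.shape:
            raise ValueError("seqs and quals must share a shape")

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]


@dataclass
class ReadSet:
    """A set of single-end reads; iterable as (id, sequence, quality-string)."""

    blocks: list[ReadBlock]
    name: str = "read"

    def __len__(self) -> int:
        return sum(b.n for b in self.blocks)

    def iter_records(self) -> Iterator[tuple[str, str, str]]:
        i = 0
        for block in self.blocks:
            qual_ascii = (block.quals + 33).astype(np.uint8)
            for row in range(block.n):
                yield (f"{self.name}_{i}",
                       codes_to_seq(block.seqs[row]),
                       qual_ascii[row].tobytes().decode())
                i += 1

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.iter_records():
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    @classmethod
    def from_fastq(cls, path, name: str = "read") -> "ReadSet":
        from Bio import SeqIO
        by_length: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        order: list[int] = []
        for rec in SeqIO.parse(str(path), "fastq"):
            codes = seq_to_codes(str(rec.seq))
            quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.uint8)
            by_length.setdefault(len(codes), []).append((codes, quals))
            if len(codes) not in order:
                order.append(len(codes))
        blocks = [
            ReadBlock(np.array([s for s, _ in by_length[L]]),
                      np.array([q for _, q in by_length[L]]))
            for L in order
        ]
        return cls(blocks=blocks, name=name)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """A transcript on a named chromosome.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping.  ``cds`` is the genomic interval of the coding region
    (its exonic intersection must have length divisible by 3); ``None`` for
    noncoding transcripts.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.id}: empty exon {start}-{end}")
            if start < prev_end:
                raise ValueError(f"{self.id}: exons must be sorted and non-overlapping")
            prev_end = end
        if self.cds is not None:
            lo, hi = self.cds
            if not (self.exons[0][0] <= lo < hi <= self.exons[-1][1]):
                raise ValueError(f"{self.id}: CDS outside the exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_exonic_intervals(self) -> list[tuple[int, int]]:
        if self.cds is None:
            return []
        lo, hi = self.cds
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return out

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exonic_intervals())

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds_exonic_intervals())


@dataclass
class GeneModelSet:
    """Named chromosome sequences plus transcript models."""

    chromosomes: dict[str, str]
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.chrom not in self.chromosomes:
                raise ValueError(f"{t.id}: unknown chromosome {t.chrom}")
            if t.end > len(self.chromosomes[t.chrom]):
                raise ValueError(f"{t.id}: transcript extends past chromosome end")
            if t.cds is not None and t.cds_length % 3 != 0:
                raise ValueError(f"{t.id}: spliced CDS length not divisible by 3")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def transcripts_on(self, chrom: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.chrom == chrom]

    def spliced_sequence(self, t: Transcript) -> str:
        """Exonic sequence in transcript orientation (5'->3' of the mRNA)."""
        seq = "".join(self.chromosomes[t.chrom][s:e] for s, e in t.exons)
        return revcomp(seq) if t.strand == "-" else seq

    def cds_sequence(self, t: Transcript) -> str:
        seq = "".join(self.chromosomes[t.chrom][s:e] for s, e in t.cds_exonic_intervals())
        return revcomp(seq) if t.strand == "-" else seq

    def transcript_adenosines(self, t: Transcript) -> np.ndarray:
        """1-based genomic positions that are A on the transcript strand
        (genome A for '+' transcripts, genome T for '-')."""
        want = "A" if t.strand == "+" else "T"
        chrom_seq = self.chromosomes[t.chrom]
        positions = []
        for s, e in t.exons:
            block = np.frombuffer(chrom_seq[s:e].encode(), dtype=np.uint8)
            positions.append(np.flatnonzero(block == ord(want)) + s + 1)
        return np.concatenate(positions) if positions else np.array([], dtype=np.int64)
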