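"""Transcriptome-wide A-to-I edit calling and summary statistics.

The caller scores each adenosine pileup with an explicit two-hypothesis
Bayesian model:

* **H0 (no editing)** — every non-reference base is a sequencing miscall,
  with per-read probability ``10**(-Q/10)/3`` toward the observed base.
* **H1 (editing)** — an unknown fraction ``f`` of molecules carry the edit;
  the per-read likelihood is the ``f``-mixture of the edited and unedited
  base distributions, and ``f`` is marginalised over a uniform grid.

Mapping quality enters as a per-read mis-mapping probability that mixes the
read's evidence with an uninformative likelihood (1/4 per base).  The
posterior is converted to a Phred-scaled call quality
``QUAL = -10*log10(1 - posterior)``; QUAL >= 20 corresponds to posterior
>= 0.99, the high-confidence threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .alignments import AlignmentSet
from .amplicon import UndefinedStatisticError
from .models import BASE_TO_CODE, GeneModelSet

DEFAULT_F_GRID = np.linspace(0.01, 1.0, 100)
DEFAULT_PRIOR = 1e-3
DEFAULT_MIN_QUAL = 20.0
DEFAULT_QUAL_CAP = 90.0


class NoCoverageError(ValueError):
    pass


class InvalidPileupError(ValueError):
    pass


class InfeasibleDownsampleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

@dataclass
class SitePileup:
    """All read observations covering one reference position."""

    chrom: str
    pos: int                 # 1-based
    ref: str
    strand: str              # transcript strand: '+', '-' or '?'
    bases: np.ndarray        # (depth,) uint8 codes
    base_quals: np.ndarray   # (depth,) uint8 Phred
    map_quals: np.ndarray    # (depth,) uint8 Phred

    def __post_init__(self) -> None:
        if not (len(self.bases) == len(self.base_quals) == len(self.map_quals)):
            raise InvalidPileupError(
                f"{self.chrom}:{self.pos}: quality lists must match depth")

    @property
    def depth(self) -> int:
        return len(self.bases)

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.bases, minlength=4)[:4]

    @property
    def alt_base(self) -> str | None:
        """The base an A-to-I edit produces on the genome reference strand."""
        if self.strand == "+" and self.ref == "A":
            return "G"
        if self.strand == "-" and self.ref == "T":
            return "C"
        return None

    def alt_count(self, alt: str | None = None) -> int:
        alt = alt or self.alt_base
        if alt is None:
            raise InvalidPileupError(
                f"{self.chrom}:{self.pos}: not an adenosine on the "
                "transcript strand")
        return int((self.bases == BASE_TO_CODE[alt]).sum())


def site_pileups(
    aln: AlignmentSet,
    genome: dict[str, str],
    sites: list[tuple[str, int, str]],
    min_depth: int = 1,
) -> list[SitePileup]:
    """Build pileups at the requested (chrom, 1-based pos, strand) sites.

    Gapless block reads are piled up with vectorised sort/searchsorted;
    reads with I/D CIGARs are walked individually.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, strand in sites:
        by_chrom.setdefault(chrom, []).append((pos, strand))

    out: list[SitePileup] = []
    rl = aln.read_length
    for chrom, wanted in by_chrom.items():
        wanted = sorted(wanted)
        want_pos = np.array([p for p, _ in wanted], dtype=np.int64)
        try:
            ci = aln.chrom_names.index(chrom)
        except ValueError:
            ci = -1
        if ci >= 0 and aln.n_block:
            sel = np.flatnonzero(aln.chrom_idx == ci)
        else:
            sel = np.empty(0, dtype=np.int64)

        if len(sel):
            starts = aln.starts[sel]
            flat_pos = (starts[:, None] + np.arange(rl) + 1).ravel()  # 1-based
            flat_base = aln.seqs[sel].ravel()
            flat_bq = aln.quals[sel].ravel()
            flat_mq = np.repeat(aln.mapq[sel], rl)
            order = np.argsort(flat_pos, kind="stable")
            flat_pos = flat_pos[order]
            flat_base = flat_base[order]
            flat_bq = flat_bq[order]
            flat_mq = flat_mq[order]
            lo = np.searchsorted(flat_pos, want_pos, side="left")
            hi = np.searchsorted(flat_pos, want_pos, side="right")
        else:
            lo = hi = np.zeros(len(want_pos), dtype=np.int64)

        extra_hits: dict[int, list[tuple[int, int, int]]] = {}
        for read in aln.extras:
            if read.chrom != chrom:
                continue
            rpos, qpos = read.start, 0
            for op, n in read.cigar:
                if op == "M":
                    ov_lo = np.searchsorted(want_pos, rpos + 1)
                    ov_hi = np.searchsorted(want_pos, rpos + n, side="right")
                    for w in range(ov_lo, ov_hi):
                        off = want_pos[w] - 1 - rpos
                        extra_hits.setdefault(w, []).append(
                            (int(read.seq[qpos + off]),
                             int(read.quals[qpos + off]), read.mapq))
                    rpos += n
                    qpos += n
                elif op == "D":
                    rpos += n
                else:
                    qpos += n

        for w, (pos, strand) in enumerate(wanted):
            bases = flat_base[lo[w]:hi[w]] if len(sel) else np.empty(0, np.uint8)
            bq = flat_bq[lo[w]:hi[w]] if len(sel) else np.empty(0, np.uint8)
            mq = flat_mq[lo[w]:hi[w]] if len(sel) else np.empty(0, np.uint8)
            if w in extra_hits:
                eb, eq, em = zip(*extra_hits[w])
                bases = np.concatenate([bases, np.array(eb, dtype=np.uint8)])
                bq = np.concatenate([bq, np.array(eq, dtype=np.uint8)])
                mq = np.concatenate([mq, np.array(em, dtype=np.uint8)])
            if len(bases) < min_depth:
                continue
            out.append(SitePileup(
                chrom=chrom, pos=pos, ref=genome[chrom][pos - 1],
                strand=strand, bases=bases, base_quals=bq, map_quals=mq))
    return out


def adenosine_sites(models: GeneModelSet) -> list[tuple[str, int, str]]:
    """All transcript-strand adenosine positions as (chrom, pos, strand)."""
    seen: set[tuple[str, int]] = set()
    sites: list[tuple[str, int, str]] = []
    for t in models.transcripts:
        for pos in models.transcript_adenosines(t):
            key = (t.chrom, int(pos))
            if key not in seen:
                seen.add(key)
                sites.append((t.chrom, int(pos), t.strand))
    sites.sort()
    return sites


def mean_base_error_rate(pileups: list[SitePileup]) -> float:
    """Read-weighted mean per-base miscall probability 10**(-Q/10)."""
    total, n = 0.0, 0
    for p in pileups:
        total += float(np.sum(10.0 ** (-p.base_quals.astype(float) / 10.0)))
        n += p.depth
    if n == 0:
        raise NoCoverageError("no reads in pileups")
    return total / n


# ---------------------------------------------------------------------------
# Posterior model
# ---------------------------------------------------------------------------

@dataclass
class EditCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str
    depth: int
    alt_count: int
    edit_fraction: float
    posterior: float
    qual: float
    passed: bool


def posterior_to_qual(posterior: float,
                      cap: float = DEFAULT_QUAL_CAP) -> float:
    """Phred-scaled call quality; posterior 0.99 maps to exactly 20."""
    if posterior >= 1.0 - 10.0 ** (-cap / 10.0):
        return cap
    return -10.0 * math.log10(1.0 - posterior)


def qual_to_posterior(qual: float) -> float:
    return 1.0 - 10.0 ** (-qual / 10.0)


def edit_posterior(
    site: SitePileup,
    prior_edit: float = DEFAULT_PRIOR,
    f_grid: np.ndarray = DEFAULT_F_GRID,
    *,
    min_qual: float = DEFAULT_MIN_QUAL,
    qual_cap: float = DEFAULT_QUAL_CAP,
) -> EditCall:
    """Posterior probability of genuine editing at one adenosine pileup."""
    if site.depth == 0:
        raise NoCoverageError(f"{site.chrom}:{site.pos}: depth 0")
    if not 0.0 < prior_edit < 1.0:
        raise ValueError("prior_edit must lie in (0, 1)")
    alt = site.alt_base
    if alt is None:
        raise InvalidPileupError(
            f"{site.chrom}:{site.pos}: site is not an adenosine on the "
            "transcript strand")
    ref_code = BASE_TO_CODE[site.ref]
    alt_code = BASE_TO_CODE[alt]

    e = 10.0 ** (-site.base_quals.astype(float) / 10.0)
    m = 10.0 ** (-site.map_quals.astype(float) / 10.0)
    is_ref = site.bases == ref_code
    is_alt = site.bases == alt_code

    p_obs_given_ref = np.where(is_ref, 1.0 - e, e / 3.0)
    p_obs_given_alt = np.where(is_alt, 1.0 - e, e / 3.0)

    log_l0 = float(np.sum(np.log((1.0 - m) * p_obs_given_ref + m * 0.25)))
    f = np.asarray(f_grid, dtype=float)[:, None]
    mix = (1.0 - f) * p_obs_given_ref[None, :] + f * p_obs_given_alt[None, :]
    log_l1_f = np.sum(np.log((1.0 - m[None, :]) * mix + m[None, :] * 0.25), axis=1)
    log_l1 = float(logsumexp(log_l1_f) - math.log(len(f_grid)))

    # posterior log-odds; qual computed from log(1-posterior) for stability
    log_odds = math.log(prior_edit / (1.0 - prior_edit)) + log_l1 - log_l0
    posterior = 1.0 / (1.0 + math.exp(-log_odds)) if log_odds < 700 else 1.0
    log1m_post = -np.logaddexp(0.0, log_odds)
    qual = min(qual_cap, -10.0 * log1m_post / math.log(10.0))

    alt_count = int(is_alt.sum())
    passed = qual >= min_qual  # substitution admissibility is checked by filters
    return EditCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt,
        strand=site.strand, depth=site.depth, alt_count=alt_count,
        edit_fraction=alt_count / site.depth, posterior=posterior,
        qual=float(qual), passed=passed)


def call_edits(pileups: list[SitePileup], **kwargs) -> list[EditCall]:
    return [edit_posterior(p, **kwargs) for p in pileups]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

DEFAULT_ALLOWED = frozenset({("A", "G", "+"), ("T", "C", "-")})
GENOME_PLUS_ONLY = frozenset({("A", "G", "+"), ("A", "G", "?")})


@dataclass
class FilterResult:
    kept: list[EditCall]
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.kept)


def filter_edit_calls(
    calls: list[EditCall],
    min_qual: float = DEFAULT_MIN_QUAL,
    allowed: frozenset = DEFAULT_ALLOWED,
) -> FilterResult:
    """Retain A->G (transcript-strand) calls with QUAL >= ``min_qual``.

    ``allowed`` is a set of (ref, alt, strand) triples; by default A->G on
    '+' transcripts and T->C (genome strand) on '-' transcripts.
    """
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    kept: list[EditCall] = []
    dropped = {"substitution": 0, "qual": 0}
    for c in calls:
        if (c.ref, c.alt, c.strand) not in allowed:
            dropped["substitution"] += 1
        elif c.qual < min_qual:
            dropped["qual"] += 1
        else:
            kept.append(c)
    return FilterResult(kept=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# Down-sampling and replicate spread
# ---------------------------------------------------------------------------

def downsample(data, target_n: int, seed: int):
    """Uniform sampling of whole reads without replacement, order-preserving
    and deterministic for a given seed."""
    n = len(data)
    if target_n > n:
        raise InfeasibleDownsampleError(f"cannot draw {target_n} from {n} reads")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=target_n, replace=False))
    if hasattr(data, "take"):
        return data.take(idx)
    return [data[i] for i in idx]


@dataclass
class DownsampleStats:
    statistic: str
    values: list[float]
    mean: float
    spread: float   # SD across replicates ("the spread"), ddof=1

    @property
    def reps(self) -> int:
        return len(self.values)


def sem_by_repeated_downsampling(
    data,
    target_n: int,
    reps: int,
    base_seed: int,
    pipeline,
    statistic: str = "n_high_confidence_edits",
) -> DownsampleStats:
    """Replicate the full call-and-filter pipeline on independent
    down-samples (seeds ``base_seed + i``) and report the spread (SD across
    replicates) of the resulting statistic.

    ``pipeline`` maps a down-sampled data set to a number, e.g.
    ``lambda subset: len(filter_edit_calls(call_edits(...)).kept)``.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    values = [float(pipeline(downsample(data, target_n, base_seed + i)))
              for i in range(reps)]
    return DownsampleStats(
        statistic=statistic, values=values,
        mean=float(np.mean(values)),
        spread=float(np.std(values, ddof=1)))


# ---------------------------------------------------------------------------
# Condition comparison and summaries
# ---------------------------------------------------------------------------

@dataclass
class AdditionalEdits:
    count_difference: int
    n_novel_transcripts: int


def additional_edits(
    treated: list[EditCall],
    control: list[EditCall],
    models: GeneModelSet,
) -> AdditionalEdits:
    """Editor-attributable excess over the control condition.

    ``count_difference = |treated| - |control|``; a transcript is *novel* if
    it contains >=1 treated call and no control call within its exons.
    """
    treated_sites = {(c.chrom, c.pos) for c in treated}
    control_sites = {(c.chrom, c.pos) for c in control}
    novel = 0
    for t in models.transcripts:
        has_treated = has_control = False
        for chrom, pos in treated_sites:
            if chrom == t.chrom and t.in_exon(pos - 1):
                has_treated = True
                break
        if not has_treated:
            continue
        for chrom, pos in control_sites:
            if chrom == t.chrom and t.in_exon(pos - 1):
                has_control = True
                break
        if not has_control:
            novel += 1
    return AdditionalEdits(
        count_difference=len(treated) - len(control),
        n_novel_transcripts=novel)


def transcriptome_average_frequency(
    pileups: list[SitePileup],
    min_coverage: int = 20,
    weighting: str = "read",
) -> float:
    """Average A-to-I editing frequency (percent) over adenosine pileups
    with coverage >= ``min_coverage``.

    ``weighting='read'`` (default): 100 * edited reads / total reads at the
    surviving sites.  ``weighting='site'``: 100 * (sites with >=1 edited
    read) / surviving sites.
    """
    if weighting not in ("read", "site"):
        raise ValueError("weighting must be 'read' or 'site'")
    edited_reads = total_reads = 0
    edited_sites = total_sites = 0
    for p in pileups:
        if p.depth < min_coverage:
            continue
        alt = p.alt_count()
        edited_reads += alt
        total_reads += p.depth
        edited_sites += 1 if alt > 0 else 0
        total_sites += 1
    if total_sites == 0:
        raise UndefinedStatisticError(
            f"no adenosines with coverage >= {min_coverage}")
    if weighting == "read":
        return 100.0 * edited_reads / total_reads
    return 100.0 * edited_sites / total_sites


def bin_edit_density(
    calls: list[EditCall],
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Count calls in half-open ``bin_size`` windows along each chromosome.

    A 1-based position p falls into bin ``(p - 1) // bin_size``; the last
    bin is truncated at the chromosome end.  Returns a BED-like frame with
    columns chrom, start (0-based), end, count, covering every bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    counts: dict[str, np.ndarray] = {
        chrom: np.zeros(max(1, -(-length // bin_size)), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    for c in calls:
        if c.chrom not in chrom_lengths:
            raise ValueError(f"call on unknown chromosome {c.chrom}")
        if not 1 <= c.pos <= chrom_lengths[c.chrom]:
            raise ValueError(f"call at {c.chrom}:{c.pos} beyond chromosome end")
        counts[c.chrom][(c.pos - 1) // bin_size] += 1
    rows = []
    for chrom, arr in counts.items():
        length = chrom_lengths[chrom]
        for k, n in enumerate(arr):
            rows.append({"chrom": chrom, "start": k * bin_size,
                         "end": min((k + 1) * bin_size, length),
                         "count": int(n)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
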