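"""Synthetic sequencing data with per-site editing ground truth.

The generator emulates the statistical structure of base-editor experiments:

* **Amplicon deep sequencing** — single-end reads covering a full 100-500 nt
  amplicon at depths of 10^4-2x10^5, with low-frequency (0.05-2%)
  adenosine-to-inosine edits (read as A->G), Phred-calibrated miscalls, and
  optionally a programmed indel near the Cas9(D10A) nick site.
* **Mini-transcriptome RNA-seq** — gapless exon-contained reads over a small
  synthetic genome with gene models, endogenous-deaminase and editor-induced
  edit sites, strand-aware (minus-strand transcript edits appear as T->C on
  the genome reference).

All randomness flows through one integer seed; identical configuration gives
byte-identical FASTQ/SAM/truth outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alignments import AlignmentSet
from .models import (
    AmpliconSpec,
    EditingProfile,
    GeneModelSet,
    QualityModel,
    ReadBlock,
    ReadSet,
    SimConfig,
    Transcript,
    TruthTable,
    codes_to_seq,
    seq_to_codes,
)

# DNA sense of the RSL1D1 region homologous to the native TadA tRNA substrate
TADA_SUBSTRATE_MOTIF = "TCGGCTACGGAA"

_CHUNK = 1 << 15


class DegenerateReferenceError(ValueError):
    """No valid NGG protospacer placement exists in a generated reference."""


class InvalidProfileError(ValueError):
    """An editing-profile position does not carry A on the edited strand."""


# ---------------------------------------------------------------------------
# Amplicon reference construction
# ---------------------------------------------------------------------------

def make_amplicon_reference(
    seed: int,
    length: int = 240,
    gc_fraction: float = 0.5,
    *,
    n_adenosines: int | None = None,
    embed_motif: bool = False,
    target_a_protospacer_position: int | None = None,
    molecule: str = "DNA",
    name: str | None = None,
) -> AmpliconSpec:
    """Generate a random amplicon with a valid SpCas9 protospacer.

    The protospacer is placed at an existing NGG PAM (positions 21-23 of the
    protospacer numbering) closest to the amplicon centre; the nick position
    is derived from it (between protospacer bases 17 and 18).  Optional
    constraints are applied by construction: an exact adenosine count
    (``n_adenosines``), an embedded TadA-substrate-homology motif, and a
    target A at a chosen protospacer position.
    """
    if not 100 <= length <= 500:
        raise ValueError("amplicon length must be 100-500 nt")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)

    # protospacer: need GG at protospacer positions 22-23 (0-based ps+21, ps+22)
    gg = (codes[:-1] == 2) & (codes[1:] == 2)
    candidates = [i - 21 for i in np.flatnonzero(gg) if 0 <= i - 21 <= length - 23]
    if not candidates:
        raise DegenerateReferenceError("no NGG PAM placement possible")
    centre = length // 2 - 11
    ps0 = min(candidates, key=lambda c: (abs(c - centre), c))
    protected = {ps0 + 21, ps0 + 22}

    if target_a_protospacer_position is not None:
        if not 1 <= target_a_protospacer_position <= 20:
            raise ValueError("target A must lie within protospacer positions 1-20")
        tpos = ps0 + target_a_protospacer_position - 1
        codes[tpos] = 0
        protected.add(tpos)

    if embed_motif:
        motif = seq_to_codes(TADA_SUBSTRATE_MOTIF)
        span = len(motif)
        placed = False
        for off in range(5, length - span - 5):
            window = set(range(off, off + span))
            if window & set(range(ps0, ps0 + 23)) or window & protected:
                continue
            codes[off:off + span] = motif
            protected |= window
            placed = True
            break
        if not placed:
            raise DegenerateReferenceError("no room to embed the substrate motif")

    if n_adenosines is not None:
        is_a = codes == 0
        free = np.array([i for i in range(length) if i not in protected])
        have = int(is_a.sum())
        if n_adenosines > have:
            pool = free[~is_a[free]]
            need = n_adenosines - have
            if need > len(pool):
                raise DegenerateReferenceError("cannot reach requested adenosine count")
            codes[rng.choice(pool, size=need, replace=False)] = 0
        elif n_adenosines < have:
            pool = free[is_a[free]]
            drop = have - n_adenosines
            if drop > len(pool):
                raise DegenerateReferenceError("cannot reach requested adenosine count")
            chosen = rng.choice(pool, size=drop, replace=False)
            codes[chosen] = rng.choice([1, 3], size=drop)  # A -> C or T

    return AmpliconSpec(
        name=name or f"amplicon_seed{seed}",
        sequence=codes_to_seq(codes),
        protospacer_start=ps0 + 1,
        nick_position=ps0 + 17,  # 1-based coordinate of protospacer base 17
        molecule=molecule,
    )


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

def _apply_errors(rng: np.random.Generator, mat: np.ndarray,
                  qm: QualityModel) -> np.ndarray:
    """Draw qualities, then miscall each base with probability 10^(-Q/10),
    uniformly toward the three other bases.  Returns the quality matrix."""
    quals = qm.draw(rng, mat.shape)
    miscall = 10.0 ** (quals.astype(np.float32) / -10.0)
    err = rng.random(mat.shape, dtype=np.float32) < miscall
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    mat[err] = (mat[err] + shift[err]) % 4
    return quals


def _check_amplicon_profile(spec: AmpliconSpec, profile: EditingProfile) -> None:
    codes = spec.codes
    for entry in profile:
        if not 1 <= entry.position <= len(spec):
            raise InvalidProfileError(
                f"profile position {entry.position} outside amplicon {spec.name}")
        if codes[entry.position - 1] != 0:
            raise InvalidProfileError(
                f"position {entry.position} of {spec.name} is not an A")


def simulate_amplicon_reads(
    spec: AmpliconSpec,
    profile: EditingProfile,
    qm: QualityModel,
    cfg: SimConfig,
) -> tuple[ReadSet, TruthTable]:
    """Simulate single-end reads covering the full amplicon.

    Per profiled adenosine, each read carries the edit (G) independently with
    probability ``true_rate``; sequencing errors are then applied per base at
    rate ``10**(-Q/10)``.  A fraction ``cfg.indel_rate`` of reads carries the
    one programmed indel of ``cfg.indel_spec``, placed relative to the nick.
    """
    _check_amplicon_profile(spec, profile)
    ref = spec.codes
    L = len(ref)
    rng = np.random.default_rng(cfg.seed)

    ispec = cfg.indel_spec
    # first inserted/deleted base sits 3' of the nicked phosphodiester
    event0 = spec.nick_position + ispec.offset  # 0-based column
    if cfg.indel_rate > 0 and not 0 <= event0 <= L - (ispec.length if ispec.kind == "del" else 0):
        raise ValueError("programmed indel does not fit in the amplicon")
    ins_codes = rng.integers(0, 4, size=ispec.length, dtype=np.uint8)

    entries = list(profile)
    n_edited = np.zeros(len(entries), dtype=np.int64)
    plain_seq, plain_q, ind_seq, ind_q = [], [], [], []

    done = 0
    while done < cfg.depth:
        n = min(_CHUNK, cfg.depth - done)
        mat = np.repeat(ref[None, :], n, axis=0)
        for k, entry in enumerate(entries):
            if entry.true_rate <= 0:
                continue
            mask = rng.random(n, dtype=np.float32) < entry.true_rate
            mat[mask, entry.position - 1] = 2  # G
            n_edited[k] += int(mask.sum())
        carriers = (rng.random(n, dtype=np.float32) < cfg.indel_rate
                    if cfg.indel_rate > 0 else np.zeros(n, dtype=bool))

        plain = mat[~carriers]
        plain_q.append(_apply_errors(rng, plain, qm))
        plain_seq.append(plain)

        if carriers.any():
            rows = mat[carriers]
            if ispec.kind == "del":
                rows = np.delete(rows, np.s_[event0:event0 + ispec.length], axis=1)
            else:
                rows = np.concatenate(
                    [rows[:, :event0],
                     np.repeat(ins_codes[None, :], rows.shape[0], axis=0),
                     rows[:, event0:]], axis=1)
            ind_q.append(_apply_errors(rng, rows, qm))
            ind_seq.append(rows)
        done += n

    blocks = [ReadBlock(np.concatenate(plain_seq), np.concatenate(plain_q))]
    n_indel = 0
    if ind_seq:
        block = ReadBlock(np.concatenate(ind_seq), np.concatenate(ind_q))
        n_indel = block.n
        blocks.append(block)

    rows = [
        {"CHROM": spec.name, "POS": e.position, "REF": "A", "ALT": "G",
         "TRUE_RATE": e.true_rate, "ORIGIN": e.origin, "STRAND": "+",
         "N_EDITED_READS": int(n_edited[k])}
        for k, e in enumerate(entries) if e.true_rate > 0
    ]
    truth = TruthTable(pd.DataFrame(rows, columns=["CHROM", "POS", "REF", "ALT",
                                                   "TRUE_RATE", "ORIGIN", "STRAND",
                                                   "N_EDITED_READS"]),
                       n_indel_reads=n_indel)
    return ReadSet(blocks=blocks, name=f"{spec.name}_read"), truth


# ---------------------------------------------------------------------------
# Gene model generation
# ---------------------------------------------------------------------------

def make_gene_models(
    seed: int,
    n_transcripts: int = 100,
    *,
    n_chromosomes: int = 2,
    exons_per_transcript: tuple[int, int] = (1, 3),
    exon_length: tuple[int, int] = (150, 320),
    intron_length: tuple[int, int] = (200, 900),
    intergenic_gap: tuple[int, int] = (11_000, 16_000),
    noncoding_fraction: float = 0.1,
    expression_sd: float = 0.8,
) -> GeneModelSet:
    """Generate a mini-genome with non-overlapping transcript models.

    Transcripts are laid out sequentially with intergenic gaps wide enough
    that 5-kb flanking regions and true intergenic space both exist.  Coding
    transcripts get a CDS whose spliced length is divisible by 3, leaving
    UTRs on both sides.
    """
    rng = np.random.default_rng(seed)
    per_chrom = [n_transcripts // n_chromosomes] * n_chromosomes
    for i in range(n_transcripts % n_chromosomes):
        per_chrom[i] += 1

    chromosomes: dict[str, str] = {}
    transcripts: list[Transcript] = []
    t_index = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = int(rng.integers(*intergenic_gap))
        for _ in range(per_chrom[c]):
            n_ex = int(rng.integers(exons_per_transcript[0], exons_per_transcript[1] + 1))
            exons = []
            pos = cursor
            for e in range(n_ex):
                ex_len = int(rng.integers(*exon_length))
                exons.append((pos, pos + ex_len))
                pos += ex_len
                if e < n_ex - 1:
                    pos += int(rng.integers(*intron_length))
            strand = "+" if rng.random() < 0.5 else "-"
            cds = None
            if rng.random() >= noncoding_fraction:
                exonic = np.concatenate([np.arange(s, e) for s, e in exons])
                n_exonic = len(exonic)
                utr5 = int(rng.integers(10, max(11, n_exonic // 5)))
                utr3 = int(rng.integers(10, max(11, n_exonic // 5)))
                span = n_exonic - utr5 - utr3
                span -= span % 3
                if span >= 30:
                    cds = (int(exonic[utr5]), int(exonic[utr5 + span - 1]) + 1)
            transcripts.append(Transcript(
                id=f"tx{t_index:04d}", chrom=chrom, strand=strand,
                exons=tuple(exons), cds=cds,
                weight=float(rng.lognormal(0.0, expression_sd)),
            ))
            t_index += 1
            cursor = pos + int(rng.integers(*intergenic_gap))
        chrom_len = cursor + int(rng.integers(*intergenic_gap))
        chromosomes[chrom] = codes_to_seq(
            rng.integers(0, 4, size=chrom_len, dtype=np.uint8))
    return GeneModelSet(chromosomes=chromosomes, transcripts=transcripts)


def uniform_transcriptome_profile(
    models: GeneModelSet,
    rate: float,
    origin: str = "editor",
    *,
    fraction: float = 1.0,
    seed: int = 0,
) -> EditingProfile:
    """Profile covering (a sampled fraction of) all transcript-strand
    adenosines at one uniform true rate."""
    rng = np.random.default_rng(seed)
    sites: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    for t in models.transcripts:
        for pos in models.transcript_adenosines(t):
            key = (t.chrom, int(pos))
            if key not in seen:
                seen.add(key)
                sites.append(key)
    sites.sort()
    if fraction < 1.0:
        keep = rng.random(len(sites)) < fraction
        sites = [s for s, k in zip(sites, keep) if k]
    from .models import ProfileEntry
    return EditingProfile(tuple(
        ProfileEntry(pos, rate, origin, chrom) for chrom, pos in sites))


# ---------------------------------------------------------------------------
# Transcriptome simulation
# ---------------------------------------------------------------------------

def _site_transcript_map(
    models: GeneModelSet, profile: EditingProfile,
) -> dict[tuple[str | None, int], Transcript]:
    """Validate profile positions and map each (chrom, pos) to the transcript
    whose exons contain it."""
    mapping: dict[tuple[str | None, int], Transcript] = {}
    for entry in profile:
        pos0 = entry.position - 1
        owner = None
        for t in models.transcripts:
            if (entry.chrom is None or t.chrom == entry.chrom) and t.in_exon(pos0):
                owner = t
                break
        if owner is None:
            raise InvalidProfileError(
                f"profile position {entry.chrom}:{entry.position} is not exonic")
        want = "A" if owner.strand == "+" else "T"
        if models.chromosomes[owner.chrom][pos0] != want:
            raise InvalidProfileError(
                f"position {entry.chrom}:{entry.position} is not an A "
                "on the transcript strand")
        mapping[(entry.chrom, entry.position)] = owner
    return mapping


def simulate_transcriptome(
    models: GeneModelSet,
    endo: EditingProfile,
    editor: EditingProfile,
    qm: QualityModel,
    cfg: SimConfig,
) -> tuple[AlignmentSet, TruthTable]:
    """Simulate gapless exon-contained RNA-seq reads over the mini-genome.

    Per-transcript read counts are Poisson around ``cfg.depth`` (mean
    coverage) scaled by the transcript expression weight.  Edits at profiled
    sites appear as G on + transcripts and as C (genome strand) on -
    transcripts.  Profile positions are genomic 1-based coordinates; because
    generated transcripts do not overlap, a position identifies one
    transcript.  Positions used in both profiles must be disjoint.

    Note: transcript coordinates here live on a shared genomic axis per
    chromosome laid out by :func:`make_gene_models`; the simulator resolves
    each profiled position to the transcript whose exons contain it.
    """
    overlap = ({(e.chrom, e.position) for e in endo}
               & {(e.chrom, e.position) for e in editor})
    if overlap:
        raise InvalidProfileError(
            f"endogenous and editor profiles overlap at {sorted(overlap)[:5]}")
    merged = endo.merged_with(editor)
    owners = _site_transcript_map(models, merged)

    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length
    chrom_names = list(models.chromosomes)
    chrom_codes = {c: seq_to_codes(s) for c, s in models.chromosomes.items()}
    mean_w = float(np.mean([t.weight for t in models.transcripts])) or 1.0

    by_transcript: dict[str, list] = {}
    for entry in merged:
        by_transcript.setdefault(owners[(entry.chrom, entry.position)].id,
                                 []).append(entry)

    seqs, quals, cidx, starts_all, minus_all = [], [], [], [], []
    n_edited = {(e.chrom, e.position): 0 for e in merged}

    for t in models.transcripts:
        eligible = [(s, e) for s, e in t.exons if e - s >= rl]
        if not eligible:
            continue
        lam = cfg.depth * (t.weight / mean_w) * t.exonic_length / rl
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        weights = np.array([e - s - rl + 1 for s, e in eligible], dtype=float)
        exon_pick = rng.choice(len(eligible), size=n, p=weights / weights.sum())
        offsets = rng.integers(0, weights[exon_pick].astype(np.int64))
        starts = np.array([eligible[i][0] for i in exon_pick]) + offsets
        mat = chrom_codes[t.chrom][starts[:, None] + np.arange(rl)]

        for entry in by_transcript.get(t.id, []):
            pos0 = entry.position - 1
            covered = (starts <= pos0) & (pos0 < starts + rl)
            edited = covered & (rng.random(n, dtype=np.float32) < entry.true_rate)
            if edited.any():
                alt_code = 2 if t.strand == "+" else 1  # G on '+', C on '-'
                rows = np.flatnonzero(edited)
                mat[rows, pos0 - starts[rows]] = alt_code
                n_edited[(entry.chrom, entry.position)] += len(rows)

        quals.append(_apply_errors(rng, mat, qm))
        seqs.append(mat)
        cidx.append(np.full(n, chrom_names.index(t.chrom), dtype=np.int32))
        starts_all.append(starts.astype(np.int64))
        minus_all.append(np.full(n, t.strand == "-"))

    if seqs:
        aln = AlignmentSet(
            chrom_names=chrom_names,
            seqs=np.concatenate(seqs),
            quals=np.concatenate(quals),
            chrom_idx=np.concatenate(cidx),
            starts=np.concatenate(starts_all),
            minus=np.concatenate(minus_all),
            mapq=np.full(sum(len(s) for s in starts_all), 60, dtype=np.uint8),
            name="rnaseq",
        )
    else:
        aln = AlignmentSet.empty(chrom_names, rl, name="rnaseq")

    rows = []
    for entry in merged:
        if entry.true_rate <= 0:
            continue
        t = owners[(entry.chrom, entry.position)]
        ref = "A" if t.strand == "+" else "T"
        alt = "G" if t.strand == "+" else "C"
        rows.append({"CHROM": t.chrom, "POS": entry.position, "REF": ref,
                     "ALT": alt, "TRUE_RATE": entry.true_rate,
                     "ORIGIN": entry.origin, "STRAND": t.strand,
                     "TRANSCRIPT": t.id,
                     "N_EDITED_READS": n_edited[(entry.chrom, entry.position)]})
    truth = TruthTable(pd.DataFrame(
        rows, columns=["CHROM", "POS", "REF", "ALT", "TRUE_RATE", "ORIGIN",
                       "STRAND", "TRANSCRIPT", "N_EDITED_READS"]))
    return aln, truth
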