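"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM and VCF are read with pysam, GFF3
with gffutils; writers emit the plain-text subsets the in-memory types
carry (SAM with M/I/D CIGARs, VCF 4.2, 6-column BED with a count column,
GFF3 gene models).  ``write . read`` is the identity on the supported
feature subset; malformed records are rejected with the offending record
named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import AlignmentSet, ReadAln
from .models import GeneModelSet, ReadSet, Transcript, TruthTable, seq_to_codes
from .transcriptome import EditCall


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path, name: str = "read") -> ReadSet:
    return ReadSet.from_fastq(path, name=name)


def write_fastq(reads: ReadSet, path) -> None:
    reads.to_fastq(path)


# ---------------------------------------------------------------------------
# SAM subset (M/I/D operations, Phred+33)
# ---------------------------------------------------------------------------

def write_sam(aln: AlignmentSet, path, chrom_lengths: dict[str, int]) -> None:
    aln.to_sam(path, chrom_lengths)


def read_sam(path, name: str = "aln") -> AlignmentSet:
    """Read a SAM file into an :class:`AlignmentSet`.

    Gapless records sharing the modal read length become the fast block;
    everything else (I/D CIGARs, other lengths) goes to ``extras``.
    Unsupported CIGAR operations raise :class:`FormatError`.
    """
    import pysam
    records: list[ReadAln] = []
    chrom_names: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        chrom_names = list(sam.references)
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            cigar = []
            for op, n in rec.cigartuples or []:
                letter = "MIDNSHP=X"[op]
                if letter not in "MID":
                    raise FormatError(
                        f"record {rec.query_name}: unsupported CIGAR op "
                        f"{letter}")
                cigar.append((letter, n))
            quals = (np.array(rec.query_qualities, dtype=np.uint8)
                     if rec.query_qualities is not None
                     else np.zeros(len(rec.query_sequence), dtype=np.uint8))
            records.append(ReadAln(
                qname=rec.query_name, chrom=rec.reference_name,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar, seq=seq_to_codes(rec.query_sequence),
                quals=quals, mapq=rec.mapping_quality))

    gapless = [r for r in records
               if len(r.cigar) == 1 and r.cigar[0][0] == "M"]
    lengths = [len(r.seq) for r in gapless]
    modal = max(set(lengths), key=lengths.count) if lengths else 0
    block = [r for r in gapless if len(r.seq) == modal]
    block_ids = {id(r) for r in block}
    extras = [r for r in records if id(r) not in block_ids]
    if block:
        return AlignmentSet(
            chrom_names=chrom_names,
            seqs=np.array([r.seq for r in block]),
            quals=np.array([r.quals for r in block]),
            chrom_idx=np.array([chrom_names.index(r.chrom) for r in block],
                               dtype=np.int32),
            starts=np.array([r.start for r in block], dtype=np.int64),
            minus=np.array([r.strand == "-" for r in block]),
            mapq=np.array([r.mapq for r in block], dtype=np.uint8),
            extras=extras, name=name)
    out = AlignmentSet.empty(chrom_names, 0, name=name)
    out.extras = extras
    return out


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=editscope
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Edited (alt) read count">
##INFO=<ID=EF,Number=1,Type=Float,Description="Edit fraction (AC/DP)">
##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[EditCall], path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        if chrom_lengths:
            parts = _VCF_HEADER.splitlines(keepends=True)
            fh.writelines(parts[:-1])
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write(parts[-1])
        else:
            fh.write(_VCF_HEADER)
        for c in calls:
            info = (f"DP={c.depth};AC={c.alt_count};EF={c.edit_fraction:.6g};"
                    f"STRAND={c.strand}")
            filt = "PASS" if c.passed else "lowqual"
            fh.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t"
                     f"{c.qual:.4g}\t{filt}\t{info}\n")


def read_vcf(path) -> list[EditCall]:
    import pysam
    calls: list[EditCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch():
            depth = int(rec.info.get("DP", 0))
            ac = int(rec.info.get("AC", 0))
            qual = float(rec.qual if rec.qual is not None else 0.0)
            calls.append(EditCall(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alts[0] if rec.alts else ".",
                strand=str(rec.info.get("STRAND", "?")),
                depth=depth, alt_count=ac,
                edit_fraction=float(rec.info.get("EF", 0.0)),
                posterior=1.0 - 10.0 ** (-qual / 10.0),
                qual=qual,
                passed="PASS" in rec.filter.keys() if rec.filter else True))
    return calls


# ---------------------------------------------------------------------------
# BED (bins with a count column)
# ---------------------------------------------------------------------------

def write_bed(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", header=False, index=False,
                columns=["chrom", "start", "end", "count"])


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(models: GeneModelSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in models.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for t in models.transcripts:
            attrs = f"ID={t.id};expression_weight={t.weight:.6g}"
            fh.write(f"{t.chrom}\tsim\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                     f"{t.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(t.exons):
                fh.write(f"{t.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t"
                         f".\tID={t.id}.exon{i};Parent={t.id}\n")
            if t.cds is not None:
                for i, (s, e) in enumerate(t.cds_exonic_intervals()):
                    fh.write(f"{t.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{t.strand}\t0\tID={t.id}.cds{i};Parent={t.id}\n")


def read_gff3(path, chromosomes: dict[str, str]) -> GeneModelSet:
    """Parse transcript/exon/CDS features into a :class:`GeneModelSet`;
    chromosome sequences are supplied separately (e.g. from FASTA)."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    transcripts: list[Transcript] = []
    for feat in db.features_of_type("transcript"):
        exons = sorted((e.start - 1, e.end)
                       for e in db.children(feat, featuretype="exon"))
        cds_parts = sorted((c.start - 1, c.end)
                           for c in db.children(feat, featuretype="CDS"))
        cds = (cds_parts[0][0], cds_parts[-1][1]) if cds_parts else None
        weight = float(feat.attributes.get("expression_weight", ["1.0"])[0])
        transcripts.append(Transcript(
            id=feat.id, chrom=feat.seqid, strand=feat.strand,
            exons=tuple(exons), cds=cds, weight=weight))
    return GeneModelSet(chromosomes=chromosomes, transcripts=transcripts)


# ---------------------------------------------------------------------------
# TSV / truth tables / flat config
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTable, path) -> None:
    truth.to_tsv(path)


def read_truth(path) -> TruthTable:
    return TruthTable.from_tsv(path)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_config(path) -> dict[str, str]:
    """Flat key=value configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key}={value}\n")
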