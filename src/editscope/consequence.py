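"""Positional and coding-consequence classification of A-to-I edits.

Each retained edit is assigned exactly one category relative to the gene
models — CDS, 5'UTR, 3'UTR, noncoding-transcript, upstream-5kb,
downstream-5kb or intergenic — with precedence CDS > UTR >
noncoding-transcript > flanking-5kb > intergenic and ties among transcripts
broken by longest CDS then lexicographic id.  CDS edits are additionally
classified as synonymous or nonsynonymous by rebuilding the affected codon
in transcript orientation (A->G on '+' transcripts; the genomic T->C change
reads as A->G on '-' transcripts) and translating with the standard nuclear
genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .amplicon import UndefinedStatisticError
from .models import GeneModelSet, Transcript

CATEGORIES = [
    "CDS", "5'UTR", "3'UTR", "noncoding-transcript",
    "upstream-5kb", "downstream-5kb", "intergenic",
]
_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class ConsequenceRecord:
    chrom: str
    pos: int                   # 1-based
    category: str
    transcript_id: str | None = None
    codon_before: str | None = None
    codon_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None
    synonymous: bool | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        in_cds = self.category == "CDS"
        if in_cds != (self.codon_before is not None):
            raise ValueError("codon fields present iff category is CDS")


def _transcript_category(pos0: int, t: Transcript, flank: int) -> str | None:
    """Category of a 0-based genomic position relative to one transcript,
    or None if more than ``flank`` nt away."""
    if t.in_exon(pos0):
        if t.cds is None:
            return "noncoding-transcript"
        if t.in_cds(pos0):
            return "CDS"
        lo, hi = t.cds
        before_cds = pos0 < lo
        five_prime = before_cds if t.strand == "+" else not before_cds
        return "5'UTR" if five_prime else "3'UTR"
    if t.contains(pos0):          # intronic
        return "noncoding-transcript"
    if t.start - flank <= pos0 < t.start:
        return "upstream-5kb" if t.strand == "+" else "downstream-5kb"
    if t.end <= pos0 < t.end + flank:
        return "downstream-5kb" if t.strand == "+" else "upstream-5kb"
    return None


def classify_region(call, models: GeneModelSet, flank: int = 5000
                    ) -> tuple[str, Transcript | None]:
    """Assign the winning (category, transcript) for a call.

    ``call`` needs ``chrom`` and 1-based ``pos`` attributes.  Precedence:
    CDS > 5'/3'UTR > noncoding-transcript > upstream/downstream-5kb >
    intergenic; among equal categories the transcript with the longest CDS
    wins, then the lexicographically smallest id.
    """
    pos0 = call.pos - 1
    best: tuple[int, int, str, str, Transcript] | None = None
    for t in models.transcripts_on(call.chrom):
        cat = _transcript_category(pos0, t, flank)
        if cat is None:
            continue
        key = (_RANK[cat], -t.cds_length, t.id)
        if best is None or key < best[:3]:
            best = (*key, cat, t)
    if best is None:
        return "intergenic", None
    return best[3], best[4]


def coding_consequence(call, transcript: Transcript,
                       models: GeneModelSet) -> ConsequenceRecord:
    """Codon-level consequence of an A-to-I edit inside a CDS."""
    pos0 = call.pos - 1
    if not transcript.in_cds(pos0):
        raise ValueError(f"{call.chrom}:{call.pos} is not in the CDS of "
                         f"{transcript.id}")
    cds_seq = models.cds_sequence(transcript)
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"{transcript.id}: CDS frame broken")

    # index of the edited base within the spliced CDS, transcript orientation
    offset = 0
    cds_index = None
    for s, e in transcript.cds_exonic_intervals():
        if s <= pos0 < e:
            cds_index = offset + (pos0 - s)
            break
        offset += e - s
    if cds_index is None:
        raise ValueError("position not covered by CDS exons")
    if transcript.strand == "-":
        cds_index = len(cds_seq) - 1 - cds_index

    if cds_seq[cds_index] != "A":
        raise ValueError(f"{call.chrom}:{call.pos}: CDS base is not an A on "
                         "the transcript strand")
    codon_i = cds_index // 3
    within = cds_index % 3
    before = cds_seq[3 * codon_i:3 * codon_i + 3]
    after = before[:within] + "G" + before[within + 1:]
    aa_before = str(Seq(before).translate())
    aa_after = str(Seq(after).translate())
    return ConsequenceRecord(
        chrom=call.chrom, pos=call.pos, category="CDS",
        transcript_id=transcript.id,
        codon_before=before, codon_after=after,
        aa_before=aa_before, aa_after=aa_after,
        synonymous=aa_before == aa_after)


def classify_call(call, models: GeneModelSet, flank: int = 5000
                  ) -> ConsequenceRecord:
    """Full classification of one call (region + codon consequence)."""
    category, transcript = classify_region(call, models, flank)
    if category == "CDS":
        return coding_consequence(call, transcript, models)
    return ConsequenceRecord(
        chrom=call.chrom, pos=call.pos, category=category,
        transcript_id=transcript.id if transcript else None)


def annotate_calls(calls, models: GeneModelSet, flank: int = 5000
                   ) -> list[ConsequenceRecord]:
    return [classify_call(c, models, flank) for c in calls]


def consequence_summary(records: list[ConsequenceRecord]) -> dict:
    """Category proportions and the synonymous/nonsynonymous split of CDS
    edits.  Each partition's proportions sum to 1."""
    if not records:
        raise UndefinedStatisticError("no consequence records")
    n = len(records)
    by_cat = {c: 0 for c in CATEGORIES}
    for r in records:
        by_cat[r.category] += 1
    cds = [r for r in records if r.category == "CDS"]
    n_nonsyn = sum(1 for r in cds if not r.synonymous)
    out = {
        "n_records": n,
        "category_proportions": {c: by_cat[c] / n for c in CATEGORIES},
        "coding_fraction": by_cat["CDS"] / n,
    }
    if cds:
        out["nonsynonymous_fraction_of_coding"] = n_nonsyn / len(cds)
        out["synonymous_fraction_of_coding"] = 1.0 - n_nonsyn / len(cds)
    return out


def records_to_frame(records: list[ConsequenceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
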