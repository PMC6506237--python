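# editscope

Quantification of guide-RNA-independent RNA editing and on-/off-target DNA
editing by adenine base editors (ABEs), from amplicon deep sequencing and
transcriptome-wide RNA-seq — together with a synthetic-data generator that
emulates both assay types with known per-adenosine ground truth, so every
stage of the analysis can be validated without external data.

ABEs (TadA–TadA*–Cas9(D10A) fusions) convert A•T to G•C in DNA, but their
deaminase domains also edit cellular RNA at low frequency. Because inosine
is read as guanosine by polymerases and sequencers, A-to-I editing appears
as A→G in cDNA reads (T→C on the genome strand for minus-strand
transcripts). This package implements the analyses used to measure that
activity:

- **Amplicon quantification** — semi-global affine-gap alignment of
  single-end reads to an amplicon; a per-position nucleotide-percentage
  table; the per-adenosine A→G frequency; the number of adenosines with
  frequency strictly above 0.1% ("detectable"); A→G within the protospacer
  editing window (positions 4–8, PAM = 21–23) as DNA editing efficiency;
  and the fraction of reads with an indel overlapping a 30-bp window
  centred on the Cas9(D10A) nick.
- **Transcriptome edit calling** — per-adenosine pileups are scored with a
  two-hypothesis Bayesian model (sequencing/mapping error only vs. genuine
  editing at an unknown fraction *f*, marginalised over a uniform grid).
  The posterior is Phred-scaled, `QUAL = −10·log₁₀(1 − posterior)`, and
  calls with QUAL ≥ 20 (posterior ≥ 0.99) and an A→G transcript-strand
  substitution are retained as high-confidence edits. Utilities cover
  treated-vs-control additional-edit counts, read-weighted average editing
  frequency over adenosines with coverage ≥ 20, 1-Mb bin edit densities,
  and spread (SD) estimation by repeated random down-sampling of whole
  reads.
- **Consequence classification** — each retained edit gets one category
  (CDS, 5′UTR, 3′UTR, noncoding transcript, 5-kb upstream/downstream,
  intergenic; precedence in that order) and CDS edits are classified
  synonymous/nonsynonymous by rebuilding the affected codon in transcript
  orientation.
- **Simulator** — amplicon read sets (depth up to a few 10⁵) and
  mini-transcriptome SAM alignments with per-site truth tables,
  Phred-calibrated miscalls, programmed nick-proximal indels, and strand
  aware A-to-I placement. One integer seed makes every output
  byte-identical.

## Worked example

Simulate a 20,000-read amplicon data set in which every one of 46
adenosines is edited at a true rate of 1.3%, then quantify it:

```sh
$ editscope simulate --kind amplicon --seed 7 --depth 20000 --rate 0.013 --out-dir sim
wrote 20000 reads to sim
$ editscope amplicon-quant --reads sim/reads.fastq --ref sim/amplicon.fa \
      --protospacer-start 103 --out-dir quant
46/46 adenosines above 0.1%; mean 1.3124%
```

The mean per-adenosine A→G frequency (1.3124%) recovers the simulated rate
plus the expected Q30 miscall contribution (~0.033 percentage points:
errors hit each A at rate 10⁻³ and one third of them read as G), and all
46 adenosines clear the 0.1% detectability threshold at this editing
level. `quant/position_table.tsv` holds the per-position A/C/G/T/del/ins
frequency table the statistics are computed from, in the layout of a
nucleotide-percentage summary (rows = bases, columns = reference
positions). The same operations are available as a library:

```python
from editscope import presets, SimConfig
from editscope import (simulate_amplicon_reads, align_reads_to_amplicon,
                       nucleotide_percentage_table, mean_a_to_i_frequency)

spec = presets.amplicon_stand_in("RSL1D1", seed=7)
profile = presets.uniform_amplicon_profile(spec, 0.013)
reads, truth = simulate_amplicon_reads(
    spec, profile, presets.Q30, SimConfig(depth=20_000, seed=7))
table = nucleotide_percentage_table(align_reads_to_amplicon(reads, spec), spec)
print(mean_a_to_i_frequency(table, spec))   # ~0.0133
```

`editscope call-edits`, `editscope consequence` and `editscope report`
drive the transcriptome caller, the consequence classifier, and the full
simulate→quantify→call→classify pipeline; `editscope report` writes a
deterministic bundle (tables, VCF, BED, truth files, `report.json`) for a
given seed.

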