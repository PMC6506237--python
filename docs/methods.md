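# Methods

## Scope and model overview

The package quantifies adenine-base-editor (ABE) activity from two kinds of
sequencing input: targeted amplicon deep sequencing (DNA or cDNA) and
transcriptome-wide RNA-seq alignments. A-to-I deamination is observed as
A→G on the edited strand (T→C on the genome reference strand for
minus-strand transcripts), because polymerases read inosine as guanosine.
All statistics are computed from raw base counts; no background is
subtracted within a condition — treated vs. control comparisons are an
explicit, separate step (`additional_edits`), mirroring how an
endogenous-deaminase control condition is used in practice.

## Amplicon quantification

**Alignment.** Reads are aligned to the amplicon semi-globally (end gaps on
the amplicon are free, so a read may cover only part of it) with affine gap
penalties: a gap of length *g* costs `gap_open + g·gap_extend`. Defaults
(match 5, mismatch −4, gap open 20, extend 2) follow widely used
amplicon-analysis settings. Reads scoring below
`min_score_fraction × read_length × match` (default 0.6) are discarded and
tallied; they enter neither numerator nor denominator of any frequency.

A full-length read with *k* mismatches and no indel is accepted without
running the dynamic program whenever
`k·(match + mismatch_penalty) ≤ match + gap_open + gap_extend`
(*k* ≤ 3 at the defaults). Any alignment containing a gap aligns at most
`L−1` read bases and pays at least one gap opening, so its score is bounded
by `(L−1)·match − gap_open − gap_extend`; under the condition above the
gapless score meets or beats that bound, and ties break toward mismatches
over gaps. The shortcut is therefore exact, not heuristic; a test compares
scores against an independently coded textbook O(nm) affine DP. At typical
error and editing rates ≥95% of reads take the shortcut, which is what
makes depth-2×10⁵ analyses run in seconds.

**Position table.** Per 1-based position: counts of A, C, G, T and
deletion; depth is the column sum (reads covering the position).
Insertions are counted at the position preceding the inserted bases and are
not part of depth. All downstream statistics derive from this table.

**Editing statistics.**
- *Detectable adenosines*: reference-A positions whose G frequency is
  **strictly** greater than the threshold (default 0.001). The strict
  inequality follows the operational spreadsheet formula
  (`COUNTIF(...,">0.001")`) rather than the "≥0.1%" wording that
  accompanies it; at realistic depths the two differ only when a frequency
  lands exactly on the threshold.
- *Mean A-to-I frequency*: unweighted mean of per-adenosine G frequencies
  over **all** sequenced adenosines, zeros included.
- *Protospacer window*: protospacer positions are numbered 1–20 with the
  PAM at 21–23; the editing window defaults to positions 4–8. The DNA
  editing efficiency is the A→G frequency at the target A (an explicit
  `target_position`, the window's unique A, or the most edited window A, in
  that order of preference).
- *Indels*: fraction of aligned reads with ≥1 insertion or deletion
  overlapping a 30-nt window centred on the nick, 1-based positions
  `nick−15 … nick+14`. The Cas9(D10A) nick is placed between protospacer
  positions 17 and 18 (3 bp 5′ of the PAM, the canonical SpCas9 geometry);
  `nick_position` stores the coordinate of protospacer base 17.
  Substitutions never count as indels.

**Error correction.** With per-base miscall rate *e* (uniform over the
three other bases), an A site with true editing rate *r* shows G at
frequency `r·(1−e) + (1−r)·e/3`. `error_corrected_frequency` inverts this
channel, `r = (g − e/3)/(1 − 4e/3)`, using the known or estimated mean
error rate. This matters only for editing rates comparable to `e/3`
(e.g. the ~0.06% control condition at Q30); at percent-level editing the
correction is negligible.

## Transcriptome edit calling

Each adenosine pileup (base calls with base and mapping qualities) is
scored with an explicit two-hypothesis Bayesian model, replacing a
general-purpose variant caller with a model that uses exactly the four
pieces of evidence that matter here: depth, edited-read count, base
quality, and mapping quality.

- H₀ (no editing): each observed base arises from the reference allele
  with miscall probability `e_i = 10^(−Q_i/10)`, distributed `e_i/3` to
  each other base.
- H₁ (editing): an unknown fraction *f* of molecules carry G (transcript
  strand); the per-read likelihood is the *f*-mixture of the edited and
  unedited channels. *f* is marginalised over a uniform grid of 100 points
  on [0.01, 1].
- Mis-mapping: with probability `m_i = 10^(−MQ_i/10)` a read is
  uninformative (likelihood ¼ per base), mixed per read into both
  hypotheses.
- Posterior: Bayes' rule with a site prior of 10⁻³ for genuine editing.
  `QUAL = −10·log₁₀(1 − posterior)`, computed from the posterior log-odds
  via `log1p`/`logaddexp` for stability and capped (default 90). QUAL 20 ↔
  posterior 0.99 exactly; the mapping is self-inverse to 1e−9 wherever
  `1 − posterior` is representable at that accuracy in double precision
  (QUAL ≤ ~60; beyond that the cap and floating-point spacing dominate).

High-confidence edits are calls with QUAL ≥ 20 and substitution A→G on
'+' transcripts or T→C (genome strand) on '−' transcripts. The strictly
genome-plus A→G filter is available via the `allowed` set. No population
database lookup is performed: germline-variant removal is emulated by
control-condition comparison, which is the role of `additional_edits`
(count difference, and transcripts with treated calls but no control
calls). With coverage 100 and Q30, truth sites edited at ≥10% are
recovered with sensitivity ≥ 0.95 and null sites pass at well under the 1%
implied by the 0.99 cutoff (verified over 10⁴ null sites in the tests).

**Average frequency.** Adenosine pileups with coverage < 20 are removed to
avoid low-sampling artefacts; the default estimator is read-weighted
(100 × edited reads / total reads over surviving sites). A site-weighted
alternative — the fraction of surviving adenosines with at least one edited
read — is available behind `weighting="site"`, since "number of adenosines
converted divided by total adenosines" admits both readings; the
read-weighted form is the default because it matches the frequency scale of
the per-site figures.

**Down-sampling.** Whole reads are drawn uniformly without replacement,
deterministically per seed. The spread estimate re-runs the complete
call-and-filter pipeline on `reps` independent down-samples (seeds
`base_seed + i`) and reports the SD across replicates (ddof = 1) — the
spread itself, not SD/√reps.

**Binning.** 1-based position *p* maps to bin `(p−1) // bin_size`
(default 1 Mb); the last bin is truncated at the chromosome end and bin
counts sum to the number of calls.

## Consequence classification

One category per edit with precedence CDS > UTR > noncoding-transcript >
flanking-5kb > intergenic; ties among transcripts break by longest CDS,
then lexicographic id (single-winner attribution keeps category
proportions a partition). Introns are classified noncoding-transcript —
polyadenylated mRNA-seq makes intronic calls rare, and the flank categories
are reserved for positions outside the transcript span. Flanks are
strand-aware (genomic right of a '−' transcript is its upstream side). CDS
edits are re-coded in transcript orientation, the affected codon rebuilt
and translated with the standard nuclear code only; a '−'-strand CDS edit
and its reverse-complemented '+' mirror give identical amino-acid changes
(tested). Protein-impact scoring (SIFT-style) is out of scope.

## Synthetic data generator

The generator emulates the statistical structure of the study's inputs,
not their sequences (the amplicon primers are unpublished, so stand-ins
with matched adenosine counts — 46/59/77 for the RSL1D1/CTNNB1/IP90-like
amplicons — are used; the RSL1D1 stand-in embeds the published
TadA-substrate-homology motif `TCGGCTACGGAA`).

- *Amplicon reads*: single-end, full-length (no paired-end merging),
  matching the 220–260 bp single-end assay design. Per profiled adenosine
  each read is edited independently with probability `true_rate`
  (binomial sampling); errors are then applied per base at `10^(−Q/10)`
  uniformly toward the three other bases. One programmed indel type per
  run (offset from the nick, length, ins/del) is carried by a configurable
  fraction of reads — sufficient to exercise the 30-bp window counter.
- *Qualities*: truncated normal on the Phred scale, rounded and clamped to
  [2, 41] (MiSeq-like); `sd_q = 0` gives the constant-Q study conditions,
  and an error-free model (Q93) disables the channel for calibration
  tests.
- *Mini-transcriptome*: non-overlapping transcripts (1–3 exons, CDS
  divisible by 3, lognormal expression weights) laid out with intergenic
  gaps wide enough that 5-kb flanks and true intergenic space both exist.
  Reads are gapless and exon-contained (splice-junction realism is out of
  scope); per-transcript read counts are Poisson around the configured
  mean coverage scaled by expression weight. Minus-strand edits appear as
  T→C on the genome strand with strand kept in the truth table.
- *Determinism*: one integer seed; fixed chunking makes FASTQ/SAM/truth
  outputs byte-identical across runs.

What the generator does **not** emulate — PCR amplification bias, UMI
structure, quality-score correlation along reads, splice-spanning reads,
mapping ambiguity (simulated MAPQ is constant 60) — bounds what passing
tests show: estimator correctness and calibration under a faithful error
model, not robustness to alignment or library artefacts in real data.

## Study-condition presets and problem sizes

`editscope.presets` pins the generator to the reported means (treated
1.3% / control 0.060% per-adenosine RSL1D1 editing; 27 of 46 detectable;
46.6% DNA on-target; 2.3% indels; 0.22% transcriptome average; 0.068%
across 182 adenosines for the RNA-sparing variant). The detectable-count
profile uses 27 sites with rates spread linearly over 0.3–3% (within the
observed per-adenosine range) and 19 strictly unedited sites; the count
statistic is insensitive to the exact spread at depth 2×10⁵.
`scripts/acceptance.py` runs these scenarios at depth 200,000 (amplicon,
matching the assay-scale depths), 100,000 (DNA on-target), 50,000
(indels), and a ~60-transcript mini-transcriptome at coverage 100 giving
≥5,000 adenosines passing the coverage filter — sizes chosen so each
scenario completes in seconds on one CPU while leaving the binomial
sampling error of each estimate several-fold smaller than the quantity
being recovered. The 120-million-read down-sample of the original analysis
is a parameter of `downsample`, not a default.

## Numerical and design notes

- Coordinates are 0-based half-open internally; 1-based inclusive in all
  outputs (SAM/VCF/GFF3, truth tables) and in protospacer numbering.
- The position table treats depth as reads covering the position, so
  A+C+G+T+del = depth holds at every column by construction.
- Replicate structure: alignments from biological replicates are expected
  to be concatenated before calling (higher coverage, better calls);
  replicate variability is addressed by the down-sampling spread, not by
  per-replicate calling.
- Degenerate inputs raise typed errors rather than returning sentinel
  values: no-NGG references, profile positions off adenosines or outside
  exons, empty read sets, zero-coverage pileups, infeasible down-samples,
  and statistics over empty site sets.
- `filter_edit_calls` reports dropped-call counts by reason, and the
  aligner reports discarded-read counts, so filter effects are auditable
  in pipeline logs.
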