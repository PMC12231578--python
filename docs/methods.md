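# Methods

## The measurement problem

A cytidine base editor recruited to a target site by an sgRNA deaminates
cytidines within a position-dependent window relative to the PAM. For
*diversifying* editors the repair outcome is distributed over C>T, C>A and
C>G, and deamination can also hit the strand annealing to the sgRNA (the
target strand), which the sequencer reads as G>N on the harmonized strand
("CompC>N"). Characterizing an editor means estimating, across many target
sites at once: how often molecules are edited, where, into what, in which
sequence contexts, and how much allelic diversity results.

The package measures these quantities from a paired-library design: each
cassette couples an sgRNA with its own synthetic target site and a 7-nt
degenerate UMI, so that every (pair, UMI) triplet marks one independently
cloned molecule lineage. Pre-existing damage (synthesis or cloning errors) is
separated from editing by sequencing the unedited **Parent** library and
(a) whitelisting triplets whose Parent reads are >90% indel-free,
(b) subtracting Parent allele frequencies from editor-sample frequencies.

## Coordinate conventions

After harmonization (bottom-strand targets reverse-complemented), the PAM
"N" is position 0, the "GG" +1/+2, and the protospacer occupies −20..−1.
All windows, Aggregate Editing profiles and substitution records use this
frame. The choice of 0 at the PAM "N" makes the conventional narrow editing
window land at −18..−13 and the sgRNA region span −20..0.

## Stage-by-stage model and parameter choices

### Library design

* `target_length = 104`, PAM "N" at offset `target_length // 2 = 52`
  ("centred"); protospacer immediately 5′. Flanks and the PAM "N" are i.i.d.
  draws with P(G)=P(C)=`gc_bias`/2, default `gc_bias = 0.52` (human-genome-like).
* Protospacers are random screened 20-mers rather than a published
  non-targeting list: only their sequence composition matters downstream,
  and this keeps the designer self-contained.
* Restriction screening uses the standard recognition sequences Esp3I/BsmBI
  `CGTCTC`, BsaI `GGTCTC`, BlpI `GCTNAGC`, on both strands, IUPAC-aware.
* Negative controls embed a Fisher–Yates shuffle of the protospacer,
  re-drawn until Hamming distance ≥ 10 from the original and verified absent
  from both strands, so the sgRNA cannot bind. Generation is bounded at 1000
  resamples per site before failing loudly.
* Half of the *non-control* sites (floor) are reverse-complemented. The
  whole site is flipped and coordinates recomputed — the design is symmetric
  under this flip, which the mirror-equivalence test exploits.

### Simulator

Editing is applied **once per molecule** (a (pair, UMI) cassette), before
sequencing error — matching the biology of a heritable edit versus a read
artifact. Per edited molecule:

* the number of deamination events k is drawn from `edits_per_allele`
  (default {1: 0.70, 2: 0.25, 3: 0.05});
* each event picks a harmonized-strand C with probability ∝
  `window_weight(pos) × motif_weight(7-mer)`, or — at relative rate
  `comp_ratio` — a target-strand C (a harmonized G); the default motif bias
  is 3× on WRC contexts, the known preference of AID-family deaminases;
* the outcome follows `spectrum` (C>T, C>A, C>G; target-strand events mirror
  to G>A/T/C). Preset spectra use 67:16:18 normalized by its sum (the
  printed percentages round to 101);
* an indel occurs with `indel_rate` at a window-drawn position
  (sizes default {−1: 0.5, −2: 0.2, +1: 0.2, +2: 0.1}).

Sequencing: Poisson read depth per triplet (`depth_per_triplet`), per-base
substitution error `0.001` with an optional linear ramp along the read
(later cycles are noisier on real instruments), Read 1 = UMI + up to 132
target bases, Read 2 = the 20-nt protospacer. Exposure time is collapsed
into the single per-molecule `efficiency` parameter; no kinetic model is
attempted.

Parent and editor samples of a replicate share one UMI map — they sequence
the same integrated library — which is what makes Parent-derived triplet
whitelists applicable to editor samples.

**What the simulator does not emulate:** PCR duplicates and chimeras,
lentiviral recombination (the pairing filter therefore removes ~0% here,
versus a real-data role), quality-score structure, depth skew between
cassettes, and culture-passage drift. Passing recovery tests therefore show
the *analysis* is correct under the stated generative model, not that the
model captures every artifact of real screens.

### Read processing

* sgRNA assignment: unique protospacer within Hamming distance ≤ 1, else
  unassigned (ambiguity is never broken arbitrarily — a misassigned read
  inflates apparent editing).
* Target assignment: Smith–Waterman (match +2, mismatch −3, gap open −5,
  extend −1) over k-mer-seeded candidates; accept if the best score clears
  `1.2 × read length` and is untied. The floor is permissive enough for
  heavily edited alleles (a 104-nt read with 10 substitutions still scores
  158 > 125) and strict enough to reject unrelated sequence.
* Whitelist: triplet acceptable iff indel-free Parent reads / total > 0.90
  (strict) and total ≥ 2 (a single Parent read cannot attest a lineage; this
  floor is a config knob, `min_parent_reads`). Indel presence is decided by
  the same global alignment used for allele calling.
* UMIs are matched exactly; no error-tolerant clustering. This is the
  conservative choice — a sequencing error in the UMI only removes the read
  at the whitelist stage.

### Quantification

* Global alignment: Needleman–Wunsch, match +5, mismatch −4, gap open −8,
  extend −2 (amplicon-quantification convention). With these scores a
  substitution never ties with a gap pair, so co-optimal ambiguity concerns
  gap placement only; the first deterministic traceback is used. A fast path
  handles equal-length sequences within Hamming distance 2, where the
  gap-free alignment is provably optimal (converting two mismatches gains at
  most 18 < 20, the cheapest insertion+deletion pair).
* Edit counting excludes the leftmost 5 reference bases of the sequenced
  strand (amplification-primer artifacts); no right-side exclusion; the full
  remaining amplicon is quantified.
* Targets need ≥ 10 whitelisted reads per sample to be tabulated; alleles
  with a single read are removed and frequencies renormalized (single-read
  alleles are dominated by sequencing error); frequencies are carried in
  percent throughout.
* Allele identity for Parent matching and replicate reconciliation is the
  exact called allele sequence of the target-site region. Matching by
  sequence (not by table-row identity) is required for UMI-independent
  matching across samples.
* Reconciliation: union of alleles per target, missing-in-replicate = 0,
  `mean_norm_freq` = mean over replicates.

### Characterization

* Coverage filter: targets with fewer than 200 reads summed over both
  replicates are removed (boundary 200 retained).
* The 0.5% allele cutoff is applied to `mean_norm_freq` (strictly greater).
  Applying it to the replicate mean rather than per-replicate values is a
  deliberate resolution of an ambiguity; it is the less noisy of the two.
* Aggregate Editing sums substitution-record frequencies per position ÷ 100;
  substitutions on indel-carrying alleles are included (nothing in the
  definition excludes them). The inactive-deaminase cutoff is μ + 2σ with
  **population** σ across assayed positions. Window calls use strict > and
  report only the extreme positions; interior sub-cutoff positions do not
  split a window.
* Efficiency breakdowns: "modified" includes indel-only alleles; C>N uses
  alleles with C-reference substitutions (classes C>N or both), CompC>N the
  G-reference analogue; the −18..−13 in/out split keys on whether the allele
  carries any substitution inside/outside that range.
* Motif ES: the PWM is the allele-frequency-weighted distribution of 7-mer
  contexts (−3..+3) around edited bases; ES = log₂(P_observed/P_background)
  with the background at `gc_bias` split equally within G/C and within A/T
  (WRC ⇒ 0.48 × 0.5 = 0.24). A motif unobservable under the PWM reports −∞
  ("depleted beyond resolution"). G-edit contexts can be
  reverse-complemented so the deaminated base reads as C.
* Entropy includes the reference allele with probability
  (100 − Σ retained non-reference frequencies)/100 — sub-cutoff alleles fold
  into the reference mass so probabilities sum to 1, which the stated
  inclusion of the reference requires but does not spell out.
* Editor-level summaries are medians across targets, lower-median for even
  counts (no interpolation).

## Problem sizes

The test fixtures are `tiny` (5 pairs, 2 UMIs/pair, ~20 reads/triplet;
sub-second) and `small` (50 pairs, 10 UMIs/pair, ~200 reads/triplet,
2 replicates ≈ 4 × 10⁵ read pairs; a few seconds end to end thanks to
per-sequence alignment caching). The `small` fixture is the
parameter-recovery condition: efficiency 0.30, support −18..−13, spectrum
67:16:18, `comp_ratio` 0. The `tiny` fixture scales the 200-read coverage
floor to 40 (half its nominal per-target yield, the same ratio as the
nominal design); all other cutoffs are identical at both scales.

## Known limitations

* The simulator's presets are illustrative editor classes, not fits to any
  dataset; dataset-specific numbers (e.g. published median allele counts or
  μ+2σ values) are not reproduction targets.
* Indel placement is drawn from the editing window rather than from a
  repair-outcome model; indel-size realism is limited to the configured
  distribution.
* The aligner reports one optimal alignment; allele identity is sequence-
  based, so gap-placement ambiguity cannot split an allele, but per-position
  records of indel-adjacent substitutions follow the chosen traceback.
* Pearson comparisons between editor summaries (`metric_correlation`)
  require ≥ 3 editors and finite variance; it is a reporting utility, not an
  inferential test.
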