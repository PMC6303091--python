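# Methods

## Scoring model

A Y2H-seq screen yields per-gene fragment counts from sequencing the pooled
prey-insert amplicons of all colonies surviving selection. Counts are
normalized to FPKM, `1e9 * c_g / (L_g * T)`, where `L_g` is the supplied
per-gene effective length and `T` the screen's total mapped fragments. `T`
is carried in the count-table header and never inferred from the table's
sum, because a counts file may cover only a gene subset. Likewise the
length column is used as supplied; no exon-union recomputation is
attempted, since the package consumes quantifier output, not alignments.

The statistic is the signal-to-noise ratio SNR = FPKM(bait)/FPKM(EMPTY).
The EMPTY screen — the same protocol with an empty bait vector — measures
the background contributed by dead or arrested cells that still carry prey
plasmids, which tracks library representation. Dividing by it cancels
clone-abundance effects, leaving bait-specific enrichment.

Procedure and defaults (`ScoringParams`):

| parameter | default | meaning |
|---|---|---|
| `min_count` | 6 | bait-screen genes with fewer fragments are dropped |
| `impute_value` | 1 | replaces zero EMPTY counts (genes flagged) |
| `percentile_q` | 99.5 | SNR percentile used as the retention threshold |
| `tier_cutoff` | 100 | bait FPKM above this puts a call in the HIGH tier |
| `strict_inequality` | true | retention and tiering use strict `>` |

The gene universe for SNR and the percentile is the set of bait-screen
genes surviving the minimum-count filter; the EMPTY screen is restricted to
that universe and zero-imputed there, never count-filtered. Whether
imputation-flagged genes enter the percentile pool is configurable
(default: they do). Both choices are genuinely open in the procedure as
published; they are exposed as switches rather than silently fixed.

The percentile uses linear interpolation between closest order statistics
(numpy's default); a nearest-rank alternative is provided. No percentile
definition can be validated against the published thresholds (7.2/6.0)
because those require the full genome-wide SNR distributions, which are not
printed; the tests therefore validate the percentile against an explicit
order-statistic oracle and validate retention behaviour on simulated
screens instead.

Ranking ties (equal SNR) break by ascending gene id for determinism.
Tiering never removes a candidate; in particular a high-tier candidate
without any interaction motif must survive calling — motif evidence is
annotation, not a filter (the reference tables contain exactly one such
high-tier candidate, and the caller is required to retain it).

## Reference tables

Four tables transcribed from print ship as fixtures (comma-decimal dialect,
as printed). Typographic marks are encoded as explicit columns: `flagged`
(italic = EMPTY count imputed) and `known` (bold = previously reported
interactor); the TPL-N table's bold "Y" EAR entries (motif in the wrong
frame or a UTR) are encoded as `Y*`. The printed rank numbering has gaps
(both candidate tables skip rank 15; the NINJA table jumps from 60 to 70),
so the declared candidate totals (71 and 51) equal the maximum printed
rank, not the row count (61 and 50); the loaders expose both.

Self-consistency checks (`y2hseq fixtures-verify`): the SNR column must
equal the ratio of the FPKM columns within the propagation of the printed
3–4-decimal rounding (an exact interval bound of half an ULP per input —
for rows with EMPTY FPKM near 0.17 the propagated slack reaches ~0.3%,
which a flat 0.15% tolerance would misjudge); flagged rows must share a
constant FPKM×length product (CV < 0.5%), whose value implies the EMPTY
screen's sequencing total (~1.72e6 fragments) — both bait tables imply the
same total, as they must, since they share one EMPTY control.

## Motif annotation

EAR motifs are matched as the two canonical position patterns `LxLxL` and
`DLNxxP`, the TIFY signature as `TIF[F/Y]xG`. Matching is greedy
left-to-right and non-overlapping within a class, so a degenerate run like
`LDLNLSL` is one hit, not a ladder of shifted copies. `X` in a sequence
never satisfies a fixed position but is accepted by a wildcard. No
profile/HMM scoring is attempted; these motifs are short and effectively
binary in the literature that defines them.

Frame classification of a nucleotide span against the CDS: wholly outside →
UTR; inside with start offset ≡ 0 (mod 3) → in frame; otherwise, including
spans straddling a CDS boundary, out of frame (a straddling span cannot be
translated contiguously with the CDS — a documented convention, not a
biological claim). "Wrong frame / UTR" EAR evidence is found by
translating the three forward frames of the transcript and mapping protein
hits back to nucleotide spans; reverse frames are off by default because
the insert is directional in the prey expression vector.

## Checkpoints

*Titer*: cfu = colonies × dilution × (resuspension volume / plated volume),
checked against the 1e6-colony coverage benchmark for a primary library of
a few million clones.

*Sanger classification*: best reference by shared-k-mer count (k = 21),
then edlib infix alignment for identity over the matched span (cutoff 0.95)
and CDS coverage. `full_length` requires ≥ 90% CDS coverage *and* that the
aligned span includes the CDS start: an insert beginning downstream of the
start codon is a truncated clone regardless of length — the failure mode
that makes a library miss a true interactor whose N-terminal motif the
truncated clone lacks. The cutoffs are config-exposed; no published values
exist for them.

*qPCR*: the single-reference efficiency-corrected ddCq model,
`ratio = E_t^(Cq_t,cal − Cq_t,sample) / E_r^(Cq_r,cal − Cq_r,sample)` on
replicate means, with the unselected cDNA library pool as calibrator and a
vector-borne amplicon as reference. Multi-reference geometric averaging is
deliberately out of scope (one reference amplicon is the stated design).
Significance is a two-sided Welch t-test between per-replicate normalized
log2 quantities; target and reference wells are unpaired, so each target
replicate is normalized against the sample's mean reference Cq. With a
flat reference this reduces exactly to Welch on the raw target Cqs, which
is what the tests pin against an independent textbook implementation.
Welch rather than the pooled-variance variant because technical-replicate
variances of different amplicons need not be equal.

## Simulator

What it emulates: log-normal clone abundances (σ = 1.5, spanning several
orders of magnitude, as in real cDNA libraries), insert lengths normal
around 1,100 nt (floor 100, clipped to the transcript), truncated clones
(start downstream of the CDS start) at probability 0.1, selection as a
multiplicative fold enrichment of clone frequency, the EMPTY pool as an
independent multinomial resample of the unselected library
(`background_carryover` = 1.0 by default; if set below 1 the remainder is
spread uniformly over genes), and 125-bp paired reads drawn from clone
amplicons with fixed synthetic vector flanks attached (the flank sequences
are arbitrary 60-mers standing in for the activation-domain tail and
attR1-flanking vector sequence, labelled as such in the source). Counts
are multinomial given the totals; every stage is reproducible byte-for-byte
from its seed.

What it does not emulate: mating/transformation kinetics, plasmid copy
number, selection stringency (3-AT), PCR amplification bias beyond the
uniform carryover, quality-score decay, spliced genes (transcripts are
contiguous random sequence). Sequencing substitution errors are available
but off by default, since the scoring pipeline operates on post-trimming
counts. Consequently, passing recovery tests shows the *statistical*
procedure behaves as intended under its own model; it does not certify
robustness to mapping artefacts or amplification bias in real data.

Read assignment for synthetic end-to-end runs is a unique-k-mer voter
(k = 21, a standard transcript-discrimination size): k-mers occurring in
more than one transcript are dropped at index time (this also removes the
shared vector flanks), each mate-1 read votes with its remaining k-mers,
ties are discarded. Only mate 1 is used so each fragment is counted once.
This is deliberately simple plumbing, not an aligner.

## Problem sizes and numerical choices

The recovery experiment runs at the screen's stated scale — 12,000 genes,
20 spiked interactors at folds 20–500, 2×10⁶ fragments per screen, 20
seeds — and asserts ≥ 95% sensitivity for fold ≥ 50 spikes with expected
bait count ≥ 20 and ≤ 1% null retention (measured: sensitivity 1.0, null
retention ~0.3%). The read round trip runs at 150 genes / 150,000
fragments; the per-gene Pearson correlation for genes with ≥ 100 reads
saturates at 1.0 far below full scale, so generating millions of 125-bp
pairs would add runtime without information. Gene lengths in these
experiments are log-normal around 1.5 kb (floor 400), a typical plant
transcriptome profile.

Degenerate inputs: an empty read set yields an empty count table (not an
error); a counted gene without an annotation or transcript is an error
naming the gene; percentiles require ≥ 2 values; an EMPTY FPKM of zero in
SNR computation is an error, because it means imputation was skipped.

## Known limitations

- Single screens per bait: no replicate variance model and no
  multiple-testing correction; the percentile threshold is an empirical
  false-call budget, not an error rate.
- The published thresholds (7.2/6.0), trimming totals and qPCR bar heights
  are not recomputable from shipped data; they are treated as constants of
  the printed tables, with the procedure validated by oracle and
  simulation properties instead.
- Cross-bait "sticky prey" blacklisting is provided only as set
  subtraction, not as a statistic.
- The motif scanner is pattern-based; divergent EAR variants beyond the two
  canonical classes will not be found unless added to the pattern table.
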