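# y2hseq

Interactor calling for yeast two-hybrid (Y2H) cDNA library screens read out
by pooled sequencing, plus the computational quality checkpoints that gate
such a screen and a seeded simulator of the whole experiment.

## The problem

In a Y2H library screen, a bait protein fused to a DNA-binding domain is
screened against a cDNA prey library fused to an activation domain; yeast
carrying an interacting pair survive selection. Sequencing the pooled prey
inserts of all surviving colonies replaces one-by-one colony sequencing,
but the raw readout is confounded by library representation: abundant
clones dominate the pool whether or not they interact. Scraping selection
plates also recovers dead or arrested cells with intact prey plasmids, so a
control screen with the *empty* bait vector ("EMPTY") measures exactly that
background.

`y2hseq` scores a bait screen against the EMPTY control. With per-gene
fragment counts `c_g`, gene length `L_g` (bp) and total mapped fragments
`T` per screen:

    FPKM_g = 1e9 * c_g / (L_g * T)
    SNR_g  = FPKM_g(bait) / FPKM_g(EMPTY)

The calling procedure is:

1. drop bait-screen genes with fewer than 6 fragments;
2. replace zero EMPTY counts with 1 (flagging each imputed gene);
3. compute the per-gene SNR;
4. retain genes with SNR strictly above the 99.5th percentile of the SNR
   distribution (an empirical ~0.5% false-call budget);
5. split retained candidates into a high-confidence tier (bait FPKM > 100)
   and the rest, ranked by descending SNR.

Around the caller the package provides: EAR (`LxLxL`, `DLNxxP`) and TIFY
(`TIF[F/Y]xG`) short-linear-motif annotation with reading-frame
classification (a clone can be selected through a motif encoded out of
frame or in a UTR — real selection, spurious biology, so it is labelled,
not hidden); transformation-titer estimation against the 1e6-colony
coverage benchmark; Sanger prey-read classification with truncated-clone
detection; efficiency-corrected ddCq qPCR enrichment ratios with Welch
t-tests; and a generative simulator (log-normal clone abundance, ~1.1 kb
inserts, multiplicative fold enrichment, 125-bp paired reads with vector
flanks) for end-to-end testing with known ground truth.

## Worked example

Score a simulated screen from the shell:

```
y2hseq simulate --n-genes 2000 --n-interactors 10 --total-fragments 200000 \
    --seed 7 --outdir demo
y2hseq score --bait demo/bait_counts.tsv --empty demo/empty_counts.tsv \
    --annotations demo/annotations.tsv --out demo/candidates.tsv
```

which logs

```
INFO y2hseq: screen BAIT: threshold 19.28, 9 candidates retained
```

i.e. the 99.5th percentile of the SNR distribution over the 1,718 genes
surviving the minimum-count filter is 19.3, and 9 genes exceed it. All 9
are true spiked interactors (`demo/truth.tsv`); the missed tenth is a
fold-20 spike — with 10 spikes among 1,718 scored genes the spikes
themselves occupy the top 0.5% and push the percentile threshold up to the
weakest of them, which is the known conservatism of a purely empirical
cutoff. `demo/candidates.tsv` lists the calls ranked by SNR with tier,
imputation flags and (after `y2hseq annotate`) motif columns.

The same machinery in Python:

```python
from y2hseq import ScoringParams, score_screen

table = score_screen(bait_counts, empty_counts, annotations, ScoringParams())
table.threshold          # the 99.5th-percentile SNR cutoff
table.retained[0]        # best candidate: gene, SNR, tier, imputation flag
```

`y2hseq fixtures-verify` recomputes the internal-consistency checks of the
reference candidate tables shipped with the package (SNR column = ratio of
the FPKM columns; imputation-flagged rows all encode one imputed fragment
against a common EMPTY total of ~1.72e6 fragments; retention and tier
counts) and reports PASS/FAIL per check.

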