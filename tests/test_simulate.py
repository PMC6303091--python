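"""The screen simulator: clone library, count sampling, read generation."""

import numpy as np
import pytest
from scipy import stats

from y2hseq.quantify import GeneAnnotation
from y2hseq.simulate import (
    ScreenSimulationParams,
    generate_reads,
    simulate_library,
    simulate_screen,
    simulate_transcriptome,
    spike_interactors,
)


def _long_gene_annotations(n, length=4000):
    return {
        f"SIM{i + 1:05d}": GeneAnnotation(
            f"SIM{i + 1:05d}", length, cds_start=100, cds_end=3700
        )
        for i in range(n)
    }


class TestSimulateLibrary:
    def test_abundances_normalized(self):
        ann = _long_gene_annotations(500)
        clones = simulate_library(ScreenSimulationParams(n_genes=500), ann, seed=1)
        assert sum(c.abundance for c in clones) == pytest.approx(1.0)

    def test_no_truncation_means_every_clone_spans_cds_start(self):
        ann = _long_gene_annotations(200)
        params = ScreenSimulationParams(n_genes=200, truncation_prob=0.0)
        for c in simulate_library(params, ann, seed=2):
            assert c.insert_start <= 100 <= c.insert_end
            assert not c.truncated

    def test_full_truncation_starts_downstream_of_cds_start(self):
        ann = _long_gene_annotations(200)
        params = ScreenSimulationParams(n_genes=200, truncation_prob=1.0)
        clones = simulate_library(params, ann, seed=2)
        assert all(c.truncated and c.insert_start > 100 for c in clones)

    def test_mean_insert_length_near_target(self):
        """Law-of-large-numbers check on the insert-length sampler (transcripts
        long enough that clipping does not bind): mean within 1100 +/- 30 nt."""
        ann = _long_gene_annotations(10_000)
        params = ScreenSimulationParams(n_genes=10_000)
        clones = simulate_library(params, ann, seed=3)
        mean_len = np.mean([c.insert_length for c in clones])
        assert abs(mean_len - 1100) <= 30

    def test_insert_floor(self):
        ann = _long_gene_annotations(100)
        clones = simulate_library(ScreenSimulationParams(n_genes=100), ann, seed=4)
        assert min(c.insert_length for c in clones) >= 100

    def test_deterministic_under_seed(self):
        ann = _long_gene_annotations(100)
        params = ScreenSimulationParams(n_genes=100)
        assert simulate_library(params, ann, seed=9) == simulate_library(params, ann, seed=9)


class TestSimulateScreen:
    def test_null_screen_snr_near_unity(self):
        """With all folds 1, per-gene mean SNR over 20 seeds stays in [0.5, 2]
        for genes with expected count >= 50."""
        ann = _long_gene_annotations(200)
        params = ScreenSimulationParams(
            n_genes=200, total_fragments_bait=100_000, total_fragments_empty=100_000
        )
        clones = simulate_library(params, ann, seed=5)
        abundance = {c.gene_id: c.abundance for c in clones}
        big = [g for g, a in abundance.items() if a * 100_000 >= 50]
        assert big
        snr_sum = {g: 0.0 for g in big}
        for seed in range(20):
            screen = simulate_screen(clones, params, seed=seed)
            for g in big:
                cb = screen.bait_counts.counts[g]
                ce = max(screen.empty_counts.counts[g], 1)
                snr_sum[g] += cb / ce  # equal totals and lengths cancel
        for g in big:
            assert 0.5 <= snr_sum[g] / 20 <= 2.0

    def test_spiked_gene_snr_matches_expectation(self):
        """A fold-100 spike's SNR concentrates at fold/Z (Z = bait-pool
        normalizer), within 3 delta-method standard deviations."""
        ann = _long_gene_annotations(200)
        params0 = ScreenSimulationParams(n_genes=200)
        clones = simulate_library(params0, ann, seed=6)
        # pick a gene with >= 50 expected bait reads at fold 100
        abundance = {c.gene_id: c.abundance for c in clones}
        gene = max(abundance, key=abundance.get)
        fold = 100.0
        params = ScreenSimulationParams(
            n_genes=200, interactor_set={gene: fold},
            total_fragments_bait=100_000, total_fragments_empty=100_000,
        )
        Z = 1 + abundance[gene] * (fold - 1)
        expected_snr = fold / Z
        exp_bait = abundance[gene] * fold / Z * 100_000
        exp_empty = abundance[gene] * 100_000
        assert exp_bait >= 50
        sd = expected_snr * np.sqrt(1 / exp_bait + 1 / exp_empty)
        screen = simulate_screen(clones, params, seed=17)
        snr = screen.bait_counts.counts[gene] / max(screen.empty_counts.counts[gene], 1)
        assert abs(snr - expected_snr) <= 3 * sd

    def test_zero_bait_total_gives_all_zero_counts(self):
        ann = _long_gene_annotations(50)
        params = ScreenSimulationParams(n_genes=50, total_fragments_bait=0)
        clones = simulate_library(params, ann, seed=8)
        screen = simulate_screen(clones, params, seed=8)
        assert all(c == 0 for c in screen.bait_counts.counts.values())

    def test_empty_counts_track_library_abundance(self):
        """Rank correlation of EMPTY counts with clone abundance >= 0.9 at
        1e6 fragments: library-abundant genes surface in the control screen."""
        ann = _long_gene_annotations(1000)
        params = ScreenSimulationParams(
            n_genes=1000, total_fragments_bait=1_000_000,
            total_fragments_empty=1_000_000,
        )
        clones = simulate_library(params, ann, seed=10)
        screen = simulate_screen(clones, params, seed=10)
        abundance = [c.abundance for c in clones]
        counts = [screen.empty_counts.counts[c.gene_id] for c in clones]
        rho = stats.spearmanr(abundance, counts).statistic
        assert rho >= 0.9

    def test_truth_recorded_for_every_gene(self):
        ann = _long_gene_annotations(50)
        params = ScreenSimulationParams(
            n_genes=50, interactor_set={"SIM00001": 10.0}
        )
        clones = simulate_library(params, ann, seed=1)
        screen = simulate_screen(clones, params, seed=1)
        assert set(screen.truth) == set(ann)
        assert screen.truth["SIM00001"] == "interactor"
        assert screen.truth["SIM00002"] == "null"

    def test_unknown_interactor_rejected(self):
        ann = _long_gene_annotations(50)
        params = ScreenSimulationParams(n_genes=50, interactor_set={"NOPE": 10.0})
        clones = simulate_library(
            ScreenSimulationParams(n_genes=50), ann, seed=1
        )
        with pytest.raises(ValueError, match="NOPE"):
            simulate_screen(clones, params, seed=1)


class TestGenerateReads:
    def test_read_lengths_and_zero_counts(self, small_screen):
        screen, clones, annotations, transcripts = small_screen
        counts = screen.bait_counts
        pairs = list(generate_reads(counts, clones, transcripts, seed=1))
        assert len(pairs) == sum(counts.counts.values())
        sampled = pairs[:: max(1, len(pairs) // 200)]
        assert all(len(p.mate1) == 125 and len(p.mate2) == 125 for p in sampled)
        counted_zero = [g for g, c in counts.counts.items() if c == 0]
        produced = {p.name.split(":")[0] for p in pairs}
        assert not (set(counted_zero) & produced)

    def test_missing_transcript_names_gene(self, small_screen):
        screen, clones, annotations, transcripts = small_screen
        partial = dict(list(transcripts.items())[:10])
        with pytest.raises(ValueError, match="SIM"):
            list(generate_reads(screen.bait_counts, clones, partial, seed=1))

    def test_fastq_deterministic_under_seed(self, small_screen):
        screen, clones, annotations, transcripts = small_screen
        a = list(generate_reads(screen.bait_counts, clones, transcripts, seed=5))
        b = list(generate_reads(screen.bait_counts, clones, transcripts, seed=5))
        assert a == b


def test_transcriptome_proteins_consistent_with_cds():
    annotations, transcripts = simulate_transcriptome(20, seed=2)
    for g, ann in annotations.items():
        cds_len = ann.cds_end - ann.cds_start + 1
        assert cds_len % 3 == 0
        assert len(ann.protein) <= cds_len // 3
        assert len(transcripts[g]) == ann.length_bp


def test_spike_interactors_cycles_folds():
    spikes = spike_interactors([f"g{i}" for i in range(100)], 8, folds=(20, 50), seed=1)
    assert len(spikes) == 8
    assert sorted(set(spikes.values())) == [20.0, 50.0]
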