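"""Imputation, filtering, SNR, percentile thresholding and candidate calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from y2hseq.quantify import CountTable, FpkmTable, GeneAnnotation
from y2hseq.scoring import (
    ScoringParams,
    SnrRecord,
    Tier,
    blacklist_subtract,
    call_candidates,
    compute_snr,
    filter_min_count,
    impute_empty,
    percentile_threshold,
    score_screen,
)
from y2hseq.simulate import ScreenSimulationParams, simulate_library, simulate_screen


class TestImputeEmpty:
    def test_zeros_become_one_and_are_flagged(self):
        table = CountTable("EMPTY", {"g1": 0, "g2": 5}, 100)
        imputed, flags = impute_empty(table)
        assert imputed.counts == {"g1": 1, "g2": 5}
        assert flags == {"g1"}

    def test_no_zeros_is_identity(self):
        table = CountTable("EMPTY", {"g1": 2, "g2": 5}, 100)
        imputed, flags = impute_empty(table)
        assert imputed.counts == table.counts and flags == frozenset()

    def test_all_zeros_all_flagged(self):
        table = CountTable("EMPTY", {"a": 0, "b": 0}, 100)
        imputed, flags = impute_empty(table)
        assert set(imputed.counts.values()) == {1} and flags == {"a", "b"}


class TestFilterMinCount:
    def test_less_than_cutoff_is_exclusive(self):
        table = CountTable("B", {"g1": 5, "g2": 6}, 100)
        assert filter_min_count(table, 6).counts == {"g2": 6}

    def test_empty_input(self):
        assert filter_min_count(CountTable("B", {}, 1), 6).counts == {}

    def test_all_at_cutoff_is_identity(self):
        table = CountTable("B", {"a": 6, "b": 6}, 100)
        assert filter_min_count(table, 6).counts == table.counts


class TestComputeSnr:
    @pytest.mark.parametrize(
        "fpkm_bait,fpkm_empty,printed",
        [
            (20257.141, 27.074, 748.213),  # NINJA screen, JAZ1
            (3997.602, 11.301, 353.736),   # TPL-N screen, IAA28
        ],
    )
    def test_reproduces_printed_ratios(self, fpkm_bait, fpkm_empty, printed):
        """Ratio of printed FPKM pairs matches the printed SNR within
        3-decimal input-rounding tolerance."""
        bait = FpkmTable("B", {"g": fpkm_bait})
        empty = FpkmTable("EMPTY", {"g": fpkm_empty})
        (rec,) = compute_snr(bait, empty)
        assert rec.snr == pytest.approx(printed, rel=0.0015)

    def test_identity_ratio(self):
        (rec,) = compute_snr(FpkmTable("B", {"g": 3.5}), FpkmTable("E", {"g": 3.5}))
        assert rec.snr == 1.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="universes differ"):
            compute_snr(FpkmTable("B", {"a": 1.0}), FpkmTable("E", {"b": 1.0}))

    def test_zero_empty_fpkm_signals_missing_imputation(self):
        with pytest.raises(ValueError, match="impute"):
            compute_snr(FpkmTable("B", {"g": 1.0}), FpkmTable("E", {"g": 0.0}))

    def test_imputation_flags_propagate(self):
        recs = compute_snr(
            FpkmTable("B", {"a": 1.0, "b": 1.0}),
            FpkmTable("E", {"a": 0.5, "b": 0.5}),
            flags=frozenset({"a"}),
        )
        assert {r.gene_id: r.imputed for r in recs} == {"a": True, "b": False}


class TestPercentileThreshold:
    def test_median_of_three(self):
        assert percentile_threshold([1, 2, 3], 50) == 2

    def test_constant_values(self):
        assert percentile_threshold([4.2] * 10, 99.5) == 4.2

    def test_matches_sort_and_interpolate_oracle(self):
        """Linear-interpolation percentile equals an explicit order-statistic
        computation on 1,000 uniform draws."""
        rng = np.random.default_rng(123)
        values = rng.uniform(0, 100, size=1000)
        for q in (50.0, 90.0, 99.5):
            s = np.sort(values)
            pos = q / 100 * (len(s) - 1)
            lo, frac = int(np.floor(pos)), pos - np.floor(pos)
            oracle = s[lo] if frac == 0 else s[lo] * (1 - frac) + s[lo + 1] * frac
            assert percentile_threshold(values, q) == pytest.approx(oracle, rel=0, abs=0)

    def test_nearest_rank_method(self):
        values = list(range(1, 101))
        assert percentile_threshold(values, 99.5, method="nearest-rank") == 100
        assert percentile_threshold(values, 50, method="nearest-rank") == 50

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([1.0], 99.5)


def _record(gene, snr, fpkm_bait=None, imputed=False):
    fb = snr if fpkm_bait is None else fpkm_bait
    return SnrRecord(gene, fb, fb / snr, snr, imputed)


class TestCallCandidates:
    def test_snr_exactly_at_threshold_excluded(self):
        table = call_candidates([_record("g", 7.2)], ScoringParams(), threshold=7.2)
        assert table.retained == []

    def test_ranking_descending_snr_then_gene_id(self):
        records = [_record("b", 5.0), _record("a", 5.0), _record("c", 9.0)]
        table = call_candidates(records, ScoringParams(), threshold=1.0)
        assert [c.gene_id for c in table.retained] == ["c", "a", "b"]
        assert [c.rank for c in table.retained] == [1, 2, 3]

    def test_tier_split_on_bait_fpkm(self):
        records = [
            _record("hi", 50.0, fpkm_bait=250.0),
            _record("lo", 40.0, fpkm_bait=100.0),  # cutoff is strict
        ]
        table = call_candidates(records, ScoringParams(), threshold=1.0)
        tiers = {c.gene_id: c.tier for c in table.retained}
        assert tiers == {"hi": Tier.HIGH, "lo": Tier.LOW}

    def test_unretained_records_have_no_rank(self):
        table = call_candidates(
            [_record("a", 10.0), _record("b", 0.5)], ScoringParams(), threshold=1.0
        )
        unretained = [c for c in table.calls if not c.passes_snr]
        assert [c.gene_id for c in unretained] == ["b"]
        assert unretained[0].rank is None

    @given(
        snrs=st.lists(st.floats(0.01, 1e4), min_size=1, max_size=50),
        thr_lo=st.floats(0.1, 100),
        delta=st.floats(0.0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_raising_threshold_never_adds_candidates(self, snrs, thr_lo, delta):
        records = [_record(f"g{i}", s) for i, s in enumerate(snrs)]
        low = {c.gene_id for c in call_candidates(records, ScoringParams(), thr_lo).retained}
        high = {
            c.gene_id
            for c in call_candidates(records, ScoringParams(), thr_lo + delta).retained
        }
        assert high <= low

    def test_raising_tier_cutoff_never_promotes(self):
        records = [_record(f"g{i}", 10.0, fpkm_bait=f) for i, f in enumerate((50, 150, 500))]
        t1 = call_candidates(records, ScoringParams(tier_cutoff=100), 1.0)
        t2 = call_candidates(records, ScoringParams(tier_cutoff=200), 1.0)
        high1 = {c.gene_id for c in t1.tier_members(Tier.HIGH)}
        high2 = {c.gene_id for c in t2.tier_members(Tier.HIGH)}
        assert high2 <= high1


class TestScoreScreen:
    def test_retained_fraction_tracks_percentile_budget(self):
        """On null screens (no interactors) the 99.5th-percentile threshold
        retains ~0.5% of the scored genes, within +/-2 genes."""
        annotations = {
            f"SIM{i + 1:05d}": GeneAnnotation(f"SIM{i + 1:05d}", 800 + 7 * i)
            for i in range(2000)
        }
        params = ScreenSimulationParams(
            n_genes=2000, total_fragments_bait=200_000,
            total_fragments_empty=200_000, seed=0,
        )
        for seed in range(5):
            clones = simulate_library(params, annotations, seed=seed)
            screen = simulate_screen(clones, params, seed=seed + 100)
            table = score_screen(screen.bait_counts, screen.empty_counts, annotations)
            n_scored = len(table.calls)
            assert abs(len(table.retained) - 0.005 * n_scored) <= 2

    def test_genes_absent_from_bait_screen_are_dropped(self):
        annotations = {
            "a": GeneAnnotation("a", 1000),
            "b": GeneAnnotation("b", 1000),
            "c": GeneAnnotation("c", 1000),
        }
        bait = CountTable("B", {"a": 50, "b": 20}, 1000)
        empty = CountTable("EMPTY", {"a": 10, "b": 5, "c": 900}, 1000)
        table = score_screen(bait, empty, annotations, ScoringParams(percentile_q=50))
        assert {c.gene_id for c in table.calls} == {"a", "b"}


def test_blacklist_subtract_preserves_order():
    assert blacklist_subtract(["c", "a", "b"], {"a"}) == ["c", "b"]
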