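"""Interactor calling: imputation, filtering, SNR, percentile threshold, tiers.

The caller compares a bait screen against an empty-vector control screen
("EMPTY").  Because plate scraping carries over dead or arrested cells with
intact prey plasmids, the EMPTY screen reports background abundance for
every prey that is well represented in the cDNA library; dividing the bait
FPKM by the EMPTY FPKM therefore cancels library representation and leaves
bait-specific enrichment — the per-gene signal-to-noise ratio (SNR).

Procedure, in order:

1. drop bait-screen genes with fewer than ``min_count`` fragments (default 6);
2. replace zero EMPTY counts with ``impute_value`` (default 1) so the ratio
   is defined, flagging each imputed gene;
3. FPKM-normalize both screens and take SNR = FPKM_bait / FPKM_empty;
4. call everything whose SNR exceeds the 99.5th percentile of the SNR
   distribution (an empirical false-call budget of ~0.5%);
5. split calls into a high-confidence tier (bait FPKM > 100) and the rest,
   and rank by descending SNR.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .quantify import CountTable, FpkmTable, GeneAnnotation, compute_fpkm

__all__ = [
    "Tier",
    "SnrRecord",
    "CandidateCall",
    "CandidateTable",
    "ScoringParams",
    "impute_empty",
    "filter_min_count",
    "compute_snr",
    "percentile_threshold",
    "call_candidates",
    "score_screen",
    "blacklist_subtract",
]


class Tier(enum.Enum):
    """Confidence tier of a retained candidate (bait FPKM above/below cutoff)."""

    HIGH = "HIGH"
    LOW = "LOW"


@dataclass(frozen=True)
class SnrRecord:
    gene_id: str
    fpkm_bait: float
    fpkm_empty: float
    snr: float
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.fpkm_empty <= 0:
            raise ValueError(
                f"{self.gene_id}: empty-control FPKM must be positive after "
                f"imputation, got {self.fpkm_empty}"
            )


@dataclass(frozen=True)
class CandidateCall:
    record: SnrRecord
    passes_snr: bool
    tier: Tier
    rank: Optional[int] = None  # 1 = highest SNR among retained genes

    @property
    def gene_id(self) -> str:
        return self.record.gene_id


@dataclass
class CandidateTable:
    """Ranked output of one bait-vs-EMPTY comparison."""

    screen_id: str
    threshold: float
    calls: List[CandidateCall] = field(default_factory=list)

    @property
    def retained(self) -> List[CandidateCall]:
        return [c for c in self.calls if c.passes_snr]

    def tier_members(self, tier: Tier) -> List[CandidateCall]:
        return [c for c in self.retained if c.tier is tier]

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class ScoringParams:
    """Tunable constants of the calling procedure (defaults as published)."""

    min_count: int = 6
    impute_value: int = 1
    percentile_q: float = 99.5
    tier_cutoff: float = 100.0
    strict_inequality: bool = True
    #: percentile method; "linear" interpolates between order statistics,
    #: "nearest-rank" takes the ceil(q/100*n)-th order statistic.
    percentile_method: str = "linear"
    #: whether imputation-flagged genes enter the percentile computation
    include_imputed_in_percentile: bool = True

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not (0 < self.percentile_q < 100):
            raise ValueError("percentile_q must lie in (0, 100)")
        if self.tier_cutoff <= 0:
            raise ValueError("tier_cutoff must be positive")
        if self.percentile_method not in ("linear", "nearest-rank"):
            raise ValueError(f"unknown percentile method {self.percentile_method!r}")


def impute_empty(
    counts: CountTable, impute_value: int = 1
) -> Tuple[CountTable, FrozenSet[str]]:
    """Replace zero counts in the negative-control screen by ``impute_value``.

    Returns the imputed table and the set of genes that were zero (the
    imputation flags, propagated through the rest of the pipeline so a
    reader can see which SNRs rest on an arbitrary denominator).
    """
    flags = frozenset(g for g, c in counts.counts.items() if c == 0)
    new = {g: (impute_value if c == 0 else c) for g, c in counts.counts.items()}
    return CountTable(counts.screen_id, new, counts.total_fragments), flags


def filter_min_count(counts: CountTable, min_count: int = 6) -> CountTable:
    """Retain exactly the genes with count >= ``min_count`` (bait screen)."""
    kept = {g: c for g, c in counts.counts.items() if c >= min_count}
    return CountTable(counts.screen_id, kept, counts.total_fragments)


def compute_snr(
    bait: FpkmTable,
    empty: FpkmTable,
    flags: FrozenSet[str] = frozenset(),
) -> List[SnrRecord]:
    """Per-gene SNR = bait FPKM / empty FPKM over a shared gene universe.

    Raises
    ------
    ValueError
        If the gene universes differ, or an empty FPKM is zero (which means
        imputation was skipped).
    """
    if set(bait.fpkm) != set(empty.fpkm):
        missing = set(bait.fpkm) ^ set(empty.fpkm)
        raise ValueError(
            f"bait and empty gene universes differ ({len(missing)} genes, "
            f"e.g. {sorted(missing)[:3]})"
        )
    records = []
    for gene_id in bait.fpkm:
        fe = empty.fpkm[gene_id]
        if fe == 0:
            raise ValueError(
                f"{gene_id}: empty-control FPKM is 0; impute zero counts first"
            )
        fb = bait.fpkm[gene_id]
        records.append(
            SnrRecord(gene_id, fb, fe, fb / fe, imputed=gene_id in flags)
        )
    return records


def percentile_threshold(
    snr_values: Sequence[float], q: float = 99.5, method: str = "linear"
) -> float:
    """q-th percentile of the SNR distribution.

    Default is linear interpolation between closest order statistics;
    ``method="nearest-rank"`` is provided as the common alternative since
    the percentile definition is a genuine degree of freedom of the
    procedure.
    """
    values = np.asarray(snr_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 SNR values for a percentile threshold")
    if not np.all(np.isfinite(values)):
        raise ValueError("SNR values must be finite")
    if method == "linear":
        return float(np.percentile(values, q, method="linear"))
    if method == "nearest-rank":
        idx = max(int(math.ceil(q / 100.0 * values.size)) - 1, 0)
        return float(np.sort(values)[idx])
    raise ValueError(f"unknown percentile method {method!r}")


def call_candidates(
    records: Iterable[SnrRecord],
    params: ScoringParams,
    threshold: float,
    screen_id: str = "",
) -> CandidateTable:
    """Apply the SNR threshold and FPKM tier cutoff, rank retained genes.

    Retention is strict (``snr > threshold``) by default; ties in SNR are
    broken by ascending gene id so output order is deterministic.  Tiering
    never removes a candidate — a retained gene with bait FPKM at or below
    the cutoff simply lands in the LOW tier.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    recs = list(records)
    if params.strict_inequality:
        passing = [r for r in recs if r.snr > threshold]
    else:
        passing = [r for r in recs if r.snr >= threshold]
    passing.sort(key=lambda r: (-r.snr, r.gene_id))
    passing_ids = {r.gene_id for r in passing}
    calls = []
    for rank, r in enumerate(passing, start=1):
        tier = Tier.HIGH if r.fpkm_bait > params.tier_cutoff else Tier.LOW
        calls.append(CandidateCall(r, True, tier, rank))
    for r in sorted(recs, key=lambda r: (-r.snr, r.gene_id)):
        if r.gene_id not in passing_ids:
            tier = Tier.HIGH if r.fpkm_bait > params.tier_cutoff else Tier.LOW
            calls.append(CandidateCall(r, False, tier, None))
    return CandidateTable(screen_id, threshold, calls)


def score_screen(
    bait_counts: CountTable,
    empty_counts: CountTable,
    genes: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    params: ScoringParams = ScoringParams(),
) -> CandidateTable:
    """Full calling pipeline for one bait screen against the EMPTY control.

    The gene universe is the set of bait-screen genes surviving the
    minimum-count filter; the EMPTY screen is restricted to that universe
    (never count-filtered) and zero-imputed there.  The percentile
    threshold is computed on the resulting SNR distribution.
    """
    bait_kept = filter_min_count(bait_counts, params.min_count)
    empty_restricted = empty_counts.restricted_to(bait_kept.counts)
    empty_imputed, flags = impute_empty(empty_restricted, params.impute_value)
    bait_fpkm = compute_fpkm(bait_kept, genes)
    empty_fpkm = compute_fpkm(empty_imputed, genes)
    records = compute_snr(bait_fpkm, empty_fpkm, flags)
    if params.include_imputed_in_percentile:
        pool = [r.snr for r in records]
    else:
        pool = [r.snr for r in records if not r.imputed]
    threshold = percentile_threshold(pool, params.percentile_q, params.percentile_method)
    return call_candidates(records, params, threshold, screen_id=bait_counts.screen_id)


def blacklist_subtract(
    candidates: Iterable[str], blacklist: Iterable[str]
) -> List[str]:
    """Remove library-specific recurring ("sticky") preys from a candidate list.

    Plain set subtraction preserving input order; provided as a convenience
    for cross-bait comparisons, not a statistic.
    """
    bl = set(blacklist)
    return [g for g in candidates if g not in bl]
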