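"""Computational counterparts of the screen's three quality checkpoints.

Before a screen's sequencing output is worth scoring, three cheap checks
gate the wet-lab product:

* **titer** — the transformation titer (colony-forming units) must cover
  the library; at least 1e6 colonies is the usual benchmark for a primary
  cDNA library of a few million clones.
* **Sanger classification** — a handful of surviving colonies are
  Sanger-sequenced; the reads should map to plausible preys, and truncated
  clones (insert starting downstream of the CDS start, possibly missing the
  interaction motif) should be recognized as such.
* **qPCR enrichment** — known interactors should be enriched in the pooled
  screen amplicon relative to the unselected cDNA library, quantified with
  the efficiency-corrected ddCq ratio against a vector-borne reference
  amplicon and tested with a Welch t-test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

import edlib

__all__ = [
    "TiterObservation",
    "estimate_titer",
    "meets_coverage_benchmark",
    "COVERAGE_BENCHMARK_CFU",
    "SangerRead",
    "SangerCall",
    "SangerReference",
    "classify_sanger",
    "summarize_sanger_calls",
    "QpcrMeasurement",
    "qpcr_relative_quantity",
]

#: minimum advised number of screened colonies for full library coverage
COVERAGE_BENCHMARK_CFU: float = 1e6


@dataclass(frozen=True)
class TiterObservation:
    """Colony count on a control plate of a known dilution.

    ``dilution_factor`` is the fold dilution of the plated aliquot (1e3 for
    a 10^-3 plate); volumes are in millilitres.
    """

    colonies: int
    dilution_factor: float
    plated_volume_ml: float
    resuspension_volume_ml: float

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")
        if self.plated_volume_ml <= 0 or self.resuspension_volume_ml <= 0:
            raise ValueError("volumes must be positive")


def estimate_titer(obs: TiterObservation) -> float:
    """Total colony-forming units of the transformation.

    cfu = colonies x dilution x (resuspension volume / plated volume);
    linear in both the colony count and the dilution factor.
    """
    return (
        obs.colonies
        * obs.dilution_factor
        * (obs.resuspension_volume_ml / obs.plated_volume_ml)
    )


def meets_coverage_benchmark(
    cfu_total: float, benchmark: float = COVERAGE_BENCHMARK_CFU
) -> bool:
    return cfu_total >= benchmark


@dataclass(frozen=True)
class SangerRead:
    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.read_id}: empty sequence")


@dataclass(frozen=True)
class SangerReference:
    """Transcript sequence with its CDS span, used as classification target."""

    gene_id: str
    sequence: str
    cds_start: int  # 1-based inclusive
    cds_end: int


@dataclass(frozen=True)
class SangerCall:
    read_id: str
    gene_id: Optional[str]  # None = UNASSIGNED
    identity_fraction: float = 0.0
    covered_cds_fraction: float = 0.0
    full_length: bool = False

    @property
    def assigned(self) -> bool:
        return self.gene_id is not None


def _shared_kmer_counts(
    read: str, references: Sequence[SangerReference], k: int
) -> Counter:
    read_kmers = {read[i : i + k] for i in range(len(read) - k + 1)}
    scores: Counter = Counter()
    for ref in references:
        s = ref.sequence.upper()
        n = sum(1 for i in range(len(s) - k + 1) if s[i : i + k] in read_kmers)
        if n:
            scores[ref.gene_id] = n
    return scores


def classify_sanger(
    read: SangerRead,
    references: Sequence[SangerReference],
    k: int = 21,
    identity_cutoff: float = 0.95,
    full_length_coverage: float = 0.9,
) -> SangerCall:
    """Assign a Sanger read to its best reference and assess clone integrity.

    The best gene is picked by shared-k-mer count, then the read is
    infix-aligned (edlib) to that reference to get identity over the matched
    span and the span's CDS coverage.  ``full_length`` requires both that
    the aligned span covers at least ``full_length_coverage`` of the CDS
    and that it includes the CDS start — an insert beginning downstream of
    the start codon is a truncated clone even if long.
    """
    if not references:
        raise ValueError("references must be non-empty")
    seq = read.sequence.upper()
    scores = _shared_kmer_counts(seq, references, k)
    if not scores:
        return SangerCall(read.read_id, None)
    best_gene = max(scores.items(), key=lambda kv: (kv[1], kv[0]))[0]
    ref = next(r for r in references if r.gene_id == best_gene)
    aln = edlib.align(seq, ref.sequence.upper(), mode="HW", task="locations")
    identity = 1.0 - aln["editDistance"] / len(seq)
    if identity < identity_cutoff:
        return SangerCall(read.read_id, None, identity_fraction=identity)
    loc_start, loc_end = aln["locations"][0]  # 0-based inclusive on reference
    span_start, span_end = loc_start + 1, loc_end + 1
    cds_len = ref.cds_end - ref.cds_start + 1
    overlap = max(
        0, min(span_end, ref.cds_end) - max(span_start, ref.cds_start) + 1
    )
    covered = overlap / cds_len
    full = covered >= full_length_coverage and span_start <= ref.cds_start
    return SangerCall(read.read_id, best_gene, identity, covered, full)


def summarize_sanger_calls(calls: Iterable[SangerCall]) -> Dict[str, int]:
    """Collapse per-read calls into per-gene colony counts."""
    counts: Counter = Counter(
        c.gene_id for c in calls if c.gene_id is not None
    )
    return dict(counts)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cq replicates of one amplicon in one sample.

    ``efficiency`` is the per-cycle amplification factor (2.0 = perfect
    doubling); realistic assays fall in [1.5, 2.2].
    """

    target_id: str
    sample_id: str
    cq_replicates: Tuple[float, ...]
    efficiency: float = 2.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if len(self.cq_replicates) < 2:
            raise ValueError(
                f"{self.target_id}/{self.sample_id}: need >= 2 Cq replicates"
            )
        if self.efficiency <= 1:
            raise ValueError(
                f"{self.target_id}: efficiency must exceed 1, got {self.efficiency}"
            )

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq_replicates))


def _replicate_log2_quantities(
    target: QpcrMeasurement, reference: QpcrMeasurement
) -> np.ndarray:
    """Per-replicate reference-normalized log2 quantity of one sample.

    Target and reference wells are not paired, so each target replicate is
    normalized against the sample's mean reference Cq.
    """
    lt = math.log2(target.efficiency)
    lr = math.log2(reference.efficiency)
    cqs = np.asarray(target.cq_replicates, dtype=float)
    return -lt * cqs + lr * reference.mean_cq


def qpcr_relative_quantity(
    target: QpcrMeasurement,
    reference: QpcrMeasurement,
    calibrator_target: QpcrMeasurement,
    calibrator_reference: QpcrMeasurement,
) -> Tuple[float, float]:
    """Efficiency-corrected relative quantity of a prey versus the library.

    ratio = E_t^(Cq_t,cal - Cq_t,sample) / E_r^(Cq_r,cal - Cq_r,sample)
    on replicate means, where the calibrator is the unselected cDNA library
    pool; ratio > 1 means the prey is enriched in the screen.  The p-value
    is a two-sided Welch t-test between the per-replicate normalized log2
    quantities of sample and calibrator.
    """
    ratio = (
        target.efficiency ** (calibrator_target.mean_cq - target.mean_cq)
        / reference.efficiency ** (calibrator_reference.mean_cq - reference.mean_cq)
    )
    sample_logq = _replicate_log2_quantities(target, reference)
    cal_logq = _replicate_log2_quantities(calibrator_target, calibrator_reference)
    result = stats.ttest_ind(sample_logq, cal_logq, equal_var=False)
    return float(ratio), float(result.pvalue)
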