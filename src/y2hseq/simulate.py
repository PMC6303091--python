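"""Generative model of a Y2H-seq experiment with known ground truth.

The simulator emulates the moving parts the scoring procedure actually
sees: a cDNA prey library with log-normally distributed clone abundances
and ~1.1 kb inserts (some truncated, i.e. starting downstream of the CDS
start), bait-specific selection modeled as a multiplicative fold enrichment
on clone frequency, an empty-vector control pool that is essentially a
resample of the unselected library (dead or arrested cells still carrying
prey plasmids), and optional 125-bp paired-end read generation with vector
flanks attached, so trimming/assignment logic can be exercised end to end.

Everything is driven by an explicit seed: the same seed reproduces the
clone table, the count tables and the FASTQ records byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .quantify import CountTable, GeneAnnotation

__all__ = [
    "LibraryClone",
    "ScreenSimulationParams",
    "SimulatedScreen",
    "ReadPair",
    "simulate_transcriptome",
    "simulate_library",
    "simulate_screen",
    "generate_reads",
    "spike_interactors",
    "VECTOR_FLANK_5P",
    "VECTOR_FLANK_3P",
]

# Synthetic stand-ins for the activation-domain tail and attR1-flanking
# vector sequence amplified along with every insert (not the real vector
# sequence; fixed arbitrary 60-mers so every amplicon shares them).
VECTOR_FLANK_5P = (
    "ACGGTCTAGCAGTCCGATAACTGGCATTACGGATCGTTAGCCTGAACGTCATCGGATCCA"
)
VECTOR_FLANK_3P = (
    "TGACCGGATTCAGCTAACGGTTCAGATCCGGCTTAAGCGTACCGGTTCAACTGATCCGGA"
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class LibraryClone:
    """One prey clone: a (possibly partial) transcript insert at a frequency."""

    gene_id: str
    abundance: float  # relative clone frequency; sums to 1 over the library
    insert_start: int  # 1-based inclusive span on the transcript
    insert_end: int
    truncated: bool  # insert starts downstream of the CDS start
    in_frame: bool

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start + 1


@dataclass(frozen=True)
class ScreenSimulationParams:
    """Study conditions of a simulated screen.

    Defaults follow the experiment being emulated where it states them
    (125-bp paired reads elsewhere; ~1.1 kb mean insert; screen totals of
    order 2e6 mapped fragments) and field-typical values otherwise
    (log-normal clone abundance with sigma 1.5, spanning several orders of
    magnitude as in real cDNA libraries; 10% truncated clones).
    """

    n_genes: int = 12_000
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.5
    interactor_set: Mapping[str, float] = field(default_factory=dict)
    background_carryover: float = 1.0
    total_fragments_bait: int = 2_000_000
    total_fragments_empty: int = 2_000_000
    truncation_prob: float = 0.1
    mean_insert_nt: float = 1100.0
    sd_insert_nt: float = 250.0
    min_insert_nt: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.abundance_lognormal_sigma <= 0:
            raise ValueError("abundance_lognormal_sigma must be positive")
        if not (0 < self.background_carryover <= 1):
            raise ValueError("background_carryover must be in (0, 1]")
        if not (0 <= self.truncation_prob <= 1):
            raise ValueError("truncation_prob must be in [0, 1]")
        for g, fold in self.interactor_set.items():
            if fold <= 1:
                raise ValueError(f"interactor {g}: fold must exceed 1, got {fold}")


@dataclass
class SimulatedScreen:
    """Counts of a bait and an empty screen plus the generating truth."""

    bait_counts: CountTable
    empty_counts: CountTable
    truth: Dict[str, str]  # gene_id -> "interactor" | "null"
    clone_table: List[LibraryClone]
    interactor_folds: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ReadPair:
    name: str
    mate1: str
    mate2: str


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_transcriptome(
    n_genes: int,
    seed: int = 0,
    mean_length_nt: float = 1500.0,
    min_length_nt: int = 400,
) -> Tuple[Dict[str, GeneAnnotation], Dict[str, str]]:
    """Random transcripts with CDS coordinates and translated proteins.

    Lengths are log-normal around ``mean_length_nt``; each transcript gets
    a short 5' UTR, a CDS of a multiple of 3, and a 3' UTR.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    annotations: Dict[str, GeneAnnotation] = {}
    transcripts: Dict[str, str] = {}
    sigma = 0.35
    mu = np.log(mean_length_nt) - sigma**2 / 2
    for i in range(n_genes):
        gene_id = f"SIM{i + 1:05d}"
        length = int(max(min_length_nt, rng.lognormal(mu, sigma)))
        utr5 = int(rng.integers(30, 150))
        utr3 = int(rng.integers(50, 250))
        cds_len = length - utr5 - utr3
        cds_len -= cds_len % 3
        if cds_len < 90:
            cds_len = 90
            length = utr5 + cds_len + utr3
        seq = _random_sequence(rng, length)
        cds_start = utr5 + 1
        cds_end = utr5 + cds_len
        protein = str(Seq(seq[cds_start - 1 : cds_end]).translate()).rstrip("*")
        annotations[gene_id] = GeneAnnotation(
            gene_id, length, cds_start=cds_start, cds_end=cds_end, protein=protein
        )
        transcripts[gene_id] = seq
    return annotations, transcripts


def simulate_library(
    params: ScreenSimulationParams,
    annotations: Mapping[str, GeneAnnotation],
    seed: Optional[int] = None,
) -> List[LibraryClone]:
    """Draw one clone per gene: abundance, insert span, truncation status.

    Abundances are i.i.d. log-normal then normalized to sum to 1.  Insert
    lengths are normal around ``mean_insert_nt`` floored at
    ``min_insert_nt`` and clipped to the transcript.  With probability
    ``truncation_prob`` the insert starts strictly downstream of the CDS
    start (a truncated clone); otherwise it starts in the 5' UTR or at the
    cap, so it spans the CDS start.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    gene_ids = sorted(annotations)[: params.n_genes]
    if len(gene_ids) < params.n_genes:
        raise ValueError(
            f"annotations cover {len(gene_ids)} genes; params ask for {params.n_genes}"
        )
    raw = rng.lognormal(
        params.abundance_lognormal_mu,
        params.abundance_lognormal_sigma,
        size=len(gene_ids),
    )
    abundances = raw / raw.sum()
    clones: List[LibraryClone] = []
    for gene_id, abundance in zip(gene_ids, abundances):
        ann = annotations[gene_id]
        length = int(
            np.clip(
                rng.normal(params.mean_insert_nt, params.sd_insert_nt),
                params.min_insert_nt,
                ann.length_bp,
            )
        )
        cds_start = ann.cds_start if ann.cds_start is not None else 1
        truncated = bool(rng.random() < params.truncation_prob) and cds_start < ann.length_bp
        if truncated:
            hi = max(cds_start + 1, ann.length_bp - params.min_insert_nt + 1)
            start = int(rng.integers(cds_start + 1, hi + 1))
        else:
            # start early enough that the insert covers the CDS start
            low = max(1, cds_start - length + 1)
            start = int(rng.integers(low, cds_start + 1))
        end = min(start + length - 1, ann.length_bp)
        if end - start + 1 < params.min_insert_nt:
            start = max(1, end - params.min_insert_nt + 1)
            truncated = start > cds_start
        in_frame = (start - cds_start) % 3 == 0 if truncated else True
        clones.append(
            LibraryClone(gene_id, float(abundance), start, end, truncated, in_frame)
        )
    return clones


def simulate_screen(
    clones: Sequence[LibraryClone],
    params: ScreenSimulationParams,
    seed: Optional[int] = None,
) -> SimulatedScreen:
    """Draw bait and empty count tables from the clone frequencies.

    Bait counts are multinomial with probabilities proportional to
    abundance x fold (fold 1 for non-interactors); empty counts are an
    independent multinomial over the unselected library, a fraction
    ``1 - background_carryover`` of the pool being spread uniformly over
    genes instead.  Selection is deliberately a multiplicative shift in
    relative frequency, which is all the downstream SNR statistic can see.
    """
    for g in params.interactor_set:
        if g not in {c.gene_id for c in clones}:
            raise ValueError(f"interactor {g!r} is not a library gene")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    gene_ids = [c.gene_id for c in clones]
    abundance = np.array([c.abundance for c in clones], dtype=float)
    folds = np.array(
        [params.interactor_set.get(g, 1.0) for g in gene_ids], dtype=float
    )
    p_bait = abundance * folds
    p_bait /= p_bait.sum()
    carry = params.background_carryover
    p_empty = carry * abundance + (1 - carry) / len(gene_ids)
    p_empty /= p_empty.sum()
    if params.total_fragments_bait > 0:
        bait = rng.multinomial(params.total_fragments_bait, p_bait)
    else:
        bait = np.zeros(len(gene_ids), dtype=int)
    if params.total_fragments_empty > 0:
        empty = rng.multinomial(params.total_fragments_empty, p_empty)
    else:
        empty = np.zeros(len(gene_ids), dtype=int)
    truth = {
        g: ("interactor" if g in params.interactor_set else "null") for g in gene_ids
    }
    return SimulatedScreen(
        bait_counts=CountTable(
            "BAIT", dict(zip(gene_ids, map(int, bait))), params.total_fragments_bait
        ),
        empty_counts=CountTable(
            "EMPTY", dict(zip(gene_ids, map(int, empty))), params.total_fragments_empty
        ),
        truth=truth,
        clone_table=list(clones),
        interactor_folds=dict(params.interactor_set),
    )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_reads(
    counts: CountTable,
    clones: Sequence[LibraryClone],
    transcripts: Mapping[str, str],
    seed: int = 0,
    read_len: int = 125,
    mean_fragment: float = 350.0,
    sd_fragment: float = 60.0,
    vector_flank_5p: str = VECTOR_FLANK_5P,
    vector_flank_3p: str = VECTOR_FLANK_3P,
    error_rate: float = 0.0,
) -> Iterator[ReadPair]:
    """One 125-bp read pair per counted fragment, drawn from the amplicon.

    The amplicon of a clone is 5' vector flank + insert + 3' vector flank.
    Each fragment takes a normal length (floored at ``read_len``, capped at
    the amplicon) at a uniform start; mate 1 is its 5' end, mate 2 the
    reverse complement of its 3' end.  Substitution errors at
    ``error_rate`` are available but off by default.  Genes with count 0
    yield no reads; a counted gene without a transcript is an error.
    """
    rng = np.random.default_rng(seed)
    clone_by_gene = {c.gene_id: c for c in clones}
    for gene_id in sorted(counts.counts):
        c = counts.counts[gene_id]
        if c == 0:
            continue
        if gene_id not in transcripts:
            raise ValueError(f"no transcript for counted gene {gene_id!r}")
        clone = clone_by_gene.get(gene_id)
        if clone is None:
            raise ValueError(f"no library clone for counted gene {gene_id!r}")
        insert = transcripts[gene_id][clone.insert_start - 1 : clone.insert_end]
        amplicon = vector_flank_5p + insert + vector_flank_3p
        n = len(amplicon)
        frag_lens = np.clip(
            rng.normal(mean_fragment, sd_fragment, size=c), read_len, n
        ).astype(int)
        starts = (rng.random(c) * (n - frag_lens + 1)).astype(int)
        for i in range(c):
            s, fl = int(starts[i]), int(frag_lens[i])
            fragment = amplicon[s : s + fl]
            mate1 = fragment[:read_len]
            mate2 = _revcomp(fragment[-read_len:])
            if error_rate > 0:
                mate1 = _mutate(mate1, error_rate, rng)
                mate2 = _mutate(mate2, error_rate, rng)
            yield ReadPair(f"{gene_id}:{i}", mate1, mate2)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
    return arr.tobytes().decode()


def spike_interactors(
    gene_ids: Sequence[str],
    n_interactors: int = 20,
    folds: Sequence[float] = (20.0, 50.0, 100.0, 500.0),
    seed: int = 0,
) -> Dict[str, float]:
    """Pick random genes as true interactors, cycling through ``folds``."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(gene_ids, dtype=object), size=n_interactors, replace=False)
    return {g: float(folds[i % len(folds)]) for i, g in enumerate(chosen)}
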