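"""FPKM quantification of per-gene fragment counts, plus a k-mer read assigner.

A Y2H-seq screen is sequenced as a pool of PCR-amplified prey cDNA inserts.
Upstream tools map the reads and emit one fragment count per gene together
with the total number of mapped fragments; this module normalizes those
counts to FPKM (fragments per kilobase of transcript per million mapped
fragments),

    FPKM_g = 1e9 * c_g / (L_g * T),

where ``c_g`` is the fragment count of gene *g*, ``L_g`` its effective
length in bases and ``T`` the screen's total mapped fragments.

For synthetic end-to-end runs the module also provides
:func:`assign_reads`, a deliberately simple unique-k-mer voting assigner
that plays the role of a spliced aligner on simulated data.  Only mate 1 of
each pair is used, mirroring the convention of counting each fragment once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "GeneAnnotation",
    "CountTable",
    "FpkmTable",
    "compute_fpkm",
    "KmerIndex",
    "assign_reads",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal per-gene annotation.

    Parameters
    ----------
    gene_id
        Locus identifier, e.g. ``AT1G19180``.
    length_bp
        Effective transcript length in bases (the "gene length" used as the
        FPKM denominator); must be >= 1.
    alias
        Optional human-readable gene symbol.
    cds_start, cds_end
        Optional 1-based inclusive CDS coordinates on the transcript.
    protein
        Optional amino-acid sequence (used by motif annotation).
    """

    gene_id: str
    length_bp: int
    alias: Optional[str] = None
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.gene_id}: length_bp must be >= 1, got {self.length_bp}")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.gene_id}: cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (1 <= self.cds_start < self.cds_end <= self.length_bp):
                raise ValueError(
                    f"{self.gene_id}: invalid CDS span "
                    f"[{self.cds_start}, {self.cds_end}] on length {self.length_bp}"
                )


def as_annotation_map(
    genes: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
) -> Dict[str, GeneAnnotation]:
    if isinstance(genes, Mapping):
        return dict(genes)
    return {g.gene_id: g for g in genes}


@dataclass
class CountTable:
    """Per-gene fragment counts of one screen.

    ``total_fragments`` is the screen's total mapped fragment count as
    reported by the mapper.  It is carried explicitly because the counts
    map may cover only a subset of the genome, so it is never inferred
    from ``sum(counts.values())``.
    """

    screen_id: str
    counts: Dict[str, int] = field(default_factory=dict)
    total_fragments: int = 0

    def __post_init__(self) -> None:
        for gene, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {gene}: {c}")
        if self.counts and self.total_fragments < max(self.counts.values()):
            raise ValueError(
                "total_fragments must be at least the largest single gene count"
            )

    def restricted_to(self, genes: Iterable[str]) -> "CountTable":
        """Counts over exactly ``genes``; absent genes get count 0."""
        return CountTable(
            self.screen_id,
            {g: self.counts.get(g, 0) for g in genes},
            self.total_fragments,
        )

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)


@dataclass
class FpkmTable:
    screen_id: str
    fpkm: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, gene_id: str) -> float:
        return self.fpkm[gene_id]

    def __len__(self) -> int:
        return len(self.fpkm)


def fpkm_value(count: int, length_bp: int, total_fragments: int) -> float:
    """Closed-form FPKM for a single gene."""
    return 1e9 * count / (length_bp * total_fragments)


def compute_fpkm(
    counts: CountTable,
    genes: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
) -> FpkmTable:
    """Normalize a count table to FPKM.

    Every counted gene must have an annotation supplying its length; genes
    that are annotated but not counted are absent from the output.

    Raises
    ------
    ValueError
        If ``total_fragments <= 0`` or a counted gene has no annotation.
    """
    if counts.total_fragments <= 0:
        raise ValueError(
            f"screen {counts.screen_id!r}: total_fragments must be positive, "
            f"got {counts.total_fragments}"
        )
    ann = as_annotation_map(genes)
    out: Dict[str, float] = {}
    for gene_id, c in counts.counts.items():
        try:
            length = ann[gene_id].length_bp
        except KeyError:
            raise ValueError(f"no annotation for counted gene {gene_id!r}") from None
        out[gene_id] = fpkm_value(c, length, counts.total_fragments)
    return FpkmTable(counts.screen_id, out)


class KmerIndex:
    """Index of k-mers that occur in exactly one transcript.

    K-mers shared by two or more transcripts are discriminatively useless
    and are dropped at build time, which also removes vector-flank sequence
    common to every amplicon.
    """

    def __init__(self, transcripts: Mapping[str, str], k: int = 21):
        if k < 11:
            raise ValueError(f"k must be >= 11, got {k}")
        if not transcripts:
            raise ValueError("transcripts must be non-empty")
        self.k = k
        owner: Dict[str, Optional[str]] = {}
        for gene_id, seq in transcripts.items():
            s = str(seq).upper()
            seen = set()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if kmer in seen:
                    continue
                seen.add(kmer)
                if kmer in owner and owner[kmer] != gene_id:
                    owner[kmer] = None  # ambiguous
                else:
                    owner[kmer] = gene_id
        self._index: Dict[str, str] = {
            kmer: g for kmer, g in owner.items() if g is not None
        }

    def vote(self, read: str) -> Optional[str]:
        """Gene receiving the most unique-k-mer votes from ``read``.

        Returns ``None`` when no k-mer hits the index or when the top vote
        is tied between two genes (conservative discard).
        """
        k = self.k
        s = read.upper()
        votes: Counter = Counter()
        for i in range(len(s) - k + 1):
            g = self._index.get(s[i : i + k])
            if g is not None:
                votes[g] += 1
        if not votes:
            return None
        best = votes.most_common(2)
        if len(best) == 2 and best[0][1] == best[1][1]:
            return None
        return best[0][0]


def assign_reads(
    reads: Iterable[Tuple[str, str] | str],
    transcripts: Mapping[str, str],
    k: int = 21,
) -> CountTable:
    """Assign read pairs to transcripts by unique-k-mer voting.

    ``reads`` yields either ``(mate1, mate2)`` tuples or bare mate-1
    sequences; mate 2 is ignored so each fragment is counted at most once.
    A read increments exactly one gene (the best vote) or none;
    ``total_fragments`` is the number of assigned reads.
    """
    index = KmerIndex(transcripts, k=k)
    counts: Counter = Counter()
    assigned = 0
    for item in reads:
        mate1 = item[0] if isinstance(item, (tuple, list)) else item
        gene = index.vote(str(mate1))
        if gene is not None:
            counts[gene] += 1
            assigned += 1
    return CountTable("assigned", dict(counts), assigned)
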