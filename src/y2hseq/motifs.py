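"""EAR and TIFY short-linear-motif scanning with reading-frame classification.

Candidate preys of a TPL-type co-repressor bait are expected to carry an
EAR repression motif (LxLxL or DLNxxP), and preys of a NINJA-type adaptor a
TIFY domain signature (TIF[F/Y]xG).  A clone can also be retained because
the *nucleotide* sequence of its insert happens to encode an EAR stretch
out of frame or in an untranslated region — biologically spurious but real
selection, so the annotation distinguishes in-frame protein evidence from
wrong-frame/UTR evidence instead of silently merging them.

Patterns are plain position patterns (no profile/HMM scoring): an upper-case
letter must match exactly, ``x`` matches any residue.  The unknown residue
``X`` in a scanned sequence never satisfies a fixed position but is accepted
by ``x``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .quantify import GeneAnnotation

__all__ = [
    "MotifClass",
    "FrameClass",
    "MotifHit",
    "MOTIF_PATTERNS",
    "scan_protein",
    "classify_frame",
    "translate_frames",
    "scan_transcript",
    "annotate_candidates",
]


class MotifClass(enum.Enum):
    EAR_LxLxL = "EAR_LxLxL"
    EAR_DLNxxP = "EAR_DLNxxP"
    TIFY = "TIFY"


class FrameClass(enum.Enum):
    CDS_IN_FRAME = "CDS_IN_FRAME"
    OUT_OF_FRAME = "OUT_OF_FRAME"
    UTR = "UTR"
    NA = "NA"


#: position patterns: a set means "one of", None means any residue (x)
MOTIF_PATTERNS: Dict[MotifClass, Tuple[Optional[frozenset], ...]] = {
    MotifClass.EAR_LxLxL: (
        frozenset("L"), None, frozenset("L"), None, frozenset("L"),
    ),
    MotifClass.EAR_DLNxxP: (
        frozenset("D"), frozenset("L"), frozenset("N"), None, None, frozenset("P"),
    ),
    MotifClass.TIFY: (
        frozenset("T"), frozenset("I"), frozenset("F"), frozenset("FY"),
        None, frozenset("G"),
    ),
}


@dataclass(frozen=True)
class MotifHit:
    motif_class: MotifClass
    start: int  # 1-based inclusive, in the scanned amino-acid sequence
    end: int
    frame_class: FrameClass = FrameClass.NA

    def __post_init__(self) -> None:
        expected = len(MOTIF_PATTERNS[self.motif_class])
        if self.end - self.start + 1 != expected:
            raise ValueError(
                f"{self.motif_class.value} hit must span {expected} residues"
            )


def scan_protein(
    protein: str,
    motif_class: Optional[MotifClass] = None,
) -> List[MotifHit]:
    """Matches of a motif class (or of all classes) in a protein.

    Matching is greedy left-to-right and non-overlapping within a class:
    after a hit the scan resumes past its end, so a degenerate run like
    ``LDLNLSL`` yields one LxLxL hit, not a ladder of shifted copies.
    Hits come out left to right (and by class order when scanning all
    classes).  An empty sequence yields an empty list.
    """
    classes = [motif_class] if motif_class is not None else list(MotifClass)
    seq = protein.upper()
    hits: List[MotifHit] = []
    for mc in classes:
        pattern = MOTIF_PATTERNS[mc]
        m = len(pattern)
        i = 0
        while i <= len(seq) - m:
            ok = True
            for j, allowed in enumerate(pattern):
                if allowed is not None and seq[i + j] not in allowed:
                    ok = False
                    break
            if ok:
                hits.append(MotifHit(mc, i + 1, i + m))
                i += m
            else:
                i += 1
    return hits


def classify_frame(
    cds_start: int,
    cds_end: int,
    span_start: int,
    span_end: int,
    transcript_length: Optional[int] = None,
) -> FrameClass:
    """Classify a nucleotide span of a transcript relative to its CDS.

    1-based inclusive coordinates throughout.  A span wholly outside the
    CDS is UTR; a span inside is in frame iff its offset from the CDS start
    is a multiple of 3; a span straddling a CDS boundary is, by convention,
    OUT_OF_FRAME (it cannot be translated contiguously with the CDS).
    """
    if span_start < 1 or span_start > span_end:
        raise ValueError(f"invalid span [{span_start}, {span_end}]")
    if transcript_length is not None and span_end > transcript_length:
        raise ValueError(
            f"span [{span_start}, {span_end}] exceeds transcript length "
            f"{transcript_length}"
        )
    if not (1 <= cds_start < cds_end):
        raise ValueError(f"invalid CDS span [{cds_start}, {cds_end}]")
    if span_end < cds_start or span_start > cds_end:
        return FrameClass.UTR
    if span_start >= cds_start and span_end <= cds_end:
        if (span_start - cds_start) % 3 == 0:
            return FrameClass.CDS_IN_FRAME
        return FrameClass.OUT_OF_FRAME
    return FrameClass.OUT_OF_FRAME  # straddles a boundary


def translate_frames(transcript: str) -> Dict[int, str]:
    """Translations of the three forward frames (keys 0, 1, 2 = offset).

    Stop codons translate to ``*`` (which matches no motif position) so
    coordinates stay linear along the frame.
    """
    from Bio.Seq import Seq

    s = transcript.upper().replace("U", "T")
    out = {}
    for f in range(3):
        sub = s[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        out[f] = str(Seq(sub).translate())
    return out


def scan_transcript(
    transcript: str,
    cds_start: int,
    cds_end: int,
    motif_class: Optional[MotifClass] = None,
) -> List[Tuple[int, MotifHit]]:
    """Scan all three forward frames of a transcript for motif-encoding spans.

    Each protein-level hit in frame ``f`` (offset 0–2) is mapped back to its
    nucleotide span and classified against the CDS.  Returns
    ``(frame_offset, hit)`` pairs where the hit's coordinates are protein
    coordinates within that frame's translation and ``frame_class`` is set.
    Reverse-strand frames are not scanned: the insert is directional in the
    prey expression vector.
    """
    results: List[Tuple[int, MotifHit]] = []
    n = len(transcript)
    for frame, protein in translate_frames(transcript).items():
        for hit in scan_protein(protein, motif_class):
            nt_start = frame + 3 * (hit.start - 1) + 1
            nt_end = frame + 3 * hit.end
            fc = classify_frame(cds_start, cds_end, nt_start, nt_end, n)
            results.append(
                (frame, MotifHit(hit.motif_class, hit.start, hit.end, fc))
            )
    return results


def _ear_classes(hits: Iterable[MotifHit]) -> bool:
    return any(
        h.motif_class in (MotifClass.EAR_LxLxL, MotifClass.EAR_DLNxxP) for h in hits
    )


def annotate_candidates(
    candidate_genes: Sequence[str],
    annotations: Mapping[str, GeneAnnotation],
    transcripts: Optional[Mapping[str, str]] = None,
) -> Dict[str, Dict[str, str]]:
    """Fill TIFY/EAR evidence columns for a list of candidate genes.

    For each gene with a protein sequence: ``"Y"`` when the protein itself
    carries the motif.  When transcripts and CDS coordinates are available
    and the protein shows no EAR, three-frame translation evidence is
    reported as ``"Y(out-of-frame/UTR)"`` — the convention for candidates
    retained through a motif in the wrong frame or an untranslated region.
    Genes without sequences get empty columns.

    Returns ``{gene_id: {"tify": ..., "ear": ...}}`` with ``""`` for no
    evidence.
    """
    out: Dict[str, Dict[str, str]] = {}
    for gene_id in candidate_genes:
        cols = {"tify": "", "ear": ""}
        ann = annotations.get(gene_id)
        if ann is not None and ann.protein:
            if scan_protein(ann.protein, MotifClass.TIFY):
                cols["tify"] = "Y"
            if _ear_classes(scan_protein(ann.protein)):
                cols["ear"] = "Y"
        if (
            cols["ear"] == ""
            and transcripts is not None
            and gene_id in transcripts
            and ann is not None
            and ann.cds_start is not None
        ):
            frame_hits = [
                h
                for _, h in scan_transcript(
                    transcripts[gene_id], ann.cds_start, ann.cds_end
                )
                if h.motif_class is not MotifClass.TIFY
            ]
            if any(h.frame_class is FrameClass.CDS_IN_FRAME for h in frame_hits):
                cols["ear"] = "Y"
            elif frame_hits:
                cols["ear"] = "Y(out-of-frame/UTR)"
        out[gene_id] = cols
    return out
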