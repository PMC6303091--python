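"""Readers and writers for every format the pipeline touches.

Interchange conventions: tab-separated text, UTF-8, 1-based inclusive
coordinates, dot-decimal numbers in all *output*.  The shipped reference
tables were transcribed from print and use a comma-decimal dialect
("27,074" means 27.074); :func:`load_paper_fixture` parses them.  Counts
files carry the screen id and the total mapped fragments in a header line
so the FPKM denominator never has to be inferred from a gene subset.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd
import yaml

from .checkpoints import QpcrMeasurement, TiterObservation
from .quantify import CountTable, GeneAnnotation
from .scoring import CandidateTable, Tier
from .simulate import LibraryClone, ReadPair

__all__ = [
    "TableDialect",
    "load_paper_fixture",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_annotations_tsv",
    "write_annotations_tsv",
    "read_annotations_gff3",
    "read_fasta",
    "write_fasta",
    "write_fastq_pairs",
    "read_fastq",
    "write_candidate_table",
    "read_candidate_table",
    "write_clone_table",
    "read_clone_table",
    "write_truth_table",
    "read_qpcr_tsv",
    "read_titer_tsv",
    "read_config",
    "write_config",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class TableDialect:
    """Number/field separators of a tab-separated table."""

    decimal_separator: str = "."  # "." or ","
    field_separator: str = "\t"

    def parse_number(self, token: str) -> float:
        t = token.strip()
        if self.decimal_separator == ",":
            t = t.replace(",", ".")
        return float(t)


DOT_DIALECT = TableDialect(".")
COMMA_DIALECT = TableDialect(",")

_FIXTURE_FILES = {
    "T1": "table1.tsv",
    "T2": "table2.tsv",
    "T3": "table3.tsv",
    "T4": "table4.tsv",
}


def _fixture_path(table_id: str) -> Path:
    try:
        name = _FIXTURE_FILES[table_id]
    except KeyError:
        raise ValueError(
            f"unknown fixture {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}"
        ) from None
    return Path(str(importlib.resources.files("y2hseq") / "fixtures" / name))


def load_paper_fixture(table_id: str) -> pd.DataFrame:
    """Load a shipped reference table (``"T1"``–``"T4"``) as a DataFrame.

    T3/T4 (the candidate tables) come back with dot-decimal floats, boolean
    ``flagged`` (imputed empty count) and ``known`` (previously reported
    interactor) columns, a derived ``tier`` column (HIGH iff bait FPKM >
    100, which reproduces the printed section split), and — for T4 — an
    ``ear_wrong_frame`` boolean for the bold-Y rows whose EAR evidence lies
    out of frame or in a UTR.  T1 yields screen titers, T2 Sanger colony
    counts.  Print typography (bold/italic) is encoded as explicit columns
    because formatting does not survive plain text.
    """
    path = _fixture_path(table_id)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", decimal=",")
    except pd.errors.EmptyDataError:
        raise ValueError(f"fixture {table_id} at {path} is empty or unparseable") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"fixture {table_id} at {path} is malformed: {exc}") from None
    if df.empty:
        raise ValueError(f"fixture {table_id} at {path} contains no rows")
    if table_id in ("T3", "T4"):
        for col in ("alias", "full_length", "tify", "ear"):
            if col in df.columns:
                df[col] = df[col].fillna("")
        df["flagged"] = df["flagged"].astype(bool)
        df["known"] = df["known"].astype(bool)
        df["full_length"] = df["full_length"] == "Y"
        df["tier"] = (df["fpkm_bait"] > 100).map({True: "HIGH", False: "LOW"})
        if "ear" in df.columns:
            df["ear_wrong_frame"] = df["ear"] == "Y*"
        if "tify" in df.columns:
            df["tify"] = df["tify"] == "Y"
    return df


# ---------------------------------------------------------------------------
# counts


def write_counts_tsv(counts: CountTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#screen={counts.screen_id}\ttotal_fragments={counts.total_fragments}\n")
        fh.write("gene_id\tcount\n")
        for gene_id in sorted(counts.counts):
            fh.write(f"{gene_id}\t{counts.counts[gene_id]}\n")


def read_counts_tsv(path: PathLike) -> CountTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    screen_id, total = None, None
    counts: Dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#screen="):
                fields = dict(f.split("=", 1) for f in line.lstrip("#").split("\t"))
                screen_id = fields["screen"]
                total = int(fields["total_fragments"])
                continue
            if line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene_id<TAB>count'")
            counts[parts[0]] = int(parts[1])
    if screen_id is None or total is None:
        raise ValueError(f"{path}: missing '#screen=<id>\\ttotal_fragments=<int>' header")
    return CountTable(screen_id, counts, total)


# ---------------------------------------------------------------------------
# annotations


def write_annotations_tsv(
    genes: Iterable[GeneAnnotation], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlength_bp\talias\tcds_start\tcds_end\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.length_bp}\t{g.alias or ''}\t"
                f"{g.cds_start if g.cds_start is not None else ''}\t"
                f"{g.cds_end if g.cds_end is not None else ''}\n"
            )


def read_annotations_tsv(path: PathLike) -> Dict[str, GeneAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    out: Dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        cds_start = None if pd.isna(getattr(row, "cds_start", float("nan"))) else int(row.cds_start)
        cds_end = None if pd.isna(getattr(row, "cds_end", float("nan"))) else int(row.cds_end)
        alias = getattr(row, "alias", None)
        if isinstance(alias, float) and math.isnan(alias):
            alias = None
        out[row.gene_id] = GeneAnnotation(
            row.gene_id, int(row.length_bp), alias, cds_start, cds_end
        )
    return out


def read_annotations_gff3(path: PathLike, feature_type: str = "gene") -> Dict[str, GeneAnnotation]:
    """Gene annotations from GFF3; length is the feature span end-start+1."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: Dict[str, GeneAnnotation] = {}
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        alias = (feat.attributes.get("Name") or feat.attributes.get("Alias") or [None])[0]
        out[gene_id] = GeneAnnotation(gene_id, feat.end - feat.start + 1, alias)
    return out


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: PathLike) -> Dict[str, str]:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    seqio_write(records, str(path), "fasta")


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path_prefix: PathLike, quality: int = 37
) -> Tuple[Path, Path]:
    """Write read pairs to ``<prefix>_1.fastq`` / ``<prefix>_2.fastq``.

    All bases get the same Phred quality; the simulator models substitution
    errors, not quality decay.
    """
    p1 = Path(f"{path_prefix}_1.fastq")
    p2 = Path(f"{path_prefix}_2.fastq")
    with open(p1, "w", encoding="utf-8") as f1, open(p2, "w", encoding="utf-8") as f2:
        for pair in pairs:
            q1 = chr(quality + 33) * len(pair.mate1)
            q2 = chr(quality + 33) * len(pair.mate2)
            f1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{q1}\n")
            f2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{q2}\n")
    return p1, p2


def read_fastq(path: PathLike) -> List[Tuple[str, str]]:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# candidate tables

_CANDIDATE_COLUMNS = [
    "rank", "gene_id", "length_bp", "fpkm_empty", "fpkm_bait", "snr",
    "alias", "tier", "imputed", "tify", "ear",
]


def write_candidate_table(
    table: CandidateTable,
    path: PathLike,
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
    motif_columns: Optional[Mapping[str, Mapping[str, str]]] = None,
    config: Optional[Mapping[str, object]] = None,
    retained_only: bool = True,
) -> None:
    """Write a ranked candidate table (column order mirrors the print layout).

    SNR and FPKM are printed at 3 decimals with dot decimal marks; full
    precision is an in-memory concern.  The resolved run configuration is
    echoed into ``#`` header lines so every output is self-describing.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#screen={table.screen_id}\n")
        fh.write(f"#snr_threshold={table.threshold:.6g}\n")
        fh.write("#coordinates=1-based inclusive\n")
        for key, value in (config or {}).items():
            fh.write(f"#{key}={value}\n")
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        calls = table.retained if retained_only else table.calls
        for call in calls:
            r = call.record
            ann = (annotations or {}).get(r.gene_id)
            motifs = (motif_columns or {}).get(r.gene_id, {})
            fh.write(
                "\t".join(
                    [
                        str(call.rank) if call.rank is not None else "",
                        r.gene_id,
                        str(ann.length_bp) if ann else "",
                        f"{r.fpkm_empty:.3f}",
                        f"{r.fpkm_bait:.3f}",
                        f"{r.snr:.3f}",
                        (ann.alias or "") if ann else "",
                        call.tier.value,
                        "1" if r.imputed else "0",
                        motifs.get("tify", ""),
                        motifs.get("ear", ""),
                    ]
                )
                + "\n"
            )


def read_candidate_table(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    for col in ("alias", "tify", "ear"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


# ---------------------------------------------------------------------------
# simulation bookkeeping


def write_clone_table(clones: Sequence[LibraryClone], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#coordinates=1-based inclusive\n")
        fh.write("gene_id\tabundance\tinsert_start\tinsert_end\ttruncated\tin_frame\n")
        for c in clones:
            fh.write(
                f"{c.gene_id}\t{c.abundance:.10g}\t{c.insert_start}\t{c.insert_end}\t"
                f"{int(c.truncated)}\t{int(c.in_frame)}\n"
            )


def read_clone_table(path: PathLike) -> List[LibraryClone]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        LibraryClone(
            row.gene_id, float(row.abundance), int(row.insert_start),
            int(row.insert_end), bool(row.truncated), bool(row.in_frame),
        )
        for row in df.itertuples(index=False)
    ]


def write_truth_table(truth: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\ttruth\n")
        for gene_id in sorted(truth):
            fh.write(f"{gene_id}\t{truth[gene_id]}\n")


# ---------------------------------------------------------------------------
# checkpoint inputs


def read_qpcr_tsv(path: PathLike) -> List[QpcrMeasurement]:
    """qPCR input: target_id, sample_id, efficiency, is_reference, cq_replicates.

    ``cq_replicates`` is a comma-separated list of Cq values (dot decimals).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"cq_replicates": str})
    out = []
    for row in df.itertuples(index=False):
        cqs = tuple(float(x) for x in row.cq_replicates.split(","))
        out.append(
            QpcrMeasurement(
                row.target_id, row.sample_id, cqs,
                float(row.efficiency), bool(row.is_reference),
            )
        )
    return out


def read_titer_tsv(path: PathLike) -> List[Tuple[str, TiterObservation]]:
    """Titer bookkeeping: label, colonies, dilution_factor, plated/resuspension volumes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        (
            str(row.label),
            TiterObservation(
                int(row.colonies), float(row.dilution_factor),
                float(row.plated_volume_ml), float(row.resuspension_volume_ml),
            ),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# configuration


def read_config(path: PathLike) -> Dict[str, object]:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_config(config: Mapping[str, object], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
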