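"""Readers and writers for the plain-text formats the toolkit consumes.

All interchange is tab-separated text: annotation tables, BLAST/DIAMOND
outfmt-6 hit tables, prediction score tables, OTU abundance tables,
taxon-to-function maps, per-sample WGS annotation tables and sample
metadata.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .ontology import AnnotationTable

logger = logging.getLogger(__name__)

#: Column indices (protein, term, evidence) for a GAF 2.2 file.
GAF_COLUMNS = (1, 4, 6)


def read_annotation_tsv(
    path: str,
    columns: Sequence[int] = (0, 1, 2),
    comment: str = "!",
    default_evidence: str = "EXP",
) -> AnnotationTable:
    """Read annotations from a TSV ``protein<TAB>go_term<TAB>evidence``.

    ``columns`` gives the (protein, term, evidence) column indices, so a
    GAF 2.2 file is read with ``columns=io.GAF_COLUMNS``. A two-column file
    (no evidence) is accepted; records then get ``default_evidence``.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(comment) or line.startswith("protein\t"):
                continue
            parts = line.split("\t")
            p, t = parts[columns[0]], parts[columns[1]]
            ev = parts[columns[2]] if len(parts) > columns[2] else default_evidence
            rows.append((p, t, ev))
    return AnnotationTable.from_records(rows)


def write_annotation_tsv(table: AnnotationTable, path: str) -> None:
    with open(path, "w") as fh:
        for protein in sorted(table.records):
            for term in sorted(table.records[protein]):
                ev = table.evidence.get((protein, term), "")
                fh.write(f"{protein}\t{term}\t{ev}\n" if ev else f"{protein}\t{term}\n")


#: Standard BLAST/DIAMOND outfmt-6 column names.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_outfmt6(path: str) -> pd.DataFrame:
    """Read a BLAST/DIAMOND tabular (outfmt 6) hit file.

    Returns a DataFrame with at least qseqid, sseqid, evalue, bitscore.
    Files with fewer than 12 columns are accepted if they contain
    (qseqid, sseqid, evalue, bitscore) in the first four columns.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 12:
        df.columns = OUTFMT6_COLUMNS + [f"extra{i}" for i in range(df.shape[1] - 12)]
    elif df.shape[1] == 4:
        df.columns = ["qseqid", "sseqid", "evalue", "bitscore"]
    else:
        raise ValueError(
            f"{path}: expected 12 (outfmt 6) or 4 (qseqid sseqid evalue bitscore) "
            f"columns, got {df.shape[1]}"
        )
    return df[["qseqid", "sseqid", "evalue", "bitscore"]].astype(
        {"evalue": float, "bitscore": float}
    )


def write_outfmt6(hits: pd.DataFrame, path: str) -> None:
    """Write hits (qseqid, sseqid, evalue, bitscore) as 12-column outfmt 6."""
    full = pd.DataFrame(
        {
            "qseqid": hits["qseqid"],
            "sseqid": hits["sseqid"],
            "pident": 90.0,
            "length": 100,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": 100,
            "sstart": 1,
            "send": 100,
            "evalue": hits["evalue"],
            "bitscore": hits["bitscore"],
        }
    )
    full.to_csv(path, sep="\t", header=False, index=False)


def read_otu_table(path: str) -> pd.DataFrame:
    """Read a sample x taxon relative-abundance table (samples as rows)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t")


def read_taxon_function_map(path: str) -> dict[str, set[str]]:
    """Read ``taxon<TAB>go_term`` rows into taxon -> set of terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("taxon\t"):
                continue
            taxon, term = line.split("\t")[:2]
            out.setdefault(taxon, set()).add(term)
    return out


def write_taxon_function_map(mapping: dict[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(mapping):
            for term in sorted(mapping[taxon]):
                fh.write(f"{taxon}\t{term}\n")


def read_wgs_annotations(path: str) -> pd.DataFrame:
    """Read per-sample WGS protein annotations: sample, protein, go_term[, score]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["sample", "protein", "go_term", "score"][: df.shape[1]]
    df.columns = names
    if "score" not in df.columns:
        df["score"] = 1.0
    return df


def read_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata (first column sample ID, remaining phenotypes)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_split_tsv(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("protein\t"):
                continue
            protein, label = line.split("\t")[:2]
            out[protein] = label
    return out


def write_split_tsv(labels: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for protein in sorted(labels):
            fh.write(f"{protein}\t{labels[protein]}\n")


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta_ids(path: str) -> list[str]:
    """Sequence IDs of a FASTA file, in file order (an inventory reader)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                ids.append(line[1:].split()[0].strip())
    return ids
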