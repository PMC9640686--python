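"""Readers and writers for the file dialects the pipeline consumes and emits.

Proteomes are amino-acid multi-FASTA, one file per genome.  The header
convention ``>{genome_id}|{protein_id}`` ties every protein to its source
genome; when the header carries no ``|`` the genome id is taken from the
file name.  Annotation tables are tab-separated with a header line; the
column schemas are documented on each reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputFormatError

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBXZ")


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence tied to a source genome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read one proteome FASTA file.

    Headers are either ``genome|protein`` or bare protein ids; in the
    latter case the genome id defaults to the file stem (or the explicit
    ``genome_id`` argument).  Sequences are upper-cased.  Duplicate
    protein ids and empty sequences are hard errors.
    """
    path = Path(path)
    default_genome = genome_id if genome_id is not None else path.stem
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            gid, pid = header.split("|", 1)
        else:
            gid, pid = default_genome, header
        seq = str(rec.seq).upper()
        if not seq:
            raise InputFormatError(f"empty sequence for protein {pid!r} in {path}")
        if pid in seen:
            raise InputFormatError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(protein_id=pid, genome_id=gid, sequence=seq))
    return records


def read_proteome_dir(directory: str | Path, pattern: str = "*.fasta") -> list[ProteinRecord]:
    """Read every proteome FASTA in a directory, sorted by file name."""
    records: list[ProteinRecord] = []
    ids: set[str] = set()
    for path in sorted(Path(directory).glob(pattern)):
        for rec in read_fasta(path):
            if rec.protein_id in ids:
                raise InputFormatError(
                    f"duplicate protein id {rec.protein_id!r} across proteomes"
                )
            ids.add(rec.protein_id)
            records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as ``>{genome_id}|{protein_id}`` FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.genome_id}|{r.protein_id}", description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


# --------------------------------------------------------------------------
# Annotation table dialects.  All are TSV with a header row.
# --------------------------------------------------------------------------

DOMAIN_COLUMNS = ["protein_id", "accession", "name", "ievalue", "start", "end"]
COG_COLUMNS = ["protein_id", "cog_category", "evalue"]
KO_COLUMNS = ["protein_id", "ko", "score", "threshold", "ievalue"]
CAZY_COLUMNS = ["protein_id", "family"]
BGC_COLUMNS = ["protein_id", "bgc_id", "bgc_type", "core_enzyme"]

_TABLE_COLUMNS: Mapping[str, list[str]] = {
    "domains": DOMAIN_COLUMNS,
    "cog": COG_COLUMNS,
    "ko": KO_COLUMNS,
    "cazy": CAZY_COLUMNS,
    "bgc": BGC_COLUMNS,
}


def read_annotation_tsv(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one annotation table, validating its header against the dialect.

    ``kind`` is one of ``domains``, ``cog``, ``ko``, ``cazy``, ``bgc``.
    """
    if kind not in _TABLE_COLUMNS:
        raise ValueError(f"unknown annotation table kind {kind!r}")
    expected = _TABLE_COLUMNS[kind]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise InputFormatError(f"malformed TSV {path}: {exc}") from exc
    if list(df.columns) != expected:
        raise InputFormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    for col in ("ievalue", "evalue", "score", "threshold"):
        if col in df.columns:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise InputFormatError(
                    f"{path}: non-numeric value in column {col!r}", line=int(bad[0]) + 2
                )
            df[col] = pd.to_numeric(df[col])
    for col in ("start", "end"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    if "core_enzyme" in df.columns:
        df["core_enzyme"] = df["core_enzyme"].map(
            {"1": True, "0": False, "true": True, "false": False, "True": True, "False": False}
        )
        if df["core_enzyme"].isna().any():
            raise InputFormatError(f"{path}: core_enzyme must be 0/1 or true/false")
    return df


def write_annotation_tsv(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    expected = _TABLE_COLUMNS[kind]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected} for kind {kind!r}")
    out = df.copy()
    if "core_enzyme" in out.columns:
        out["core_enzyme"] = out["core_enzyme"].map(lambda v: "1" if v else "0")
    out.to_csv(path, sep="\t", index=False)


def write_truth_tsv(rows: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write planted-truth assignments as ``protein_id genome_id group_id``."""
    with open(path, "w") as fh:
        fh.write("protein_id\tgenome_id\tgroup_id\n")
        for protein_id, genome_id, group_id in rows:
            fh.write(f"{protein_id}\t{genome_id}\t{group_id}\n")


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["protein_id", "genome_id", "group_id"]:
        raise InputFormatError(f"{path}: not a truth table")
    return df


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def iter_tsv_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for each non-empty line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")
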