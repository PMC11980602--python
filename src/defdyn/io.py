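"""Readers and writers for the pipeline's plain-text formats.

Abundance matrices are TSV with samples as rows and entity IDs as the
header; timelines map sample IDs to month indices and ISO dates.  FASTA is
handled through Biopython.  Lines starting with ``#`` (pipeline metadata
headers) are ignored on read.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError


def write_abundance_tsv(matrix: pd.DataFrame, path: str | os.PathLike,
                        header_lines: Iterable[str] = ()) -> None:
    """Write a samples x entities abundance matrix as TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", index_label="sample_id")


def read_abundance_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if df.isna().any().any():
        raise InputError(f"{path}: abundance table contains missing values")
    if (df.values < 0).any():
        raise InputError(f"{path}: abundance table contains negative values")
    return df


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Like :func:`read_abundance_tsv` but allows negative values
    (environmental variables, residual tables)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    if df.isna().any().any():
        raise InputError(f"{path}: table contains missing values")
    return df


def write_timeline_tsv(timeline: pd.DataFrame, path: str | os.PathLike,
                       header_lines: Iterable[str] = ()) -> None:
    """Write a timeline (index sample_id; columns month_index, date)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        timeline.to_csv(fh, sep="\t", index_label="sample_id")


def read_timeline_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    for col in ("month_index", "date"):
        if col not in df.columns:
            raise InputError(f"{path}: timeline is missing column '{col}'")
    return df


def write_table_tsv(df: pd.DataFrame, path: str | os.PathLike,
                    header_lines: Iterable[str] = ()) -> None:
    """Write a plain record table (no meaningful index) as TSV."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
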