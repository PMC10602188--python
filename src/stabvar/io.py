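"""Reading and writing the pipeline's tabular and sequence formats.

Tables are tab-separated with a header row; sequences are standard FASTA
(wrapped at 60 columns) handled through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RAW_COLUMNS = [
    "gene",
    "protein_id",
    "position",
    "wt_aa",
    "mut_aa",
    "clin_sig",
    "allele_freq",
]

ANNOTATED_COLUMNS = RAW_COLUMNS + ["ddg_p1", "ddg_p2", "ddg_p3", "rsa", "label"]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a raw or annotated variant TSV; validates required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA file -> list of (id, sequence) with upper-cased residues."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
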