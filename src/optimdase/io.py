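"""Reading and writing the package's file formats.

Sequences travel as FASTA (labels carried in the record description as
``label=<0|1>``) or as headered CSV with ``sequence,label`` columns;
feature tables as headered CSV/TSV; fitted pipelines as single-file
joblib bundles carrying the model, frozen preprocessing, config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import SequenceEncoder
from .prep import LabelledSequenceSet

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_sequence_csv",
    "encode_table",
    "read_table",
    "save_bundle",
    "load_bundle",
]

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}


def read_sequences(path) -> LabelledSequenceSet:
    """Load labelled sequences from FASTA or a ``sequence,label`` CSV."""
    path = Path(path)
    if path.suffix.lower() in _FASTA_SUFFIXES:
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = 0
            for token in rec.description.split():
                if token.startswith("label="):
                    label = int(token.split("=", 1)[1])
            records.append((str(rec.seq), label))
        return LabelledSequenceSet(records=records)
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise ValueError(f"{path} has no 'sequence' column")
    labels = df["label"] if "label" in df.columns else [0] * len(df)
    return LabelledSequenceSet(records=list(zip(df["sequence"], labels)))


def write_fasta(data: LabelledSequenceSet, path) -> None:
    records = [
        SeqRecord(Seq(seq.bases), id=f"seq_{i:05d}", description=f"label={label}")
        for i, (seq, label) in enumerate(data.records)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sequence_csv(data: LabelledSequenceSet, path) -> None:
    pd.DataFrame({"sequence": data.sequences, "label": data.labels}).to_csv(
        path, index=False
    )


def encode_table(data: LabelledSequenceSet, window: int = 3) -> pd.DataFrame:
    """Combined-encoding feature table with named columns plus ``label``."""
    enc = SequenceEncoder(window=window).fit(data.sequences)
    df = pd.DataFrame(enc.transform(data.sequences), columns=enc.feature_names_)
    df["label"] = data.labels
    return df


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def save_bundle(path, **components) -> None:
    """Persist a fitted pipeline as one joblib file."""
    joblib.dump(components, path)


def load_bundle(path) -> dict:
    return joblib.load(path)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
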