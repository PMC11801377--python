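"""Readers and writers for the package's plain-text formats.

Tables travel as UTF-8 tab-separated text with a single header row;
sequences as FASTA; configurations and ground-truth sidecars as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ValidationError
from .simulate import TRANSITION_COLUMNS

_BOOL = {"True": True, "False": False, "true": True, "false": False, "": False}


def write_transitions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TRANSITION_COLUMNS)


def read_transitions(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "experiment_id": str,
            "sample_id": str,
            "treatment": str,
            "band": str,
            "isotopolog": str,
            "peptide": str,
            "fragment_id": str,
            "replicate_id": str,
            "compound": str,
        },
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing transition columns {missing}")
    df["timepoint_h"] = df["timepoint_h"].astype(float)
    df["intensity"] = df["intensity"].astype(float)
    df["uv_exposed"] = df["uv_exposed"].astype(str).map(_BOOL)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path) -> tuple[str, str]:
    """(id, sequence) of the first record in a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_yaml(obj: Any, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True), encoding="utf-8")


def read_yaml(path) -> Any:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
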