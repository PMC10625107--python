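"""Readers and writers for the pipeline's file formats.

Peptide systems travel as FASTA (one record per system, '+' joining the
components of a mixture) or as CSV with a ``sequence`` column.  Score and
label tables are CSV with '#'-prefixed metadata lines carrying enough
provenance (seed, parameters, normalization constants) to reproduce the
file from its generating config.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scoring import ScoreSet
from .seqspace import PeptideSystem, SequenceError


class ParseError(ValueError):
    """Malformed input file; message lists the offending records."""


def read_peptides(path: str | Path, format: str | None = None) -> list[PeptideSystem]:
    """Read peptide systems from FASTA or CSV (format inferred from suffix).

    A '+' inside a sequence denotes a two-component mixture.  Invalid
    residues are reported with their line number (CSV) or record id
    (FASTA); all offending records are collected before raising.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "csv"
    systems: list[PeptideSystem] = []
    errors: list[str] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            try:
                systems.append(PeptideSystem.parse(str(rec.seq)))
            except SequenceError as e:
                errors.append(f"record {rec.id!r}: {e}")
    elif format == "csv":
        df = pd.read_csv(path, comment="#")
        col = "sequence" if "sequence" in df.columns else df.columns[0]
        for i, raw in enumerate(df[col].astype(str)):
            try:
                systems.append(PeptideSystem.parse(raw))
            except SequenceError as e:
                errors.append(f"line {i + 2}: {e}")
    else:
        raise ValueError(f"unknown format {format!r}")
    if errors:
        raise ParseError(
            f"{len(errors)} malformed record(s) in {path.name}:\n  "
            + "\n  ".join(errors)
        )
    return systems


def write_peptides(
    path: str | Path, systems: Sequence[PeptideSystem], format: str | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".faa") else "csv"
    if format == "fasta":
        records = [
            SeqRecord(Seq(str(s)), id=f"sys{i}", description="")
            for i, s in enumerate(systems)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "csv":
        pd.DataFrame({"sequence": [str(s) for s in systems]}).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def write_scores(
    path: str | Path,
    scores: ScoreSet,
    annotations: dict | None = None,
    value_column: str = "ap",
) -> None:
    """Write a score table with provenance metadata in '#' header lines."""
    path = Path(path)
    meta = dict(scores.meta)
    if scores.norm_constants is not None:
        meta["norm_constants"] = list(scores.norm_constants)
    if annotations:
        meta.update(annotations)
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {json.dumps(meta[key])}\n")
        fh.write(f"sequence,{value_column}\n")
        for k, v in scores.values.items():
            fh.write(f"{k},{v!r}\n")


def read_scores(path: str | Path, value_column: str | None = None) -> ScoreSet:
    """Read a score table written by :func:`write_scores` (metadata kept)."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].strip().partition(":")
            try:
                meta[key.strip()] = json.loads(raw.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = raw.strip()
    df = pd.read_csv(path, comment="#")
    col = value_column or df.columns[1]
    norm = meta.pop("norm_constants", None)
    return ScoreSet(
        values=dict(zip(df[df.columns[0]].astype(str), df[col].astype(float))),
        norm_constants=tuple(norm) if norm else None,
        meta=meta,
    )


def read_sasa_pairs(path: str | Path) -> pd.DataFrame:
    """Read a SASA pair table: sequence, sasa_initial, sasa_final."""
    df = pd.read_csv(path, comment="#")
    required = {"sequence", "sasa_initial", "sasa_final"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"SASA table missing column(s): {sorted(missing)}")
    return df
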