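"""Readers and writers for every external representation the pipeline
touches: FASTA sequences, Vienna dot-bracket text, Mfold CT files, TSV
feature tables, and flat-text logistic model files.

Ingest normalises DNA-style input (T -> U, case-folded to upper) because
public miRNA registries mix conventions.  Two modes are provided: "strict"
fails fast on any malformed record (unit-test precision), "pipeline" skips
it with a logged warning (large-library robustness).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import FEATURE_NAMES, FeatureTable
from .records import HairpinRecord
from .structure import parse_dotbracket

__all__ = [
    "read_fasta",
    "read_vienna",
    "write_vienna",
    "read_ct",
    "write_ct",
    "read_feature_table",
    "write_feature_table",
    "read_labels",
    "write_labels",
]

log = logging.getLogger(__name__)

_VALID = set("ACGU")


def _normalise(raw: str, rec_id: str, mode: str) -> str | None:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        msg = f"record {rec_id!r} contains non-ACGU characters: {sorted(bad)}"
        if mode == "strict":
            raise ValueError(msg)
        log.warning("skipping %s", msg)
        return None
    return seq


def read_fasta(path, mode: str = "strict", label: str = "unlabelled") -> list[HairpinRecord]:
    """Read hairpin sequences from FASTA.

    T is mapped to U and sequences are upper-cased.  In ``strict`` mode a
    record with characters outside {A,C,G,U,T} is an error; in ``pipeline``
    mode it is skipped with a logged warning.
    """
    if mode not in ("strict", "pipeline"):
        raise ValueError(f"unknown mode {mode!r}")
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(entry.seq), entry.id, mode)
        if seq is not None:
            records.append(HairpinRecord(id=entry.id, sequence=seq, label=label))
    if not records and mode == "strict":
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_vienna(path, mode: str = "strict", label: str = "unlabelled") -> list[HairpinRecord]:
    """Read Vienna-style blocks: header, sequence line, structure line with
    an optional trailing ``(energy)``.  Structure length is validated
    against the sequence and brackets must balance."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    records = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected FASTA-style header at line {i + 1}")
        rec_id = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated block for record {rec_id!r}")
        raw_seq, struct_line = lines[i + 1], lines[i + 2]
        i += 3

        mfe: float | None = None
        parts = struct_line.split(None, 1)
        db = parts[0]
        if len(parts) == 2:
            mfe = float(parts[1].strip().strip("()"))
        seq = _normalise(raw_seq, rec_id, mode)
        if seq is None:
            continue
        if len(db) != len(seq):
            raise ValueError(
                f"record {rec_id!r}: structure length {len(db)} != sequence length {len(seq)}"
            )
        parse_dotbracket(db)  # raises on unbalanced brackets
        records.append(HairpinRecord(id=rec_id, sequence=seq, structure=db, mfe=mfe, label=label))
    return records


def write_vienna(records, path) -> None:
    """Write records as Vienna blocks (inverse of :func:`read_vienna`)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.structure is None:
                raise ValueError(f"record {rec.id!r} has no structure")
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.structure}")
            if rec.mfe is not None:
                fh.write(f" ({rec.mfe:.2f})")
            fh.write("\n")


def read_ct(path, label: str = "unlabelled") -> HairpinRecord:
    """Read one Mfold CT file into a record.

    CT format: header line with length and (optionally) ``dG = <energy>``,
    then one line per base: index, base, previous, next, pair index
    (0 = unpaired), original index.  Pairing must be symmetric.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    length = int(header[0])
    mfe: float | None = None
    for tok_prev, tok in zip(header, header[1:]):
        if tok_prev.lower() in ("dg", "=", "energy") or tok_prev == "=":
            try:
                mfe = float(tok)
                break
            except ValueError:
                continue
    if mfe is None:
        for tok in header[1:]:
            try:
                val = float(tok)
            except ValueError:
                continue
            if not val.is_integer() or val < 0:
                mfe = val
                break

    body = lines[1 : 1 + length]
    if len(body) != length:
        raise ValueError(f"{path}: header declares {length} bases, found {len(body)}")
    seq_chars, pair_idx = [], []
    for ln in body:
        f = ln.split()
        seq_chars.append(f[1].upper().replace("T", "U"))
        pair_idx.append(int(f[4]))
    for i, j in enumerate(pair_idx, start=1):
        if j != 0 and (j < 1 or j > length or pair_idx[j - 1] != i):
            raise ValueError(f"{path}: inconsistent pairing {i} -> {j}")
    db = []
    for i, j in enumerate(pair_idx, start=1):
        db.append("." if j == 0 else ("(" if j > i else ")"))
    rec_id = Path(path).stem
    return HairpinRecord(
        id=rec_id, sequence="".join(seq_chars), structure="".join(db), mfe=mfe, label=label
    )


def write_ct(record: HairpinRecord, path) -> None:
    """Write a record as a CT file (inverse of :func:`read_ct`)."""
    if record.structure is None:
        raise ValueError(f"record {record.id!r} has no structure")
    pt = parse_dotbracket(record.structure)
    L = pt.length
    with open(path, "w") as fh:
        energy = f"  dG = {record.mfe:.2f}" if record.mfe is not None else ""
        fh.write(f"{L}{energy}  {record.id}\n")
        for i in range(L):
            partner = pt.partner(i)
            j = 0 if partner is None else partner + 1
            fh.write(f"{i + 1} {record.sequence[i]} {i} {i + 2 if i + 1 < L else 0} {j} {i + 1}\n")


# ---------------------------------------------------------------------------
# Feature tables (TSV) and label files

_NA = "NA"


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV: ``id``, ``label``, then the 132
    canonical feature columns; missing values as ``NA``.  The round trip
    through :func:`read_feature_table` is lossless to 12 significant
    digits."""
    df = table.values.copy()
    df.insert(0, "label", table.labels)
    df.index.name = "id"
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.12g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=[_NA], keep_default_na=False)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    labels = df.pop("label").astype(str)
    missing = [n for n in FEATURE_NAMES if n not in df.columns]
    extra = [c for c in df.columns if c not in FEATURE_NAMES]
    if missing or extra:
        raise ValueError(
            f"{path}: feature columns do not match the 132-name catalog; "
            f"missing={missing} unknown={extra}"
        )
    return FeatureTable(values=df[list(FEATURE_NAMES)].astype(float), labels=labels)


def write_labels(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.label}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["id"], df["label"]))
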