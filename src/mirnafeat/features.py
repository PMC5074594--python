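"""The 132-feature numerical descriptor of a pre-miRNA hairpin.

Eight feature classes:

=====  ====  ========================================================
class  size  content
=====  ====  ========================================================
A         4  mononucleotide frequencies (A%, C%, G%, U%)
B        16  overlapping dinucleotide frequencies
C        64  overlapping trinucleotide frequencies
D        32  triplet matching-state frequencies (base x pairing marks
             of left neighbour / self / right neighbour, '+' paired,
             '.' unpaired, e.g. "G++.")
E         5  n_bulge, n_helix, n_interior, n_stack, length
F         3  MFE, AMFE (= 100*MFE/length), MFEI (= AMFE / (100*GC))
G         4  GC fraction, (G+C)/(A+U), A/C, G/U
H         4  Shannon entropies (bits) of classes A-D: IESN, IEDN,
             IETN, IESS
=====  ====  ========================================================

All frequencies are fractions in [0, 1]; each of classes A-D sums to 1.
Ratio features with a zero denominator, and MFEI at zero GC, are missing
(NaN) rather than sentinel numbers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import HairpinRecord
from .structure import PairTable, StructuralElements, decompose, fold, parse_dotbracket

__all__ = [
    "BASES",
    "MARK_PATTERNS",
    "FEATURE_NAMES",
    "FEATURE_CLASS",
    "FeatureTable",
    "catalog",
    "seq_composition",
    "triplet_state_features",
    "structural_counts",
    "energy_features",
    "ratio_features",
    "entropy",
    "extract_all",
    "extract_table",
]

log = logging.getLogger(__name__)

BASES = "ACGU"
#: pairing-mark patterns for (left neighbour, self, right neighbour);
#: ordered unpaired-first so "A..." precedes "A..+" etc.
MARK_PATTERNS = ("...", "..+", ".+.", ".++", "+..", "+.+", "++.", "+++")

_MONO = [f"{b}%" for b in BASES]
_DI = [f"{a}{b}%" for a, b in itertools.product(BASES, repeat=2)]
_TRI = ["".join(t) + "%" for t in itertools.product(BASES, repeat=3)]
_TRIPLET = [f"{b}{m}%" for b in BASES for m in MARK_PATTERNS]
_STRUCT = ["n_bulge", "n_helix", "n_interior", "n_stack", "length"]
_ENERGY = ["MFE", "AMFE", "MFEI"]
_RATIO = ["gc_content", "gc_over_au", "a_over_c", "g_over_u"]
_ENTROPY = ["IESN", "IEDN", "IETN", "IESS"]

#: canonical ordering of the 132 features
FEATURE_NAMES: tuple[str, ...] = tuple(
    _MONO + _DI + _TRI + _TRIPLET + _STRUCT + _ENERGY + _RATIO + _ENTROPY
)

FEATURE_CLASS: dict[str, str] = {}
for _names, _cls in [
    (_MONO, "A"), (_DI, "B"), (_TRI, "C"), (_TRIPLET, "D"),
    (_STRUCT, "E"), (_ENERGY, "F"), (_RATIO, "G"), (_ENTROPY, "H"),
]:
    for _n in _names:
        FEATURE_CLASS[_n] = _cls

_DESCRIPTION = {
    "E": "structural element count / sequence length",
    "F": "free-energy feature (kcal/mol based)",
    "G": "base-composition ratio",
    "H": "Shannon entropy of a frequency class (bits)",
}


def catalog() -> pd.DataFrame:
    """Machine-readable feature catalog: name, class, index, description."""
    rows = []
    for i, name in enumerate(FEATURE_NAMES):
        cls = FEATURE_CLASS[name]
        if cls == "A":
            desc = f"frequency of {name[:-1]}"
        elif cls == "B":
            desc = f"overlapping dinucleotide frequency of {name[:-1]}"
        elif cls == "C":
            desc = f"overlapping trinucleotide frequency of {name[:-1]}"
        elif cls == "D":
            desc = f"triplet matching-state frequency of {name[:-1]}"
        else:
            desc = _DESCRIPTION[cls]
        rows.append({"name": name, "class": cls, "index": i, "description": desc})
    return pd.DataFrame(rows)


@dataclass
class FeatureTable:
    """Feature matrix for a cohort: rows are hairpin ids, columns the 132
    canonical features, plus a per-row class label."""

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(FEATURE_NAMES):
            missing = set(FEATURE_NAMES) - set(self.values.columns)
            extra = set(self.values.columns) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature table must have the 132 canonical columns; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate ids: {dup}")
        self.labels = self.labels.reindex(self.values.index)

    @property
    def n(self) -> int:
        return len(self.values)

    def class_labels(self) -> list[str]:
        return sorted(self.labels.dropna().unique())


def _validate_seq(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return seq


def seq_composition(sequence: str) -> dict[str, float]:
    """Classes A-C: mono-, di- and trinucleotide frequencies.

    k-mers are counted in overlapping windows and normalised by L-k+1.
    Class B requires L >= 2 and class C requires L >= 3; below that the
    affected class is missing (NaN).
    """
    seq = _validate_seq(sequence)
    L = len(seq)
    out: dict[str, float] = {}
    for k, names in ((1, _MONO), (2, _DI), (3, _TRI)):
        if L < k:
            out.update({n: np.nan for n in names})
            continue
        counts: dict[str, int] = {}
        for i in range(L - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        denom = L - k + 1
        out.update({n: counts.get(n[:-1], 0) / denom for n in names})
    return out


def triplet_state_features(sequence: str, pt: PairTable) -> dict[str, float]:
    """Class D: frequencies of the 32 (base, pairing-triplet) states.

    Every position contributes one state combining its base with the
    paired/unpaired marks of its left neighbour, itself, and its right
    neighbour; terminal positions take a virtual unpaired neighbour, so
    the 32 frequencies always sum to 1.
    """
    seq = _validate_seq(sequence)
    L = len(seq)
    if pt.length != L:
        raise ValueError(f"structure length {pt.length} != sequence length {L}")
    counts = {name: 0 for name in _TRIPLET}
    for i in range(L):
        left = pt.is_paired(i - 1) if i > 0 else False
        right = pt.is_paired(i + 1) if i < L - 1 else False
        marks = ("+" if left else ".") + ("+" if pt.is_paired(i) else ".") + (
            "+" if right else "."
        )
        counts[f"{seq[i]}{marks}%"] += 1
    return {name: c / L for name, c in counts.items()}


def structural_counts(elements: StructuralElements, sequence: str) -> dict[str, float]:
    """Class E: bulge-loop, helix, interior-loop and stack counts + length."""
    return {
        "n_bulge": float(elements.n_bulge),
        "n_helix": float(elements.n_helix),
        "n_interior": float(elements.n_interior),
        "n_stack": float(elements.n_stack),
        "length": float(len(sequence)),
    }


def energy_features(mfe: float | None, length: int, gc_fraction: float) -> dict[str, float]:
    """Class F: MFE, AMFE = 100*MFE/length, MFEI = AMFE / (100*GC).

    AMFE normalises the folding energy per 100 nt; MFEI further divides by
    the GC percentage, giving the ~-1 magnitudes typical of true hairpins.
    With mfe absent the whole class is missing; at zero GC only MFEI is.
    """
    if mfe is None:
        log.warning("record without MFE: class F features set to missing")
        return {"MFE": np.nan, "AMFE": np.nan, "MFEI": np.nan}
    amfe = 100.0 * mfe / length
    mfei = amfe / (100.0 * gc_fraction) if gc_fraction > 0 else np.nan
    return {"MFE": float(mfe), "AMFE": amfe, "MFEI": mfei}


def ratio_features(sequence: str) -> dict[str, float]:
    """Class G: GC fraction, (G+C)/(A+U), A/C and G/U ratios.

    A zero denominator makes the corresponding ratio missing (NaN).
    """
    seq = _validate_seq(sequence)
    L = len(seq)
    a, c, g, u = (seq.count(b) for b in BASES)
    return {
        "gc_content": (g + c) / L,
        "gc_over_au": (g + c) / (a + u) if (a + u) > 0 else np.nan,
        "a_over_c": a / c if c > 0 else np.nan,
        "g_over_u": g / u if u > 0 else np.nan,
    }


def entropy(freqs) -> float:
    """Shannon information entropy -sum(p * log2 p) in bits.

    Zero frequencies contribute nothing (0*log 0 := 0).  The frequencies
    must be non-negative and sum to 1 within 1e-9.
    """
    p = np.asarray(list(freqs), dtype=float)
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()!r}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def extract_all(record: HairpinRecord, engine=None) -> dict[str, float]:
    """Full 132-value feature vector of one hairpin, in canonical order.

    The record needs a structure (or a folding engine); class F needs an
    energy, which a folding engine also supplies.
    """
    seq = _validate_seq(record.sequence)
    structure, mfe = record.structure, record.mfe
    if structure is None:
        structure, folded_mfe = fold(seq, engine=engine)
        if mfe is None:
            mfe = folded_mfe
    pt = parse_dotbracket(structure)
    if pt.length != len(seq):
        raise ValueError(
            f"record {record.id}: structure length {pt.length} != sequence length {len(seq)}"
        )
    elements = decompose(pt)

    fv: dict[str, float] = {}
    fv.update(seq_composition(seq))
    fv.update(triplet_state_features(seq, pt))
    fv.update(structural_counts(elements, seq))
    ratios = ratio_features(seq)
    fv.update(energy_features(mfe, len(seq), ratios["gc_content"]))
    fv.update(ratios)
    fv["IESN"] = entropy(fv[n] for n in _MONO)
    fv["IEDN"] = entropy(fv[n] for n in _DI) if len(seq) >= 2 else np.nan
    fv["IETN"] = entropy(fv[n] for n in _TRI) if len(seq) >= 3 else np.nan
    fv["IESS"] = entropy(fv[n] for n in _TRIPLET)
    return {name: fv[name] for name in FEATURE_NAMES}


def extract_table(records, engine=None) -> FeatureTable:
    """Extract features for a cohort of records into a :class:`FeatureTable`."""
    rows, ids, labels = [], [], []
    for rec in records:
        rows.append(extract_all(rec, engine=engine))
        ids.append(rec.id)
        labels.append(rec.label)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=list(FEATURE_NAMES))
    return FeatureTable(values=values, labels=pd.Series(labels, index=values.index, name="label"))
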