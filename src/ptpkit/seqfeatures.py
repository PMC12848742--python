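"""Sequence descriptors used in thermophile-vs-mesophile comparisons.

Implements the classic suite of thermostability-relevant descriptors for a
protein sequence: amino-acid composition, hydrophobic residue fraction on
the Kyte-Doolittle scale, GRAVY (grand average of hydropathy), the Ikai
aliphatic index and the Guruprasad instability index. Non-standard residue
characters are hard errors, never silently skipped.

Constant tables and provenance
------------------------------
* Kyte & Doolittle, J. Mol. Biol. 157 (1982) 105-132 (hydropathy values).
* Ikai, J. Biochem. 88 (1980) 1895-1898 (aliphatic index coefficients
  a = 2.9 for Val, b = 3.9 for Ile/Leu).
* Guruprasad, Reddy & Pandit, Protein Eng. 4 (1990) 155-161 (dipeptide
  instability weights, see :mod:`ptpkit._diwv`; values < 40 indicate a
  stable protein).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._diwv import DIWV
from .exceptions import ParameterError

#: Kyte-Doolittle hydropathy, one value per standard residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_RESIDUES = frozenset(KYTE_DOOLITTLE)

#: Residues with strictly positive Kyte-Doolittle hydropathy.
HYDROPHOBIC_RESIDUES = frozenset(
    r for r, h in KYTE_DOOLITTLE.items() if h > 0
)  # {A, C, F, I, L, M, V}

_ALIPHATIC_VAL = 2.9
_ALIPHATIC_ILE_LEU = 3.9

INSTABILITY_STABLE_BELOW = 40.0


def _check_sequence(seq: str, min_length: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_length:
        raise ParameterError(f"sequence shorter than {min_length}")
    bad = [(i, c) for i, c in enumerate(seq) if c not in STANDARD_RESIDUES]
    if bad:
        shown = ", ".join(f"{c!r}@{i}" for i, c in bad[:10])
        raise ParameterError(f"non-standard residue(s): {shown}")
    return seq


def composition(seq: str) -> dict[str, float]:
    """Mole fraction of each of the 20 standard residues."""
    seq = _check_sequence(seq)
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in sorted(STANDARD_RESIDUES)}


def hydrophobic_fraction(seq: str, threshold: float = 0.0) -> float:
    """% of residues with Kyte-Doolittle hydropathy strictly above
    ``threshold`` (default 0, i.e. the positive-hydropathy set
    A/C/F/I/L/M/V)."""
    seq = _check_sequence(seq)
    count = sum(1 for c in seq if KYTE_DOOLITTLE[c] > threshold)
    return 100.0 * count / len(seq)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _check_sequence(seq)
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index: 100*(X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu))."""
    comp = composition(seq)
    return 100.0 * (
        comp["A"]
        + _ALIPHATIC_VAL * comp["V"]
        + _ALIPHATIC_ILE_LEU * (comp["I"] + comp["L"])
    )


def instability_index(seq: str) -> tuple[float, str]:
    """Guruprasad instability index and its stability label.

    II = (10/L) * sum over consecutive dipeptides of DIWV[x][y];
    values < 40 are labelled "stable", otherwise "unstable".
    """
    seq = _check_sequence(seq, min_length=2)
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    value = 10.0 / len(seq) * total
    label = "stable" if value < INSTABILITY_STABLE_BELOW else "unstable"
    return value, label


@dataclass
class FeatureRecord:
    """All descriptors for one sequence."""

    sequence_id: str
    composition: dict
    hydrophobic_fraction: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    stability_label: str
    length: int


def featurize(sequence_id: str, seq: str) -> FeatureRecord:
    ii, label = instability_index(seq)
    return FeatureRecord(
        sequence_id=sequence_id,
        composition=composition(seq),
        hydrophobic_fraction=hydrophobic_fraction(seq),
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        instability_index=ii,
        stability_label=label,
        length=len(seq),
    )


def feature_table(records) -> pd.DataFrame:
    """FeatureRecord table for (id, sequence) pairs; gap characters are
    stripped first (descriptors are sequence, not alignment, properties)."""
    rows = []
    for name, seq in records:
        rec = featurize(name, seq.replace("-", ""))
        row = {
            "sequence_id": rec.sequence_id,
            "length": rec.length,
            "hydrophobic_fraction_pct": rec.hydrophobic_fraction,
            "gravy": rec.gravy,
            "aliphatic_index": rec.aliphatic_index,
            "instability_index": rec.instability_index,
            "stability_label": rec.stability_label,
        }
        row.update({f"frac_{aa}": f for aa, f in rec.composition.items()})
        rows.append(row)
    return pd.DataFrame(rows)
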