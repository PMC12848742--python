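"""Chimeric sequence design by per-column random residue selection.

The design rule: at an alignment column conserved by a single residue,
that residue is selected; at a column holding several residues, one is
drawn uniformly over the *distinct* states (unweighted by occurrence).
An occurrence-weighted mode is provided for sensitivity comparisons, and
gap handling is a policy parameter (a gap may be selectable as a state,
or excluded before drawing).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, UndefinedResultError

GAP = "-"


@dataclass(frozen=True)
class ColumnProfile:
    """Distinct residue states and their occurrence counts at one column."""

    column_index: int
    states: frozenset
    counts: dict

    def __post_init__(self):
        if not self.states:
            raise ParameterError(f"column {self.column_index} has no states")


@dataclass(frozen=True)
class ChimeraResult:
    """A sampled chimera: gap-stripped sequence plus per-column choices."""

    sequence: str
    per_column_choice: tuple
    seed: int


def build_profiles(alignment: Sequence[tuple[str, str]]) -> list[ColumnProfile]:
    """Per-column state sets/counts of an equal-length alignment."""
    if not alignment:
        raise ParameterError("empty alignment")
    seqs = [seq.upper() for _, seq in alignment]
    if len(seqs) < 2:
        raise ParameterError("need at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ParameterError(f"unequal sequence lengths {sorted(lengths)}")
    profiles = []
    for col in range(lengths.pop()):
        column = [s[col] for s in seqs]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        profiles.append(ColumnProfile(col, frozenset(counts), counts))
    return profiles


def sample_chimera(profiles: Sequence[ColumnProfile], seed: int,
                   gap_policy: str = "selectable",
                   weighting: str = "distinct") -> ChimeraResult:
    """Draw one chimera from column profiles.

    ``weighting='distinct'`` (default) draws uniformly over distinct states;
    ``'occurrence'`` weights states by their occurrence counts. Under
    ``gap_policy='excluded'`` gaps are removed from state sets before
    drawing (an all-gap column then emits a gap). The returned sequence has
    gaps stripped; ``per_column_choice`` keeps them.
    """
    if not profiles:
        raise ParameterError("no column profiles")
    if gap_policy not in ("selectable", "excluded"):
        raise ParameterError(f"unknown gap_policy {gap_policy!r}")
    if weighting not in ("distinct", "occurrence"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    choices = []
    for profile in profiles:
        states = sorted(profile.states)
        if gap_policy == "excluded":
            states = [s for s in states if s != GAP] or [GAP]
        if len(states) == 1:
            choices.append(states[0])
            continue
        if weighting == "distinct":
            pick = states[rng.integers(len(states))]
        else:
            weights = np.array([profile.counts[s] for s in states], dtype=float)
            pick = states[rng.choice(len(states), p=weights / weights.sum())]
        choices.append(pick)
    sequence = "".join(c for c in choices if c != GAP)
    return ChimeraResult(sequence, tuple(choices), seed)


class SubstitutionCount(NamedTuple):
    """Differing non-gap positions, with gap-involving positions reported
    separately."""

    substitutions: int
    gapped_positions: int

    def __int__(self) -> int:
        return self.substitutions


def hamming_substitutions(seq_a: str, seq_b: str) -> SubstitutionCount:
    """Count positions with differing non-gap characters on a fixed alignment."""
    if len(seq_a) != len(seq_b):
        raise ParameterError(
            f"sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    subs = gapped = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == GAP or b == GAP:
            gapped += a != b
        elif a != b:
            subs += 1
    return SubstitutionCount(subs, gapped)


def percent_identity(seq_a: str, seq_b: str) -> float:
    """100 x matches / positions where both sequences are non-gap.

    Computed on the given alignment as-is; no re-alignment is performed.
    """
    if len(seq_a) != len(seq_b):
        raise ParameterError(
            f"sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    matches = comparable = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == GAP or b == GAP:
            continue
        comparable += 1
        matches += a == b
    if comparable == 0:
        raise UndefinedResultError("no position where both sequences are non-gap")
    return 100.0 * matches / comparable


def identity_report(chimera: ChimeraResult,
                    alignment: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Per-progenitor identity and substitution counts for one chimera,
    computed on the alignment coordinates (per-column choices)."""
    aligned = "".join(chimera.per_column_choice)
    rows = []
    for name, seq in alignment:
        ham = hamming_substitutions(aligned, seq)
        rows.append({
            "progenitor": name,
            "percent_identity": percent_identity(aligned, seq),
            "substitutions": ham.substitutions,
            "gapped_positions": ham.gapped_positions,
        })
    return pd.DataFrame(rows)
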