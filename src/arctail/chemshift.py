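"""Secondary chemical shifts (ΔCα), helix/strand/coil segmentation, and
disordered-tail boundary detection.

ΔCα(i) = observed Cα shift of residue i minus the random-coil Cα shift of
the same residue type.  Sustained positive runs mark α-helix, sustained
negative runs β-strand, and small/discrete values random coil.  For a
protein whose final segment is coil, the start of that terminal coil run is
the disordered-tail boundary (D357 in rat Arc).

Classification rules
--------------------
* residue i is helix if ΔCα(i) > ``pos_thresh``, strand if
  ΔCα(i) < ``neg_thresh``, else coil;
* unobserved residues (prolines, unassigned) inherit the state of their
  flanking classified neighbours when those agree, else coil — data gaps
  never break an otherwise continuous segment;
* "continuous" is enforced as a minimum run length: helix/strand runs
  shorter than ``min_run`` are relabelled coil;
* adjacent same-state runs are merged into segments.

The default thresholds are ±0.05 ppm.  That band is small compared with
the ±0.5–0.7 ppm cutoffs common for Cα secondary shifts, so both readings
are worth reporting; the thresholds are plain parameters here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ChemicalShiftTable

__all__ = [
    "RandomCoilReference",
    "WISHART_RANDOM_COIL_CA",
    "DeltaCaProfile",
    "Segment",
    "Segmentation",
    "TailStart",
    "delta_ca",
    "segment_secondary_structure",
    "detect_tail_start",
]

#: random-coil Cα chemical shifts (ppm), Wishart-style peptide reference set
_WISHART_CA = {
    "A": 52.5, "C": 58.2, "D": 54.2, "E": 56.6, "F": 57.7,
    "G": 45.1, "H": 55.0, "I": 61.1, "K": 56.2, "L": 55.1,
    "M": 55.4, "N": 53.1, "P": 63.3, "Q": 55.7, "R": 56.0,
    "S": 58.3, "T": 61.8, "V": 62.2, "W": 57.5, "Y": 57.9,
}


@dataclass(frozen=True)
class RandomCoilReference:
    """Residue-type -> random-coil Cα shift (ppm), with provenance label."""

    values: dict[str, float]
    provenance: str

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"reference lacks residues: {sorted(missing)}")
        for aa, ppm in self.values.items():
            if not 40.0 <= ppm <= 70.0:
                raise ValueError(f"implausible Cα random-coil shift {ppm} ppm for {aa}")

    def __getitem__(self, residue_type: str) -> float:
        try:
            return self.values[residue_type]
        except KeyError:
            raise KeyError(
                f"residue type {residue_type!r} absent from random-coil reference "
                f"({self.provenance})"
            ) from None


WISHART_RANDOM_COIL_CA = RandomCoilReference(_WISHART_CA, "Wishart random-coil Cα set")


@dataclass
class DeltaCaProfile:
    """Per-residue ΔCα values (ppm); residues without an observed Cα are absent."""

    construct_id: str
    span: tuple[int, int]  # construct range, full-length numbering
    values: dict[int, float]
    residue_types: dict[int, str]

    def __post_init__(self) -> None:
        for r, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite ΔCα at residue {r}")

    def residues(self) -> list[int]:
        return sorted(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, self.residue_types.get(r, "X"), self.values[r]) for r in self.residues()]
        return pd.DataFrame(rows, columns=["residue", "residue_type", "delta_ca"])


def delta_ca(
    shift_table: ChemicalShiftTable,
    reference: RandomCoilReference = WISHART_RANDOM_COIL_CA,
) -> DeltaCaProfile:
    """ΔCα(i) = observed Cα(i) − random-coil reference for the residue type."""
    ca = shift_table.atoms("CA")
    if not ca:
        raise ValueError(f"{shift_table.construct_id}: no CA entries in shift table")
    types = shift_table.residue_types()
    values = {r: shift - reference[types[r]] for r, shift in ca.items()}
    return DeltaCaProfile(shift_table.construct_id, shift_table.residue_span, values, types)


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    state: str  # 'helix' | 'strand' | 'coil'

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Segmentation:
    segments: list[Segment]
    pos_thresh: float
    neg_thresh: float
    min_run: int

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ValueError("segments overlap or are unsorted")
            if b.state == a.state and b.start == a.end + 1:
                raise ValueError("adjacent segments share a state (unmerged)")

    def count(self, state: str) -> int:
        return sum(1 for s in self.segments if s.state == state)

    def state_at(self, residue: int) -> str | None:
        for s in self.segments:
            if s.start <= residue <= s.end:
                return s.state
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.start, s.end, s.length, s.state) for s in self.segments],
            columns=["start", "end", "length", "state"],
        )


def segment_secondary_structure(
    profile: DeltaCaProfile,
    pos_thresh: float = 0.05,
    neg_thresh: float = -0.05,
    min_run: int = 4,
) -> Segmentation:
    """Classify residues from ΔCα and merge them into secondary-structure
    segments (see module docstring for the exact rules)."""
    if not (pos_thresh >= 0.0 >= neg_thresh):
        raise ValueError(
            f"thresholds must satisfy pos >= 0 >= neg, got ({pos_thresh}, {neg_thresh})"
        )
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    lo, hi = profile.span
    observed = profile.values

    # 1. raw per-residue classification
    state: dict[int, str | None] = {}
    for r in range(lo, hi + 1):
        if r in observed:
            v = observed[r]
            state[r] = "helix" if v > pos_thresh else "strand" if v < neg_thresh else "coil"
        else:
            state[r] = None

    # 2. missing residues inherit agreeing flanking states, else coil
    filled: dict[int, str] = {}
    obs_positions = sorted(observed)
    for r in range(lo, hi + 1):
        if state[r] is not None:
            filled[r] = state[r]
            continue
        left = next((state[q] for q in range(r - 1, lo - 1, -1) if state[q] is not None), None)
        right = next((state[q] for q in range(r + 1, hi + 1) if state[q] is not None), None)
        filled[r] = left if (left is not None and left == right) else "coil"
    del obs_positions

    # 3. helix/strand runs shorter than min_run become coil
    runs = _runs(filled, lo, hi)
    relabelled: dict[int, str] = {}
    for start, end, st in runs:
        keep = st == "coil" or (end - start + 1) >= min_run
        for r in range(start, end + 1):
            relabelled[r] = st if keep else "coil"

    # 4. merge into segments
    segments = [Segment(s, e, st) for s, e, st in _runs(relabelled, lo, hi)]
    return Segmentation(segments, pos_thresh, neg_thresh, min_run)


def _runs(states: dict[int, str], lo: int, hi: int) -> list[tuple[int, int, str]]:
    runs: list[tuple[int, int, str]] = []
    start = lo
    for r in range(lo + 1, hi + 1):
        if states[r] != states[start]:
            runs.append((start, r - 1, states[start]))
            start = r
    runs.append((start, hi, states[start]))
    return runs


@dataclass(frozen=True)
class TailStart:
    """Location of the disordered C-terminal tail, if the construct ends in coil."""

    found: bool
    residue: int | None = None
    residue_type: str | None = None


def detect_tail_start(
    segmentation: Segmentation, residue_types: dict[int, str] | str
) -> TailStart:
    """Start of the final coil segment reaching the C-terminus.

    ``residue_types`` is either a residue-number -> one-letter-code map
    (e.g. from the shift table) or a full-length sequence string indexed
    1-based.  Returns ``TailStart(found=False)`` when the construct does
    not end in coil.
    """
    if not segmentation.segments:
        return TailStart(found=False)
    last = segmentation.segments[-1]
    if last.state != "coil":
        return TailStart(found=False)
    if isinstance(residue_types, str):
        rtype = residue_types[last.start - 1] if last.start <= len(residue_types) else None
    else:
        rtype = residue_types.get(last.start)
    return TailStart(found=True, residue=last.start, residue_type=rtype)
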