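"""PEST degradation-signal scan and scoring (Rogers-Wells-Rechsteiner style).

A PEST signal is a stretch rich in Pro, Glu, Ser, Thr (and Asp) lying
strictly between positively charged residues (K, R, H) or the sequence
termini; such regions are associated with rapid proteasome-dependent
turnover.  In rat Arc the signal sits in the divergent C-terminal tail.

Scoring follows the classical PEST-FIND statistic as popularised by the
EMBOSS ``epestfind`` tool:

* ``depst_fraction`` — the mass-percent of D/E/P/S/T within the candidate
  region, after subtracting one equivalent each of (D or E), P and
  (S or T); the equivalent of a pair is taken as the mean of the two
  residue masses.
* ``hydrophobicity_index`` — the mass-weighted mean of the Kyte-Doolittle
  hydropathy values linearly rescaled to a non-negative range,
  ``ltkdhi = 10 * KD + 45`` (Ile -> 90, Arg -> 0).
* ``score = 0.55 * depst_fraction - 0.5 * hydrophobicity_index``; regions
  scoring at or above +5.0 are classed *potential*, valid-but-weaker
  regions *poor*, and regions failing the residue-content rule *invalid*.

The rescaling constants and thresholds are configurable; the defaults
mirror the epestfind conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .conservation import KYTE_DOOLITTLE
from .io_formats import ProteinSequence

__all__ = [
    "PESTParams",
    "PESTRegion",
    "candidate_pest_regions",
    "pest_score",
    "pest_profile",
    "position_score_track",
    "AVERAGE_RESIDUE_MASS",
]

#: average residue masses (Da; amino acid minus water), standard values
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132, "X": 110.0,
}

POSITIVE_RESIDUES = frozenset("KRH")
DEPST = frozenset("DEPST")


def _ltkdhi(aa: str) -> float:
    """Kyte-Doolittle hydropathy rescaled to [0, 90] (Ile 90, Arg 0)."""
    return 10.0 * KYTE_DOOLITTLE[aa] + 45.0


@dataclass(frozen=True)
class PESTParams:
    min_window: int = 10
    potential_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.min_window < 2:
            raise ValueError(f"min_window must be >= 2, got {self.min_window}")


@dataclass(frozen=True)
class PESTRegion:
    """A candidate PEST segment between positively charged flanks.

    ``start``/``end`` are 1-based positions of the region itself, exclusive
    of the flanks; a flank of ``'^'``/``'$'`` marks the N-/C-terminus.
    """

    start: int
    end: int
    flank_left: str
    flank_right: str
    depst_fraction: float | None = None
    hydrophobicity_index: float | None = None
    score: float | None = None
    validity: str | None = None  # 'potential' | 'poor' | 'invalid'

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def candidate_pest_regions(
    sequence: ProteinSequence | str, min_window: int = 10
) -> list[PESTRegion]:
    """Maximal stretches between positively charged residues (or termini)
    of length >= ``min_window``.

    Regions must contain at least one P, one of {D, E} and one of {S, T};
    those failing the content rule are returned with ``validity='invalid'``
    (unscored), the rest with ``validity=None`` pending scoring.
    """
    PESTParams(min_window=min_window)  # validates
    residues = sequence.residues if isinstance(sequence, ProteinSequence) else sequence
    flanks = [(-1, "^")] + [
        (i, aa) for i, aa in enumerate(residues) if aa in POSITIVE_RESIDUES
    ] + [(len(residues), "$")]
    regions: list[PESTRegion] = []
    for (li, laa), (ri, raa) in zip(flanks, flanks[1:]):
        start, end = li + 2, ri  # 1-based, exclusive of flanks
        if end - start + 1 < min_window:
            continue
        frag = residues[start - 1 : end]
        ok = (
            "P" in frag
            and (("D" in frag) or ("E" in frag))
            and (("S" in frag) or ("T" in frag))
        )
        regions.append(
            PESTRegion(start, end, laa, raa, validity=None if ok else "invalid")
        )
    return regions


def pest_score(
    region: PESTRegion, sequence: ProteinSequence | str, params: PESTParams = PESTParams()
) -> PESTRegion:
    """Score a candidate region; invalid regions pass through unscored."""
    if region.validity == "invalid":
        return region
    residues = sequence.residues if isinstance(sequence, ProteinSequence) else sequence
    frag = residues[region.start - 1 : region.end]
    total_mass = sum(AVERAGE_RESIDUE_MASS[aa] for aa in frag)
    depst_mass = sum(AVERAGE_RESIDUE_MASS[aa] for aa in frag if aa in DEPST)
    # one equivalent each of (D|E), P, (S|T); pair equivalents as pair means
    correction = (
        (AVERAGE_RESIDUE_MASS["D"] + AVERAGE_RESIDUE_MASS["E"]) / 2.0
        + AVERAGE_RESIDUE_MASS["P"]
        + (AVERAGE_RESIDUE_MASS["S"] + AVERAGE_RESIDUE_MASS["T"]) / 2.0
    )
    depst_fraction = 100.0 * max(depst_mass - correction, 0.0) / total_mass
    hydro_index = sum(AVERAGE_RESIDUE_MASS[aa] * _ltkdhi(aa) for aa in frag) / total_mass
    score = 0.55 * depst_fraction - 0.5 * hydro_index
    validity = "potential" if score >= params.potential_threshold else "poor"
    return replace(
        region,
        depst_fraction=depst_fraction,
        hydrophobicity_index=hydro_index,
        score=score,
        validity=validity,
    )


def pest_profile(
    sequence: ProteinSequence | str, params: PESTParams = PESTParams()
) -> list[PESTRegion]:
    """All candidate regions of a sequence, scored and sorted by start."""
    regions = candidate_pest_regions(sequence, params.min_window)
    scored = [pest_score(r, sequence, params) for r in regions]
    return sorted(scored, key=lambda r: r.start)


def position_score_track(
    sequence: ProteinSequence | str, regions: list[PESTRegion]
) -> pd.DataFrame:
    """Per-position PEST score track (NaN outside scored regions)."""
    residues = sequence.residues if isinstance(sequence, ProteinSequence) else sequence
    track = [float("nan")] * len(residues)
    for r in regions:
        if r.score is None:
            continue
        for p in range(r.start, r.end + 1):
            track[p - 1] = r.score
    return pd.DataFrame(
        {
            "position": range(1, len(residues) + 1),
            "residue": list(residues),
            "pest_score": track,
        }
    )


def regions_frame(regions: list[PESTRegion]) -> pd.DataFrame:
    rows = [
        (
            r.start,
            r.end,
            r.length,
            r.depst_fraction,
            r.hydrophobicity_index,
            r.score,
            r.validity,
        )
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "start",
            "end",
            "length",
            "depst_fraction",
            "hydrophobicity_index",
            "score",
            "validity",
        ],
    )
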