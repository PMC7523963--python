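"""Per-column conservation of an ortholog family and region-wise variation rates.

The statistic of interest is deliberately simple: an alignment column is
*variant* when the family members are not unanimous there (a gap or an 'X'
counts as disagreement), and the variation rate of a region is the fraction
of variant columns among the reference positions it spans.  For mammalian
Arc orthologs — near-identical in length — this cleanly separates the
divergent C-terminal tail (residues 351-396 in rat numbering) from the
conserved capsid region.

Families of equal-length sequences are compared positionally; families with
length differences are aligned with MAFFT (recorded in the family metadata)
and all coordinates are mapped back to reference (rat) numbering.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_formats import ProteinSequence, read_fasta, write_fasta

__all__ = [
    "RegionSpec",
    "AlignedFamily",
    "ConservationProfile",
    "RegionRate",
    "build_family",
    "family_from_alignment",
    "conservation_profile",
    "region_variation_rate",
    "region_summary",
    "disorder_index",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named region in reference coordinates, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"region {self.name!r}: invalid span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class AlignedFamily:
    """Aligned ortholog sequences plus a column -> reference-position map.

    ``column_map[c]`` is the 1-based reference position of alignment column
    ``c``, or ``None`` for columns where the reference has a gap.
    """

    members: list[tuple[str, str]]  # (sequence id, aligned string with '-')
    reference_id: str
    column_map: list[int | None]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.members}
        if len(lengths) != 1:
            raise ValueError("aligned member strings differ in length")
        (width,) = lengths
        if len(self.column_map) != width:
            raise ValueError("column_map length does not match alignment width")
        refpos = [p for p in self.column_map if p is not None]
        if refpos != sorted(set(refpos)) or (refpos and refpos != list(range(refpos[0], refpos[-1] + 1))):
            raise ValueError("column_map must increase by one over non-gap reference columns")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def reference_length(self) -> int:
        return sum(1 for p in self.column_map if p is not None)

    def reference_row(self) -> str:
        for mid, aligned in self.members:
            if mid == self.reference_id:
                return aligned
        raise KeyError(self.reference_id)

    def column_of(self, reference_position: int) -> int:
        for c, p in enumerate(self.column_map):
            if p == reference_position:
                return c
        raise KeyError(f"reference position {reference_position} not in alignment")


@dataclass
class ConservationProfile:
    """Per-reference-position residue counts, majority residue and variant flag."""

    family_size: int
    positions: list[int]
    counts: dict[int, Counter]
    majority: dict[int, str]
    variant: dict[int, bool]
    reference_residue: dict[int, str]

    def variant_positions(self) -> list[int]:
        return [p for p in self.positions if self.variant[p]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.positions:
            rows.append(
                (
                    p,
                    self.reference_residue[p],
                    self.majority[p],
                    int(self.variant[p]),
                    " ".join(f"{aa}:{n}" for aa, n in sorted(self.counts[p].items())),
                )
            )
        return pd.DataFrame(
            rows, columns=["position", "reference_residue", "majority", "variant", "counts"]
        )


@dataclass(frozen=True)
class RegionRate:
    """Variation rate of one region, with the raw counts behind it."""

    region: RegionSpec
    length: int
    variant_count: int
    rate: float


# ---------------------------------------------------------------------------
# Family construction
# ---------------------------------------------------------------------------

def build_family(
    sequences: list[ProteinSequence], reference_id: str
) -> AlignedFamily:
    """Build an aligned family from raw sequences.

    Equal-length inputs are compared positionally (no alignment step);
    otherwise a global multiple alignment is computed with MAFFT and the
    column map is read off the reference row.
    """
    if len(sequences) < 2:
        raise ValueError("a family needs at least 2 sequences")
    ids = [s.id for s in sequences]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among sequence ids {ids}")
    lengths = {len(s) for s in sequences}
    if len(lengths) == 1:
        members = [(s.id, s.residues) for s in sequences]
        column_map = list(range(1, lengths.pop() + 1))
        return AlignedFamily(members, reference_id, column_map, {"engine": "positional"})
    aligned = _mafft_align(sequences)
    return family_from_alignment(aligned, reference_id, metadata={"engine": "mafft"})


def family_from_alignment(
    aligned: list[tuple[str, str]], reference_id: str, metadata: dict | None = None
) -> AlignedFamily:
    """Build a family from pre-aligned (id, gapped string) rows."""
    ids = [mid for mid, _ in aligned]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among sequence ids {ids}")
    ref_row = dict(aligned)[reference_id]
    column_map: list[int | None] = []
    pos = 0
    for ch in ref_row:
        if ch == "-":
            column_map.append(None)
        else:
            pos += 1
            column_map.append(pos)
    return AlignedFamily(list(aligned), reference_id, column_map, metadata or {})


def _mafft_align(sequences: list[ProteinSequence]) -> list[tuple[str, str]]:
    if shutil.which("mafft") is None:
        raise RuntimeError("sequences differ in length and MAFFT is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta_in = Path(tmp) / "family.fasta"
        write_fasta(sequences, fasta_in)
        proc = subprocess.run(
            ["mafft", "--auto", "--anysymbol", "--quiet", str(fasta_in)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: list[tuple[str, str]] = []
    current_id, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if current_id is not None:
                aligned.append((current_id, "".join(chunks).upper()))
            current_id, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if current_id is not None:
        aligned.append((current_id, "".join(chunks).upper()))
    return aligned


# ---------------------------------------------------------------------------
# Conservation statistics
# ---------------------------------------------------------------------------

def conservation_profile(family: AlignedFamily) -> ConservationProfile:
    """Per-reference-position counts, majority residue, and variant flag.

    A position is variant unless every member carries the same standard
    residue there; gaps and the ambiguity code 'X' never count as agreement.
    Majority ties are broken in favour of the reference residue, then
    alphabetically.
    """
    ref_row = family.reference_row()
    positions, counts, majority, variant, ref_res = [], {}, {}, {}, {}
    for c, p in enumerate(family.column_map):
        if p is None:
            continue
        column = [aligned[c] for _, aligned in family.members]
        ctr = Counter(column)
        is_variant = len(ctr) > 1 or "X" in ctr or "-" in ctr
        ref_aa = ref_row[c]
        best = max(ctr.values())
        tied = sorted(aa for aa, n in ctr.items() if n == best)
        maj = ref_aa if ref_aa in tied else tied[0]
        positions.append(p)
        counts[p] = ctr
        majority[p] = maj
        variant[p] = is_variant
        ref_res[p] = ref_aa
    return ConservationProfile(family.size, positions, counts, majority, variant, ref_res)


def region_variation_rate(profile: ConservationProfile, region: RegionSpec) -> RegionRate:
    """Fraction of variant positions within a region (plus raw counts)."""
    last = profile.positions[-1]
    if region.end > last:
        raise ValueError(f"region {region.name!r} ({region.start}-{region.end}) exceeds reference length {last}")
    n_variant = sum(1 for p in region.positions() if profile.variant[p])
    return RegionRate(region, region.length, n_variant, n_variant / region.length)


def region_summary(profile: ConservationProfile, regions: list[RegionSpec]) -> pd.DataFrame:
    rows = []
    for region in regions:
        rr = region_variation_rate(profile, region)
        rows.append((region.name, rr.length, rr.variant_count, rr.rate))
    return pd.DataFrame(rows, columns=["region", "length", "variant_count", "variation_rate"])


# ---------------------------------------------------------------------------
# Charge/hydropathy disorder index (plumbing, not a disorder predictor)
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy values
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

_CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}


def disorder_index(sequence: ProteinSequence | str, window: int = 21) -> list[float]:
    """Sliding-window charge/hydropathy disorder index.

    For each residue i, over a window of ``window`` residues centred on i
    (truncated at the termini), compute the mean absolute net charge per
    residue ``<R>`` and the mean Kyte-Doolittle hydropathy normalised to
    [0, 1], ``<H> = (KD + 4.5) / 9``.  The score is

        d(i) = (<R> + 1.151) / 2.785 - <H>

    i.e. the signed distance of the window from the charge/hydropathy
    order-disorder boundary line: positive scores indicate disorder.  This
    is a simple built-in cross-check index, not a replacement for dedicated
    disorder predictors.
    """
    residues = sequence.residues if isinstance(sequence, ProteinSequence) else sequence
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > len(residues):
        raise ValueError(f"window {window} larger than sequence length {len(residues)}")
    half = window // 2
    scores = []
    for i in range(len(residues)):
        lo, hi = max(0, i - half), min(len(residues), i + half + 1)
        frag = residues[lo:hi]
        mean_charge = abs(sum(_CHARGE.get(aa, 0.0) for aa in frag)) / len(frag)
        mean_hydro = sum((KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in frag) / len(frag)
        scores.append((mean_charge + 1.151) / 2.785 - mean_hydro)
    return scores
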