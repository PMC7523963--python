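"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Every generator takes an explicit seed, returns machine-readable truth
alongside the data, and is byte-deterministic for a fixed seed.  The
defaults encode the study conditions for an Arc-like protein of 396
residues in rat numbering:

* ortholog families of nine members with per-region column substitution
  probabilities 0.391 (C-terminal tail, 351-396), 0.070 (N-lobe, 207-277)
  and 0.1365 elsewhere in 1-350 (so the 1-350 average is 0.123);
* chemical-shift tables for the 280-396 construct with five planted
  α-helices in the C-lobe (all ending by residue 356) and a random-coil
  tail from D357: coil ΔCα drawn uniformly within the ±0.05 ppm
  insignificance band with occasional isolated "discrete" outliers,
  helix magnitude +2.5 ± 0.3 ppm;
* construct pairs whose amide shifts differ only at inter-domain junction
  residues (282-285 or 362-363) above a small spectral-reproducibility
  noise floor;
* a PEST-compliant D/E/P/S/T-rich segment implanted at 351-392 between
  lysine flanks.

All sequences produced here are synthetic stand-ins: random backbones with
the features above implanted, not database sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemshift import Segment, Segmentation, WISHART_RANDOM_COIL_CA
from .conservation import AlignedFamily, RegionSpec
from .io_formats import ChemicalShiftTable, ProteinSequence, ShiftEntry, STANDARD_AA

__all__ = [
    "FamilyConfig",
    "ShiftConfig",
    "CspConfig",
    "PestConfig",
    "SimulationConfig",
    "simulate_family",
    "simulate_shift_table",
    "simulate_csp_pair",
    "implant_pest",
    "synthetic_arc_sequence",
    "DEFAULT_REGIONS",
    "DEFAULT_HELICES",
]

#: study regions in reference (rat) numbering with per-column substitution
#: probabilities; 0.1365 outside the named regions makes the 1-350 average
#: 0.123 given the N-lobe at 0.070.
DEFAULT_REGIONS: list[tuple[RegionSpec, float]] = [
    (RegionSpec("nterm_and_core", 1, 206), 0.1365),
    (RegionSpec("n_lobe", 207, 277), 0.070),
    (RegionSpec("c_lobe_core", 278, 350), 0.1365),
    (RegionSpec("c_terminal_tail", 351, 396), 0.391),
]

#: planted α-helix spans of the C-lobe five-helix bundle (construct 280-396);
#: everything else in the construct, including the tail from 357, is coil.
DEFAULT_HELICES: list[tuple[int, int]] = [
    (281, 289),
    (293, 304),
    (308, 319),
    (323, 337),
    (342, 356),
]

#: D/E/P/S/T-rich implant template (no K/R/H; contains P, D/E and S/T,
#: interleaved with small neutral residues as in natural PEST stretches)
DEFAULT_PEST_RECIPE = "ESPTAGDQSVETLPSDGQ"


@dataclass
class FamilyConfig:
    n_members: int = 9
    reference_length: int = 396
    regions: list[tuple[RegionSpec, float]] = field(
        default_factory=lambda: list(DEFAULT_REGIONS)
    )


@dataclass
class ShiftConfig:
    construct_range: tuple[int, int] = (280, 396)
    helices: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_HELICES))
    strands: list[tuple[int, int]] = field(default_factory=list)
    magnitude: dict = field(
        default_factory=lambda: {"helix": 2.5, "strand": -2.5, "coil": 0.0}
    )
    noise_sigma: dict = field(
        default_factory=lambda: {"helix": 0.3, "strand": 0.3, "coil": 0.03}
    )
    #: when set, coil ΔCα is drawn uniformly within ±coil_band (the
    #: "insignificant" band) instead of Gaussian noise_sigma['coil']
    coil_band: float | None = 0.05
    coil_outlier_prob: float = 0.05
    coil_outlier_range: tuple[float, float] = (0.1, 0.5)
    missing: list[int] | str = "auto"  # 'auto': first two residues + prolines


@dataclass
class CspConfig:
    construct_range: tuple[int, int] = (280, 396)
    perturbed: frozenset[int] = frozenset({282, 283, 284, 285})
    offset_h: float = 0.15
    offset_n: float = 0.6
    noise_sigma_h: float = 0.01
    noise_sigma_n: float = 0.05


@dataclass
class PestConfig:
    region: tuple[int, int] = (351, 392)
    recipe: str = DEFAULT_PEST_RECIPE


@dataclass
class SimulationConfig:
    seed: int
    family: FamilyConfig = field(default_factory=FamilyConfig)
    shifts: ShiftConfig = field(default_factory=ShiftConfig)
    csp: CspConfig = field(default_factory=CspConfig)
    pest: PestConfig = field(default_factory=PestConfig)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def synthetic_arc_sequence(seed: int = 0, length: int = 396) -> ProteinSequence:
    """A synthetic Arc-like reference sequence (random backbone, not a
    database sequence) with the features the pipeline expects planted:
    a PEST-compliant segment at 351-392 between lysine flanks, and an
    aspartate at position 357 where the disordered tail begins."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(STANDARD_AA), size=length))
    seq = ProteinSequence("SYN_ARC", "synthetic Arc-like stand-in", residues)
    if length >= 396:
        seq = implant_pest(seq, RegionSpec("pest_implant", 351, 392), DEFAULT_PEST_RECIPE)
        r = list(seq.residues)
        r[356] = "D"  # tail starts at D357
        seq = ProteinSequence(seq.id, seq.species, "".join(r))
    return seq


def implant_pest(
    sequence: ProteinSequence, region: RegionSpec, recipe: str = DEFAULT_PEST_RECIPE
) -> ProteinSequence:
    """Replace ``region`` with a D/E/P/S/T-rich stretch built from ``recipe``
    (cycled to length), placing K flanks immediately outside the region
    where the sequence extends that far."""
    if region.end > len(sequence.residues):
        raise ValueError("implant region extends beyond the sequence")
    bad = set(recipe) & set("KRH")
    if bad:
        raise ValueError(f"recipe contains positively charged residues {sorted(bad)}")
    if "P" not in recipe:
        raise ValueError("recipe must contain at least one P")
    if not set(recipe) & set("DE"):
        raise ValueError("recipe must contain at least one of D/E")
    if not set(recipe) & set("ST"):
        raise ValueError("recipe must contain at least one of S/T")
    length = region.length
    fragment = (recipe * (length // len(recipe) + 1))[:length]
    if "P" not in fragment or not set(fragment) & set("DE") or not set(fragment) & set("ST"):
        fragment = "PES" + fragment[3:]  # guarantee content for short regions
    r = list(sequence.residues)
    r[region.start - 1 : region.end] = list(fragment)
    if region.start >= 2:
        r[region.start - 2] = "K"
    if region.end < len(r):
        r[region.end] = "K"
    return ProteinSequence(sequence.id, sequence.species, "".join(r))


# ---------------------------------------------------------------------------
# Ortholog families
# ---------------------------------------------------------------------------

def simulate_family(
    config: FamilyConfig | None = None, seed: int = 0
) -> tuple[AlignedFamily, set[int]]:
    """Gapless equal-length ortholog family with per-region variant columns.

    Each reference position covered by a region becomes variant with that
    region's probability: one randomly chosen non-reference member gets a
    uniformly drawn different residue there.  Returns the family and the
    set of positions actually made variant (the truth labels).
    """
    config = config or FamilyConfig()
    if config.n_members < 2:
        raise ValueError("a family needs at least 2 members")
    rng = np.random.default_rng(seed)
    length = config.reference_length
    reference = list(rng.choice(list(STANDARD_AA), size=length))
    rows = [list(reference) for _ in range(config.n_members)]
    prob = np.zeros(length)
    for region, p in config.regions:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"substitution probability {p} outside [0, 1]")
        if region.end > length:
            raise ValueError(f"region {region.name!r} outside reference length")
        prob[region.start - 1 : region.end] = p
    truth: set[int] = set()
    for pos in range(length):
        if rng.random() < prob[pos]:
            member = int(rng.integers(1, config.n_members))  # never the reference
            alternatives = [aa for aa in STANDARD_AA if aa != reference[pos]]
            rows[member][pos] = alternatives[int(rng.integers(len(alternatives)))]
            truth.add(pos + 1)
    names = ["reference"] + [f"ortholog_{k}" for k in range(1, config.n_members)]
    members = [(name, "".join(row)) for name, row in zip(names, rows)]
    family = AlignedFamily(
        members, "reference", list(range(1, length + 1)), {"engine": "synthetic"}
    )
    return family, truth


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------

def _truth_segmentation(config: ShiftConfig) -> Segmentation:
    lo, hi = config.construct_range
    labelled = {}
    for s, e in config.helices:
        for r in range(s, e + 1):
            labelled[r] = "helix"
    for s, e in config.strands:
        for r in range(s, e + 1):
            labelled[r] = "strand"
    segments = []
    start = lo
    current = labelled.get(lo, "coil")
    for r in range(lo + 1, hi + 1):
        state = labelled.get(r, "coil")
        if state != current:
            segments.append(Segment(start, r - 1, current))
            start, current = r, state
    segments.append(Segment(start, hi, current))
    return Segmentation(segments, 0.0, 0.0, 1)


def simulate_shift_table(
    config: ShiftConfig | None = None,
    seed: int = 0,
    sequence: ProteinSequence | None = None,
) -> tuple[ChemicalShiftTable, Segmentation]:
    """CA/H/N shift table with a planted helix/strand/coil pattern.

    CA(i) = random-coil reference + planted ΔCα of the residue's state
    + Gaussian noise (per-state sigma); coil residues additionally receive
    occasional isolated "discrete" outliers.  H/N are drawn near nominal
    amide values.  Residues listed as missing (default: the first two of
    the construct plus all prolines) are omitted, as in real assignments.
    Returns the table and the planted truth segmentation.
    """
    config = config or ShiftConfig()
    rng = np.random.default_rng(seed)
    sequence = sequence or synthetic_arc_sequence(0)
    lo, hi = config.construct_range
    if hi > len(sequence.residues):
        raise ValueError("construct range outside sequence")
    truth = _truth_segmentation(config)
    if config.missing == "auto":
        missing = {lo, lo + 1} | {
            r for r in range(lo, hi + 1) if sequence.residue(r) == "P"
        }
    else:
        missing = set(config.missing)
    entries: list[ShiftEntry] = []
    for r in range(lo, hi + 1):
        state = truth.state_at(r)
        aa = sequence.residue(r)
        planted = config.magnitude[state]
        if state == "coil" and config.coil_band is not None:
            jitter = rng.uniform(-config.coil_band, config.coil_band)
        else:
            sigma = config.noise_sigma[state]
            jitter = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        dca = planted + jitter
        if state == "coil" and config.coil_outlier_prob > 0:
            # "discrete" outliers are isolated: never flush against a
            # planted helix/strand, where they would read as its extension
            neighbours_coil = all(
                truth.state_at(q) in (None, "coil") for q in (r - 1, r + 1)
            )
            if neighbours_coil and rng.random() < config.coil_outlier_prob:
                a, b = config.coil_outlier_range
                dca += float(rng.choice([-1.0, 1.0])) * rng.uniform(a, b)
        h = 8.3 + rng.normal(0.0, 0.4)
        n = 119.0 + rng.normal(0.0, 3.0)
        if r in missing:
            continue
        entries.append(ShiftEntry(r, aa, "CA", WISHART_RANDOM_COIL_CA[aa] + dca))
        entries.append(ShiftEntry(r, aa, "H", h))
        entries.append(ShiftEntry(r, aa, "N", n))
    table = ChemicalShiftTable(f"SYN_{lo}-{hi}", entries, (lo, hi))
    return table, truth


# ---------------------------------------------------------------------------
# CSP construct pairs
# ---------------------------------------------------------------------------

def simulate_csp_pair(
    config: CspConfig | None = None,
    seed: int = 0,
    sequence: ProteinSequence | None = None,
) -> tuple[ChemicalShiftTable, ChemicalShiftTable, set[int]]:
    """Two amide shift tables differing by planted perturbations.

    The second table equals the first with (ΔH, ΔN) offsets applied at the
    truth residues and Gaussian noise (spectral reproducibility) added
    everywhere else.  Returns (table_a, table_b, truth set).
    """
    config = config or CspConfig()
    rng = np.random.default_rng(seed)
    sequence = sequence or synthetic_arc_sequence(0)
    lo, hi = config.construct_range
    entries_a, entries_b = [], []
    for r in range(lo, hi + 1):
        aa = sequence.residue(r)
        if aa == "P":  # prolines have no backbone amide
            continue
        h = 8.3 + rng.normal(0.0, 0.4)
        n = 119.0 + rng.normal(0.0, 3.0)
        if r in config.perturbed:
            hb, nb = h + config.offset_h, n + config.offset_n
        else:
            hb = h + rng.normal(0.0, config.noise_sigma_h)
            nb = n + rng.normal(0.0, config.noise_sigma_n)
        entries_a += [ShiftEntry(r, aa, "H", h), ShiftEntry(r, aa, "N", n)]
        entries_b += [ShiftEntry(r, aa, "H", hb), ShiftEntry(r, aa, "N", nb)]
    table_a = ChemicalShiftTable(f"SYN_A_{lo}-{hi}", entries_a, (lo, hi))
    table_b = ChemicalShiftTable(f"SYN_B_{lo}-{hi}", entries_b, (lo, hi))
    truth = {r for r in config.perturbed if lo <= r <= hi and sequence.residue(r) != "P"}
    return table_a, table_b, truth
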