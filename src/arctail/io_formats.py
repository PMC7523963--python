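"""Readers and writers for the external formats the pipeline touches.

Every other module consumes only the domain types built here:
:class:`ProteinSequence` (FASTA) and :class:`ChemicalShiftTable` (NMR-STAR
v3.x assigned-chemical-shift loops).  Residue numbering is 1-based and kept
in full-length protein coordinates throughout — BMRB depositions of
subdomain constructs carry full-length numbering in the author sequence
codes, and that is the column this reader uses.

Only the assigned-chemical-shift loop of NMR-STAR is handled; the full
NMR-STAR data model, spectra and structures are out of scope.
"""

from __future__ import annotations

import json
import math
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import seq1

__all__ = [
    "ProteinSequence",
    "ShiftEntry",
    "ChemicalShiftTable",
    "read_fasta",
    "read_aligned_fasta",
    "write_fasta",
    "read_nmrstar_shifts",
    "write_nmrstar_shifts",
    "write_tables",
    "read_table",
    "fetch_cached",
    "FLOAT_DECIMALS",
]

#: one-letter codes accepted in protein sequences ('X' = unknown residue)
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_ALPHABET = frozenset(STANDARD_AA + "X")

#: fixed precision (decimal places) used by all table writers; TSV output
#: round-trips to identical values at this precision.
FLOAT_DECIMALS = 4

#: backbone atoms consumed by downstream stages; other atom names in a
#: shift loop are preserved but ignored.
BACKBONE_ATOMS = ("CA", "H", "N")


class FastaParseError(ValueError):
    """Malformed FASTA input (reports the offending line)."""


class NmrStarFormatError(ValueError):
    """NMR-STAR file without a usable assigned-chemical-shift loop."""


class ShiftIntegrityError(ValueError):
    """Duplicate or inconsistent rows in a chemical-shift loop."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with 1-based residue positions.

    ``id`` is an accession or label (first whitespace-delimited token of the
    FASTA header); ``species`` is the remainder of the header, or ``""``.
    """

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residue codes: "
                f"{sorted(bad)} (allowed: 20 standard one-letter codes + X)"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"position {position} outside 1..{len(self.residues)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class ShiftEntry:
    """One assigned chemical shift: residue (full-length numbering), atom, ppm."""

    residue_number: int
    residue_type: str
    atom: str
    shift: float


@dataclass
class ChemicalShiftTable:
    """Assigned per-residue, per-atom chemical shifts for one construct.

    ``construct_range`` declares the residue span of the construct in
    full-length coordinates (e.g. (280, 396) for a C-lobe + tail fragment);
    every entry must fall inside it.
    """

    construct_id: str
    entries: list[ShiftEntry]
    construct_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for e in self.entries:
            key = (e.residue_number, e.atom)
            if key in seen:
                raise ShiftIntegrityError(
                    f"{self.construct_id}: duplicate shift for residue "
                    f"{e.residue_number} atom {e.atom}"
                )
            seen.add(key)
            if not math.isfinite(e.shift):
                raise ShiftIntegrityError(
                    f"{self.construct_id}: non-finite shift at residue "
                    f"{e.residue_number} atom {e.atom}"
                )
            if self.construct_range is not None:
                lo, hi = self.construct_range
                if not lo <= e.residue_number <= hi:
                    raise ShiftIntegrityError(
                        f"{self.construct_id}: residue {e.residue_number} outside "
                        f"declared construct range {lo}-{hi}"
                    )

    def atoms(self, atom: str) -> dict[int, float]:
        """residue number -> shift for one atom name."""
        return {e.residue_number: e.shift for e in self.entries if e.atom == atom}

    def residue_types(self) -> dict[int, str]:
        return {e.residue_number: e.residue_type for e in self.entries}

    @property
    def residue_span(self) -> tuple[int, int]:
        if self.construct_range is not None:
            return self.construct_range
        nums = [e.residue_number for e in self.entries]
        return (min(nums), max(nums))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.residue_number, e.residue_type, e.atom, e.shift) for e in self.entries],
            columns=["residue", "residue_type", "atom", "shift"],
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (plain or aligned) protein FASTA file.

    Header convention: ``>id species words...`` — the first token becomes
    ``id``, the rest ``species``.  Residues are uppercased; anything outside
    the 20 standard codes plus 'X' (or '-' in aligned input, which is kept)
    is rejected.
    """
    return [
        ProteinSequence(rid, species, residues)
        for rid, species, residues in _iter_fasta(Path(path))
    ]


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read an aligned FASTA file, keeping '-' gap characters.

    Returns ``(id, species, gapped_string)`` triples; letters are validated
    against the same alphabet as :func:`read_fasta`.
    """
    out = []
    for rid, species, residues in _iter_fasta(Path(path), allow_gaps=True):
        out.append((rid, species, residues))
    return out


def _iter_fasta(path: Path, allow_gaps: bool = False):
    _prescan_fasta(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        parts = rec.description.split(None, 1)
        species = parts[1].strip() if len(parts) > 1 else ""
        residues = str(rec.seq).upper()
        allowed = VALID_ALPHABET | ({"-"} if allow_gaps else set())
        bad = set(residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {rec.id!r} contains non-standard residue codes: "
                f"{sorted(bad)} (allowed: 20 standard one-letter codes + X)"
            )
        yield rec.id, species, residues


def _prescan_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected FASTA header '>' , got {line.strip()[:30]!r}"
                    )
                return
    raise FastaParseError(f"{path}: empty file")


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            header = f">{s.id} {s.species}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# NMR-STAR v3.x assigned-chemical-shift loop
# ---------------------------------------------------------------------------

_STAR_TOKEN = re.compile(r"'[^']*'|\"[^\"]*\"|\S+")


def _star_tokens(line: str) -> list[str]:
    return [t.strip("'\"") for t in _STAR_TOKEN.findall(line)]


def read_nmrstar_shifts(
    path: str | Path, construct_id: str, construct_range: tuple[int, int] | None = None
) -> ChemicalShiftTable:
    """Read the assigned-chemical-shift loop of an NMR-STAR v3.x entry.

    Residue numbering is taken from the author sequence code
    (``_Atom_chem_shift.Auth_seq_ID``) when present and numeric — BMRB
    subdomain depositions keep full-length numbering there — falling back to
    ``Seq_ID``/``Comp_index_ID`` otherwise; the chosen column is recorded in
    ``table.numbering_source``.  Unknown atom names are kept; downstream
    stages only look at CA/H/N.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() == "loop_":
            tags: list[str] = []
            j = i + 1
            while j < n and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_shift_loop(
                    lines, j, tags, construct_id, construct_range, path
                )
            i = j
        else:
            i += 1
    raise NmrStarFormatError(f"{path}: no _Atom_chem_shift loop found")


def _parse_shift_loop(
    lines: list[str],
    start: int,
    tags: list[str],
    construct_id: str,
    construct_range: tuple[int, int] | None,
    path: Path,
) -> ChemicalShiftTable:
    cols = {t.split(".", 1)[1]: k for k, t in enumerate(tags)}

    def col(*names: str) -> int | None:
        for name in names:
            if name in cols:
                return cols[name]
        return None

    c_auth = col("Auth_seq_ID")
    c_seq = col("Seq_ID", "Comp_index_ID")
    c_comp = col("Comp_ID")
    c_atom = col("Atom_ID")
    c_val = col("Val")
    if c_comp is None or c_atom is None or c_val is None or (c_auth is None and c_seq is None):
        raise NmrStarFormatError(f"{path}: shift loop lacks required columns")

    entries: list[ShiftEntry] = []
    numbering_source = None
    for line in lines[start:]:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s == "stop_":
            break
        row = _star_tokens(s)
        if len(row) < len(tags):
            continue
        seq_id = None
        if c_auth is not None and row[c_auth] not in (".", "?"):
            try:
                seq_id = int(row[c_auth])
                numbering_source = numbering_source or "Auth_seq_ID"
            except ValueError:
                seq_id = None
        if seq_id is None and c_seq is not None:
            seq_id = int(row[c_seq])
            numbering_source = numbering_source or "Seq_ID"
        if row[c_val] in (".", "?"):
            continue
        comp = row[c_comp]
        rtype = comp if len(comp) == 1 else seq1(comp.capitalize())
        entries.append(ShiftEntry(seq_id, rtype.upper(), row[c_atom].upper(), float(row[c_val])))
    if not entries:
        raise NmrStarFormatError(f"{path}: shift loop contains no data rows")
    table = ChemicalShiftTable(construct_id, entries, construct_range)
    table.numbering_source = numbering_source  # type: ignore[attr-defined]
    return table


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_nmrstar_shifts(table: ChemicalShiftTable, path: str | Path) -> None:
    """Write a minimal NMR-STAR v3.x entry holding one assigned-shift loop."""
    with open(path, "w") as fh:
        fh.write(f"data_{table.construct_id}\n\n")
        fh.write("save_assigned_chemical_shifts\n")
        fh.write("   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts\n\n")
        fh.write("   loop_\n")
        for tag in ("ID", "Auth_seq_ID", "Comp_ID", "Atom_ID", "Val"):
            fh.write(f"      _Atom_chem_shift.{tag}\n")
        fh.write("\n")
        for k, e in enumerate(
            sorted(table.entries, key=lambda e: (e.residue_number, e.atom)), start=1
        ):
            comp = _AA3.get(e.residue_type, "UNK")
            fh.write(
                f"      {k} {e.residue_number} {comp} {e.atom} "
                f"{e.shift:.{FLOAT_DECIMALS}f}\n"
            )
        fh.write("   stop_\nsave_\n")


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_tables(results, path: str | Path, format: str = "tsv") -> None:
    """Write a result object (anything with ``to_frame()``, or a DataFrame)
    as TSV or JSON with a deterministic column order and fixed float
    precision (:data:`FLOAT_DECIMALS` decimals)."""
    frame = results if isinstance(results, pd.DataFrame) else results.to_frame()
    fmt = format.lower()
    path = Path(path)
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False, float_format=f"%.{FLOAT_DECIMALS}f")
    elif fmt == "json":
        rounded = frame.round(FLOAT_DECIMALS)
        path.write_text(json.dumps(rounded.to_dict(orient="records"), indent=1) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Optional accession fetch with on-disk caching
# ---------------------------------------------------------------------------

_NCBI_FASTA = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={acc}&rettype=fasta&retmode=text"
)
_BMRB_STAR = "https://bmrb.io/ftp/pub/bmrb/entry_directories/bmr{entry}/bmr{entry}_3.str"


def fetch_cached(kind: str, accession: str, cache_dir: str | Path) -> Path:
    """Download a FASTA (``kind='fasta'``) or BMRB NMR-STAR (``kind='bmrb'``)
    record by accession, caching on disk; returns the cached path.  Requires
    network access on first call for a given accession."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    suffix = {"fasta": ".fasta", "bmrb": ".str"}[kind]
    target = cache_dir / f"{accession}{suffix}"
    if target.exists():
        return target
    url = _NCBI_FASTA.format(acc=accession) if kind == "fasta" else _BMRB_STAR.format(entry=accession)
    with urllib.request.urlopen(url, timeout=60) as resp:
        target.write_bytes(resp.read())
    return target
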