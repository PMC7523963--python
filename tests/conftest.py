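import pytest

from arctail import synthetic_arc_sequence


NMRSTAR_3RES = """\
data_minimal

save_assigned_chemical_shifts
   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts

   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Auth_seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val

      1 280 GLY CA 45.2
      2 280 GLY H  8.31
      3 280 GLY N  109.5
      4 281 ALA CA 54.8
      5 281 ALA H  8.10
      6 281 ALA N  123.4
      7 282 ASP CA 54.1
      8 282 ASP H  8.45
      9 282 ASP N  120.2
   stop_
save_
"""


@pytest.fixture
def nmrstar_file(tmp_path):
    path = tmp_path / "minimal.str"
    path.write_text(NMRSTAR_3RES)
    return path


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def arc_sequence():
    """The synthetic Arc-like stand-in sequence (396 residues)."""
    return synthetic_arc_sequence(0)
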