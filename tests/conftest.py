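import numpy as np
import pytest

from elevator.synth import ToyElevatorSpec, make_toy_elevator


def format_pdb_atom(serial, name, resname, chain, resnum, x, y, z,
                    occ=1.00, b=0.00, element="C", altloc=" "):
    """Hand-rolled fixed-column PDB ATOM record for small fixtures."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field}{altloc}{resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    """Minimal hand-written PDB with known coordinates."""
    lines = [
        format_pdb_atom(1, "N", "ALA", "A", 1, 11.104, 6.134, 2.458, element="N"),
        format_pdb_atom(2, "CA", "ALA", "A", 1, 12.560, 6.351, 2.496),
        format_pdb_atom(3, "C", "ALA", "A", 1, 13.059, 6.590, 3.927),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    expected = np.array(
        [
            [11.104, 6.134, 2.458],
            [12.560, 6.351, 2.496],
            [13.059, 6.590, 3.927],
        ]
    )
    return path, expected


@pytest.fixture
def toy_elevator():
    """Default two-state toy: 5 Å core shift, no rotation."""
    return make_toy_elevator(ToyElevatorSpec(shift=5.0))


@pytest.fixture
def small_toy_elevator():
    """Smaller toy for mode computations in tight loops."""
    return make_toy_elevator(
        ToyElevatorSpec(scaffold_residues=40, core_residues=40, shift=5.0)
    )
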