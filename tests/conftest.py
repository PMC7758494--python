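"""Shared fixtures: tiny hand-written PDB texts and synthetic monomers."""

from __future__ import annotations

import textwrap

import pytest

from actin_audit import extract_monomer
from actin_audit import synthetic as syn


def _pdb_line(serial: int, name: str, res_name: str, chain: str, res_seq: int,
              x: float, y: float, z: float, element: str,
              record: str = "ATOM", altloc: str = " ") -> str:
    return (f"{record:<6}{serial:>5} {name:^4}{altloc}{res_name:>3} {chain}"
            f"{res_seq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {element:>2}")


@pytest.fixture
def pdb_line_factory():
    return _pdb_line


@pytest.fixture
def single_atom_pdb(tmp_path):
    """One well-formed Calpha of ALA."""
    p = tmp_path / "one.pdb"
    p.write_text(_pdb_line(1, "CA", "ALA", "A", 1, 11.1, 6.1, -6.5, "C") + "\nEND\n")
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Chains A and B, three Calpha-bearing residues each."""
    lines = []
    serial = 0
    for chain in "AB":
        for i in range(3):
            serial += 1
            lines.append(_pdb_line(serial, "CA", "GLY", chain, i + 1,
                                   float(i), 0.0, 0.0 if chain == "A" else 5.0, "C"))
    p = tmp_path / "two_chains.pdb"
    p.write_text("\n".join(lines) + "\nEND\n")
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    """MODEL 1 with 2 atoms, MODEL 2 with 3 atoms; only MODEL 1 counts."""
    lines = ["MODEL        1"]
    for i in range(2):
        lines.append(_pdb_line(i + 1, "CA", "ALA", "A", i + 1, float(i), 0, 0, "C"))
    lines += ["ENDMDL", "MODEL        2"]
    for i in range(3):
        lines.append(_pdb_line(i + 1, "CA", "ALA", "A", i + 1, float(i), 1, 0, "C"))
    lines += ["ENDMDL", "END"]
    p = tmp_path / "models.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def helix_monomer():
    """30-residue ideal-helix monomer."""
    return extract_monomer(syn.make_backbone(30), chain="A")


@pytest.fixture
def helix_pair():
    """Identical helix monomer under a random rigid motion."""
    base = syn.make_backbone(30)
    moved = syn.rigid_copy(base, seed=11)
    return extract_monomer(base, chain="A"), extract_monomer(moved, chain="A")


def write_pdb_text(tmp_path, name: str, body: str):
    p = tmp_path / name
    p.write_text(textwrap.dedent(body))
    return p
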