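"""Structure and sequence I/O.

Reads legacy-format PDB files (via gemmi), selects the monomer chain to be
analysed from each entry, and handles FASTA and tabular report files.  The
chain-selection rule mirrors common ensemble-audit practice for entries that
contain several copies of the same protein (filaments, crystallographic
dimers): unless a chain is named explicitly, the first protein chain in file
order is taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "StructureModel",
    "MonomerRecord",
    "StructureParseError",
    "EmptyStructureError",
    "ChainSelectionError",
    "read_structure",
    "write_structure",
    "extract_monomer",
    "read_fasta",
    "write_fasta",
    "write_table",
    "THREE_TO_ONE",
]


class StructureParseError(ValueError):
    """A structure file could not be parsed."""


class EmptyStructureError(StructureParseError):
    """The file contained no ATOM records."""


class ChainSelectionError(ValueError):
    """No chain satisfied the monomer-selection rule."""


#: 3-letter -> 1-letter codes for the 20 standard residues plus common
#: variants seen in legacy PDB files; anything absent maps to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # frequent modified/nonstandard residues
    "MSE": "M", "SEC": "U", "PYL": "O", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "HIC": "H",
}


@dataclass(frozen=True, slots=True)
class Atom:
    """One atom of a structure, author numbering, coordinates in angstrom."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    coord: np.ndarray  # shape (3,)
    record_kind: str  # "ATOM" | "HETATM"

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coord must be 3 finite components")
        object.__setattr__(self, "coord", c)


@dataclass(slots=True)
class StructureModel:
    """Parsed structure: ordered atoms plus the derived chain list."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atoms(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(slots=True)
class MonomerRecord:
    """One selected protein chain: sequence and parallel Calpha trace.

    Residues that lack a Calpha atom are excluded from all three parallel
    lists, so ``len(sequence) == len(ca_coords) == len(res_numbers)`` always.
    """

    source_id: str
    sequence: str
    ca_coords: np.ndarray  # shape (n, 3)
    res_numbers: list[int]

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if not (len(self.sequence) == len(self.ca_coords) == len(self.res_numbers)):
            raise ValueError("sequence, ca_coords and res_numbers must be parallel")

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_pdb_lines(path: Path) -> int:
    """Check coordinate columns of ATOM/HETATM lines; return the record count.

    gemmi tolerates malformed coordinate fields (it reads them as 0), so the
    fixed columns 31-54 are checked here first and a parse error naming the
    offending line is raised instead.
    """
    n_atom_records = 0
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            n_atom_records += 1
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError(
                    f"{path}: line {lineno}: truncated coordinate record"
                )
            for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fragment = line[lo:hi]
                try:
                    float(fragment)
                except ValueError:
                    raise StructureParseError(
                        f"{path}: line {lineno}: malformed {label} coordinate "
                        f"field {fragment!r}"
                    ) from None
    return n_atom_records


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a legacy-format PDB file into a :class:`StructureModel`.

    Only the first MODEL block is kept; alternate locations other than
    blank/'A' are dropped.  Raises :class:`EmptyStructureError` for files
    without ATOM records and :class:`StructureParseError` (naming the line)
    for malformed coordinate fields.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}; only 'pdb' in v1")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)

    if _validate_pdb_lines(path) == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi internal
        raise StructureParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    serial = 0
    has_atom_record = False
    model = st[0]  # MODEL blocks after the first are ignored
    for chain in model:
        for res in chain:
            kind = "HETATM" if res.het_flag == "H" else "ATOM"
            for at in res:
                if at.altloc not in ("\x00", "", "A"):
                    continue
                serial += 1
                element = at.element.name.upper()
                if not element or element == "X":
                    element = _element_from_name(at.name)
                if kind == "ATOM":
                    has_atom_record = True
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=element,
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        record_kind=kind,
                    )
                )
    if not has_atom_record:
        raise EmptyStructureError(f"{path}: no ATOM records (HETATM only)")
    return StructureModel(id=path.stem, atoms=atoms)


def _element_from_name(atom_name: str) -> str:
    """Fall back to the atom name when the element column is absent."""
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return stripped[:2].upper()
    return stripped[:1].upper() if stripped else "C"


def write_structure(s: StructureModel, path: str | Path,
                    remarks: Sequence[str] = ()) -> None:
    """Write a :class:`StructureModel` back to legacy PDB format via gemmi."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model(1)
    chain_obj: gemmi.Chain | None = None
    res_obj: gemmi.Residue | None = None
    last_key: tuple[str, int, str, str] | None = None
    for a in s.atoms:
        if chain_obj is None or chain_obj.name != a.chain_id:
            chain_obj = gemmi.Chain(a.chain_id)
            model.add_chain(chain_obj)
            chain_obj = model[-1]
            last_key = None
        key = (a.chain_id, a.res_seq, a.icode, a.res_name)
        if key != last_key:
            res_obj = gemmi.Residue()
            res_obj.name = a.res_name
            res_obj.seqid = gemmi.SeqId(a.res_seq, a.icode or " ")
            res_obj.het_flag = "H" if a.record_kind == "HETATM" else "A"
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[-1]
            last_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.coord)
        at.occ = 1.0
        assert res_obj is not None
        res_obj.add_atom(at)
    st.add_model(model)
    st.raw_remarks = [r if r.startswith("REMARK") else f"REMARK 300 {r}" for r in remarks]
    st.write_pdb(str(path))


def extract_monomer(s: StructureModel, chain: str | None = None) -> MonomerRecord:
    """Select the monomer analysed from a (possibly multi-copy) entry.

    Returns the requested chain if given, otherwise the first chain in file
    order that has at least 20 Calpha-bearing standard residues.  HETATM
    residues are excluded; residues without a Calpha are dropped from the
    parallel lists; unknown residue names map to 'X'.
    """
    candidates = [chain] if chain is not None else s.chains
    sizes: dict[str, int] = {}
    for cid in candidates:
        seq_chars: list[str] = []
        coords: list[np.ndarray] = []
        numbers: list[int] = []
        # group this chain's ATOM records by residue, keeping file order
        current: tuple[int, str] | None = None
        res_atoms: list[Atom] = []
        groups: list[list[Atom]] = []
        for a in s.chain_atoms(cid):
            if a.record_kind != "ATOM":
                continue
            key = (a.res_seq, a.icode)
            if key != current:
                if res_atoms:
                    groups.append(res_atoms)
                res_atoms = []
                current = key
            res_atoms.append(a)
        if res_atoms:
            groups.append(res_atoms)
        for group in groups:
            ca = next((a for a in group if a.name.strip() == "CA"
                       and a.element in ("C", "")), None)
            if ca is None:
                continue
            seq_chars.append(THREE_TO_ONE.get(group[0].res_name, "X"))
            coords.append(ca.coord)
            numbers.append(ca.res_seq)
        sizes[cid] = len(seq_chars)
        min_size = 1 if chain is not None else 20
        if len(seq_chars) >= min_size:
            return MonomerRecord(
                source_id=f"{s.id}:{cid}",
                sequence="".join(seq_chars),
                ca_coords=np.array(coords).reshape(-1, 3),
                res_numbers=numbers,
            )
    raise ChainSelectionError(
        f"{s.id}: no qualifying protein chain "
        f"(Calpha residues per chain: {sizes})"
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) preserving file order.

    Sequences are upper-cased and translation stops ('*') stripped.
    Duplicate ids get a numeric suffix with a warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    out: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for rec in records:
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            warnings.warn(f"{path}: duplicate FASTA id {rid!r}; "
                          f"renamed to {rid}_{seen[rid]}")
            rid = f"{rid}_{seen[rid]}"
        else:
            seen[rid] = 0
        out.append((rid, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_table(rows: Sequence[dict], path: str | Path, format: str = "tsv") -> None:
    """Write a list of homogeneous dict rows as TSV (with header) or JSON."""
    path = Path(path)
    if format == "tsv":
        if not rows:
            path.write_text("")
            return
        header = list(rows[0].keys())
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(row[k]) for k in header))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        path.write_text(json.dumps(list(rows), indent=2) + "\n")
    else:
        raise ValueError(f"unsupported table format {format!r}")
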