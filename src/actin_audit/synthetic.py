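"""Synthetic structure and sequence generators.

Every input class the audit pipeline consumes can be generated here with a
stated distribution and a seed: near-identical structure ensembles (small
Gaussian coordinate noise plus optional rigid motions), filament-like
entries made of exact helical symmetry copies, hinge pairs for exercising
the outlier-trimming superposition, geometry-controlled burial fixtures,
and sequence families at a controlled per-site substitution rate.

The backbone model is an ideal Calpha helix (radius 2.3 A, rise 1.5 A per
residue, 100 degrees per residue -- the standard alpha-helix wheel), with
N, C and O placed by fixed local offsets.  This is deliberately simpler
than a Ramachandran-realistic chain: it is sufficient for superposition and
SASA arithmetic, which only see atom positions, and it keeps every
generator a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from actin_audit.structio import Atom, StructureModel, write_structure

__all__ = [
    "EnsembleSpec",
    "FamilySpec",
    "make_backbone",
    "perturb_structure",
    "rigid_copy",
    "make_filament_entry",
    "make_hinge_pair",
    "make_burial_fixture",
    "make_family",
    "make_ensemble",
    "write_ensemble",
]

HELIX_RADIUS = 2.3  # angstrom
HELIX_RISE = 1.5  # angstrom per residue
HELIX_TURN = math.radians(100.0)  # per residue

# canonical F-actin helical parameters, used as filament defaults
FILAMENT_RISE = 27.5  # angstrom per subunit
FILAMENT_TWIST = -166.7  # degrees per subunit

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# local backbone offsets (angstrom) relative to each Calpha, fixed geometry
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, -0.60, -0.50]),
    "C": np.array([1.20, 0.50, 0.55]),
    "O": np.array([1.60, 1.55, 0.30]),
}


@dataclass(slots=True)
class EnsembleSpec:
    """Recipe for a perturbed-structure ensemble."""

    n_structures: int
    n_res: int
    sigma: float  # per-coordinate Gaussian s.d., angstrom
    rigid_motions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_res < 4:
            raise ValueError("n_res must be >= 4")


@dataclass(slots=True)
class FamilySpec:
    """Recipe for a sequence family at a fixed per-site substitution rate."""

    n_sequences: int
    length: int
    subst_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.subst_rate <= 1.0:
            raise ValueError("subst_rate must be in [0, 1]")


def make_backbone(n_res: int, sequence: str | None = None,
                  structure_id: str = "synthetic") -> StructureModel:
    """Ideal-helix backbone trace of ``n_res`` residues (no RNG).

    Calpha atoms lie on a helix of radius 2.3 A, rise 1.5 A/residue and
    100 degrees/residue; N, C and O are added at fixed local offsets.
    Poly-alanine unless ``sequence`` gives 1-letter residue types.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    if sequence is not None and len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    atoms: list[Atom] = []
    serial = 0
    for i in range(n_res):
        theta = i * HELIX_TURN
        ca = np.array([
            HELIX_RADIUS * math.cos(theta),
            HELIX_RADIUS * math.sin(theta),
            HELIX_RISE * i,
        ])
        res_name = ONE_TO_THREE.get(sequence[i].upper(), "ALA") if sequence else "ALA"
        for name in ("N", "CA", "C", "O"):
            serial += 1
            coord = ca if name == "CA" else ca + _BACKBONE_OFFSETS[name]
            atoms.append(Atom(
                serial=serial,
                name=name,
                element=name[0],
                res_name=res_name,
                chain_id="A",
                res_seq=i + 1,
                icode="",
                coord=coord,
                record_kind="ATOM",
            ))
    return StructureModel(id=structure_id, atoms=atoms)


def _replace_coords(s: StructureModel, coords: np.ndarray,
                    new_id: str | None = None) -> StructureModel:
    atoms = [
        Atom(serial=a.serial, name=a.name, element=a.element,
             res_name=a.res_name, chain_id=a.chain_id, res_seq=a.res_seq,
             icode=a.icode, coord=c, record_kind=a.record_kind)
        for a, c in zip(s.atoms, coords)
    ]
    return StructureModel(id=new_id or s.id, atoms=atoms)


def _coords(s: StructureModel) -> np.ndarray:
    return np.array([a.coord for a in s.atoms])


def perturb_structure(s: StructureModel, sigma: float,
                      seed: int = 0) -> StructureModel:
    """Add iid Gaussian noise (s.d. ``sigma`` per coordinate) to every atom."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(s.atoms), 3)) if sigma > 0 else 0.0
    return _replace_coords(s, _coords(s) + noise, new_id=f"{s.id}_p{seed}")


def rigid_copy(s: StructureModel, seed: int = 0) -> StructureModel:
    """Apply a random rotation and a U[-20, 20] A translation (seeded)."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    return _replace_coords(s, _coords(s) @ rot.T + trans,
                           new_id=f"{s.id}_r{seed}")


def make_filament_entry(s: StructureModel, n_copies: int,
                        rise: float = FILAMENT_RISE,
                        twist: float = FILAMENT_TWIST) -> StructureModel:
    """Multi-chain entry of exact helical symmetry copies of one monomer.

    Copy k is the monomer rotated about z by ``k * twist`` degrees and
    translated by ``k * rise`` along z; chains are labelled A, B, C, ...
    Inter-copy RMSD after superposition is exactly zero by construction.
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    chain_labels = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if n_copies > len(chain_labels):
        raise ValueError(f"at most {len(chain_labels)} copies supported")
    base = _coords(s)
    atoms: list[Atom] = []
    serial = 0
    for k in range(n_copies):
        angle = math.radians(twist * k)
        rot = np.array([
            [math.cos(angle), -math.sin(angle), 0.0],
            [math.sin(angle), math.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ])
        coords = base @ rot.T + np.array([0.0, 0.0, rise * k])
        for a, c in zip(s.atoms, coords):
            serial += 1
            atoms.append(Atom(
                serial=serial, name=a.name, element=a.element,
                res_name=a.res_name, chain_id=chain_labels[k],
                res_seq=a.res_seq, icode=a.icode, coord=c,
                record_kind=a.record_kind,
            ))
    return StructureModel(id=f"{s.id}_filament{n_copies}", atoms=atoms)


def make_hinge_pair(s: StructureModel, hinge_res: int,
                    angle: float) -> tuple[StructureModel, StructureModel]:
    """Original structure plus a copy hinged at one residue.

    Residues beyond ``hinge_res`` are rotated by ``angle`` degrees about an
    axis through that residue's Calpha, perpendicular to the helix (z)
    axis.  Exercises outlier trimming: the moved part's deviation grows
    with distance from the hinge.
    """
    res_numbers = sorted({a.res_seq for a in s.atoms})
    if not (res_numbers[3] <= hinge_res <= res_numbers[-4]):
        raise ValueError("hinge_res must leave >= 4 residues on each side")
    hinge_ca = next(a.coord for a in s.atoms
                    if a.res_seq == hinge_res and a.name == "CA")
    rot = Rotation.from_rotvec(np.radians(angle) * np.array([1.0, 0.0, 0.0]))
    coords = _coords(s)
    moved = coords.copy()
    sel = np.array([a.res_seq > hinge_res for a in s.atoms])
    moved[sel] = rot.apply(coords[sel] - hinge_ca) + hinge_ca
    return s, _replace_coords(s, moved, new_id=f"{s.id}_hinge{hinge_res}_{angle:g}")


def make_burial_fixture(n_charged_surface: int, n_charged_core: int,
                        seed: int = 0) -> StructureModel:
    """Pseudo-globule with charged residues placed at designed burial.

    A solid ball of single-atom alanine filler residues (cubic grid,
    1.8 A spacing, radius 8 A) buries anything at its centre; charged
    residues are either three-atom aspartates sticking radially out of the
    surface (fully exposed) or single atoms swapped into grid sites near
    the centre (fully occluded).  The geometry gives each class clearance
    from the 0.5 relative-accessibility threshold.
    """
    if n_charged_surface < 0 or n_charged_core < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    spacing, ball_radius = 1.8, 8.0
    grid = np.arange(-ball_radius, ball_radius + spacing / 2, spacing)
    sites = np.array([[x, y, z] for x in grid for y in grid for z in grid
                      if x * x + y * y + z * z <= ball_radius ** 2])
    order = np.argsort(np.linalg.norm(sites, axis=1), kind="stable")
    sites = sites[order]  # centre-first
    if n_charged_core > len(sites) // 4:
        raise ValueError("too many core residues for the fixture ball")

    atoms: list[Atom] = []
    serial = 0
    res_seq = 0

    def add(res_name: str, coords_list: list[np.ndarray]) -> None:
        nonlocal serial, res_seq
        res_seq += 1
        for k, c in enumerate(coords_list):
            serial += 1
            atoms.append(Atom(
                serial=serial, name=f"C{k + 1}", element="C",
                res_name=res_name, chain_id="A", res_seq=res_seq,
                icode="", coord=c, record_kind="ATOM",
            ))

    # core charged residues occupy the innermost grid sites
    for i in range(n_charged_core):
        add("ASP", [sites[i]])
    # the remaining grid sites are neutral filler
    for site in sites[n_charged_core:]:
        add("ALA", [site])
    # surface charged residues: 3 atoms poking radially outwards
    directions = _fibonacci_directions(max(n_charged_surface, 1), rng)
    for i in range(n_charged_surface):
        d = directions[i]
        add("ASP", [d * (ball_radius + 2.5), d * (ball_radius + 4.5),
                    d * (ball_radius + 6.5)])
    return StructureModel(id=f"burial_s{n_charged_surface}_c{n_charged_core}",
                          atoms=atoms)


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_family(spec: FamilySpec, reference: str | None = None) -> list[str]:
    """Sequence family from one reference at a per-site substitution rate.

    Each site of each sequence is independently replaced, with probability
    ``spec.subst_rate``, by a uniformly random *different* standard residue.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = "".join(rng.choice(list(alphabet), size=spec.length))
    elif len(reference) != spec.length:
        raise ValueError("reference length must equal spec.length")
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    alpha_arr = np.frombuffer(alphabet.encode("ascii"), dtype=np.uint8)

    family: list[str] = []
    for _ in range(spec.n_sequences):
        seq = ref_arr.copy()
        hit = rng.random(spec.length) < spec.subst_rate
        for pos in np.nonzero(hit)[0]:
            choices = alpha_arr[alpha_arr != seq[pos]]
            seq[pos] = rng.choice(choices)
        family.append(seq.tobytes().decode("ascii"))
    return family


def make_ensemble(spec: EnsembleSpec) -> list[StructureModel]:
    """Ensemble of near-identical structures from one ideal backbone.

    Structure k is the base backbone with Gaussian coordinate noise
    (s.d. ``spec.sigma``) and, if ``rigid_motions``, a random rigid motion
    on top -- emulating independently solved depositions of one protein.
    """
    base = make_backbone(spec.n_res, structure_id="ens")
    out: list[StructureModel] = []
    for k in range(spec.n_structures):
        member = perturb_structure(base, spec.sigma, seed=spec.seed * 100_003 + k)
        if spec.rigid_motions:
            member = rigid_copy(member, seed=spec.seed * 100_003 + k)
        member.id = f"ens{k:03d}"
        out.append(member)
    return out


def write_ensemble(spec: EnsembleSpec, out_dir: str | Path) -> list[Path]:
    """Write an ensemble as PDB files plus a JSON manifest of the recipe."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for member in make_ensemble(spec):
        p = out_dir / f"{member.id}.pdb"
        write_structure(member, p, remarks=[f"SYNTHETIC ENSEMBLE SEED {spec.seed}"])
        paths.append(p)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return paths
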