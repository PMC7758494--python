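"""Solvent-accessible surface area and burial classification.

SASA is computed with the Shrake-Rupley method: each heavy atom carries a
deterministic golden-spiral point set on its probe-expanded sphere, a point
counts as exposed if it lies outside every neighbour's expanded sphere, and
the atom's area is the exposed fraction of the full sphere area.  Residue
areas are divided by a per-residue-type maximum (Tien et al. 2013 empirical
values by default) to give relative accessibility; a residue is called
*external* when its relative accessibility is strictly above 0.5, i.e. more
than half of its maximum observed area is solvent-exposed.  Summaries focus
on the charged residue types (Arg, Lys, Glu, Asp), whose burial pattern is
the audit's headline surface statistic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from actin_audit.structio import StructureModel

__all__ = [
    "SASAProfile",
    "BurialSummary",
    "VDW_RADII",
    "CHARGED_RESIDUES",
    "golden_spiral_points",
    "atom_areas",
    "sasa",
    "classify_external",
    "burial_summary",
    "compare_burial",
    "load_max_asa",
]

#: Van der Waals radii (angstrom) used for the expanded spheres.  Elements
#: absent from the table fall back to the "*" default.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "*": 1.80,
}

CHARGED_RESIDUES = ("ARG", "LYS", "GLU", "ASP")


@dataclass(slots=True)
class SASAProfile:
    """Per-residue absolute and relative accessible surface area."""

    residue_ids: list[tuple[str, int, str]]  # (chain, res_seq, res_name)
    asa: np.ndarray  # angstrom^2, >= 0
    rel_asa: np.ndarray | None = None  # asa / max_asa(res_name); NaN if unknown type
    external: np.ndarray | None = None  # bool; meaningless where rel_asa is NaN
    classifiable: np.ndarray | None = None  # False where res type has no max entry

    def __len__(self) -> int:
        return len(self.residue_ids)


@dataclass(slots=True)
class BurialSummary:
    class_name: str
    n_total: int
    n_external: int
    n_buried: int
    fraction_external: float | None  # None when the class is empty

    def as_dict(self) -> dict:
        return {
            "class": self.class_name,
            "n_total": self.n_total,
            "n_external": self.n_external,
            "n_buried": self.n_buried,
            "fraction_external": self.fraction_external,
        }


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Load the per-residue maximum-ASA table (angstrom^2).

    Default is the packaged empirical maximum-accessibility table; any
    two-column TSV (res_name, max_asa) can be substituted.
    """
    if path is None:
        source = resources.files("actin_audit.data").joinpath("max_asa.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        name, value = row[0].strip().upper(), float(row[1])
        if value <= 0:
            raise ValueError(f"max-ASA table: non-positive value for {name}")
        table[name] = value
    return table


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-spiral construction.

    Deterministic (no RNG), so every SASA value is bit-reproducible.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_areas(coords: np.ndarray, radii: np.ndarray,
               probe_radius: float = 1.4,
               n_sphere_points: int = 960) -> np.ndarray:
    """Shrake-Rupley per-atom accessible area (angstrom^2).

    ``radii`` are van der Waals radii; each atom's test sphere has radius
    ``r_vdw + probe_radius``.
    """
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius
    unit = golden_spiral_points(n_sphere_points)

    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neighbours = tree.query_ball_point(coords[i], ri + max_r)
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            rj = expanded[j]
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > rj * rj
            if not exposed.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * exposed.sum() / n_sphere_points
    return areas


def sasa(s: StructureModel, probe_radius: float = 1.4,
         n_sphere_points: int = 960, include_het: bool = False,
         vdw_radii: dict[str, float] | None = None) -> SASAProfile:
    """Per-residue accessible surface area of a structure.

    Hydrogens are ignored.  HETATM records (ligands, ions, waters) are
    excluded from both the surface and the occluding set unless
    ``include_het`` is true, in which case they occlude but are not
    reported as residues.
    """
    radii_table = dict(VDW_RADII if vdw_radii is None else vdw_radii)
    default = radii_table.get("*")

    coords: list[np.ndarray] = []
    radii: list[float] = []
    owner: list[int] = []  # residue index per atom, -1 for het occluders
    residue_ids: list[tuple[str, int, str]] = []
    res_key_to_idx: dict[tuple[str, int, str, str], int] = {}

    for a in s.atoms:
        if a.element in ("H", "D"):
            continue
        if a.record_kind == "HETATM" and not include_het:
            continue
        r = radii_table.get(a.element, default)
        if r is None:
            raise ValueError(f"no van der Waals radius configured for element "
                             f"{a.element!r} (atom {a.serial})")
        coords.append(a.coord)
        radii.append(r)
        if a.record_kind == "HETATM":
            owner.append(-1)
            continue
        key = (a.chain_id, a.res_seq, a.icode, a.res_name)
        if key not in res_key_to_idx:
            res_key_to_idx[key] = len(residue_ids)
            residue_ids.append((a.chain_id, a.res_seq, a.res_name))
        owner.append(res_key_to_idx[key])

    if not coords:
        raise ValueError(f"{s.id}: no heavy atoms to compute SASA for")

    areas = atom_areas(np.array(coords), np.array(radii),
                       probe_radius=probe_radius,
                       n_sphere_points=n_sphere_points)
    res_asa = np.zeros(len(residue_ids))
    for idx, area in zip(owner, areas):
        if idx >= 0:
            res_asa[idx] += area
    return SASAProfile(residue_ids=residue_ids, asa=res_asa)


def classify_external(p: SASAProfile, threshold: float = 0.5,
                      max_table: dict[str, float] | None = None) -> SASAProfile:
    """Fill in relative accessibility and the external/buried calls.

    ``external`` is strict: rel_asa must exceed the threshold ("more than
    50%"), so a residue at exactly the threshold is buried.  Residue types
    missing from the table are flagged not-classifiable and excluded from
    downstream summaries.
    """
    if max_table is None:
        max_table = load_max_asa()
    if any(v <= 0 for v in max_table.values()):
        raise ValueError("max-ASA table contains non-positive values")
    rel = np.full(len(p), np.nan)
    classifiable = np.zeros(len(p), dtype=bool)
    for i, (_, _, res_name) in enumerate(p.residue_ids):
        max_val = max_table.get(res_name.upper())
        if max_val is not None:
            rel[i] = p.asa[i] / max_val
            classifiable[i] = True
    external = np.zeros(len(p), dtype=bool)
    external[classifiable] = rel[classifiable] > threshold
    return SASAProfile(residue_ids=p.residue_ids, asa=p.asa, rel_asa=rel,
                       external=external, classifiable=classifiable)


def burial_summary(p: SASAProfile,
                   classes: dict[str, tuple[str, ...]] | None = None
                   ) -> list[BurialSummary]:
    """External/buried counts per residue class, deterministic row order.

    Default classes: 'all', the pooled 'charged' class, then each charged
    type individually.  Only classifiable residues are counted.
    """
    if p.external is None or p.classifiable is None:
        raise ValueError("profile must be classified first (classify_external)")
    if classes is None:
        classes = {
            "all": (),  # empty tuple = every classifiable residue
            "charged": CHARGED_RESIDUES,
            "Arg": ("ARG",),
            "Lys": ("LYS",),
            "Glu": ("GLU",),
            "Asp": ("ASP",),
        }
    rows: list[BurialSummary] = []
    names = np.array([rid[2].upper() for rid in p.residue_ids])
    for cls, members in classes.items():
        mask = p.classifiable.copy()
        if members:
            mask &= np.isin(names, members)
        n_total = int(mask.sum())
        n_ext = int((p.external & mask).sum())
        rows.append(BurialSummary(
            class_name=cls,
            n_total=n_total,
            n_external=n_ext,
            n_buried=n_total - n_ext,
            fraction_external=(n_ext / n_total) if n_total else None,
        ))
    return rows


def compare_burial(a: list[BurialSummary],
                   b: list[BurialSummary]) -> list[dict]:
    """Per-class difference in external fraction between two structures.

    Rows are matched by class name; a missing class on either side is an
    error.  No statistical test is attached -- this is a descriptive table.
    """
    b_by_name = {row.class_name: row for row in b}
    if set(r.class_name for r in a) != set(b_by_name):
        raise ValueError("burial summaries have mismatched class rows")
    out = []
    for row_a in a:
        row_b = b_by_name[row_a.class_name]
        if row_a.fraction_external is None or row_b.fraction_external is None:
            diff = None
        else:
            diff = row_a.fraction_external - row_b.fraction_external
        out.append({
            "class": row_a.class_name,
            "fraction_external_a": row_a.fraction_external,
            "fraction_external_b": row_b.fraction_external,
            "difference": diff,
        })
    return out
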