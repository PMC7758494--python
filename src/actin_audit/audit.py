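"""End-to-end audit orchestration.

``run_audit`` wires the stages together: parse every structure in a
directory and select its monomer, compute the all-vs-all trimmed-RMSD
matrix and its binning, run the SASA burial audit on the first structure,
score conservation of an optional sequence family, and cross exon against
subdomain definitions.  Stage failures are collected rather than fatal
(an audit of a 30-year heterogeneous ensemble must survive odd entries);
outputs are plain TSV/JSON with the resolved configuration echoed into
every JSON for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from actin_audit import regions as regions_mod
from actin_audit import seqstats, surface
from actin_audit.structio import (
    MonomerRecord,
    read_fasta,
    read_structure,
    extract_monomer,
    write_table,
)
from actin_audit.superpose import all_pairs_rmsd, bin_rmsds

logger = logging.getLogger(__name__)

__all__ = ["AuditConfig", "run_audit"]


@dataclass(slots=True)
class AuditConfig:
    """Resolved configuration of one audit run (fully serialisable)."""

    structure_dir: str | None = None
    fasta_path: str | None = None
    region_path: str | None = None  # None = packaged actin definitions
    chain: str | None = None  # None = first qualifying chain
    trim_cutoff: float = 3.5
    bin_edges: list[float] = field(default_factory=lambda: [0.0, 1.0, 2.0, 3.0])
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    include_het: bool = False
    max_asa_path: str | None = None
    out_dir: str = "audit_out"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_monomers(config: AuditConfig) -> tuple[list[MonomerRecord], list[str]]:
    stage_warnings: list[str] = []
    monomers: list[MonomerRecord] = []
    pdb_files = sorted(Path(config.structure_dir).glob("*.pdb"))
    if not pdb_files:
        raise FileNotFoundError(
            f"no .pdb files in {config.structure_dir!r}")
    for path in pdb_files:
        try:
            monomers.append(extract_monomer(read_structure(path), chain=config.chain))
        except Exception as exc:  # heterogeneous ensembles: collect, don't die
            msg = f"skipped {path.name}: {exc}"
            logger.warning(msg)
            stage_warnings.append(msg)
    return monomers, stage_warnings


def run_audit(config: AuditConfig) -> dict:
    """Run every configured stage; return a summary dict (also written to disk).

    Produces, in ``config.out_dir``: ``matrix.tsv`` and ``bins.json`` for
    the superposition stage, ``burial.json`` and ``profile.tsv`` for the
    surface stage, ``conservation.tsv`` for the sequence stage, and
    ``overlap.tsv`` for the region stage.  Completed stages' outputs are
    kept even when a later stage fails; failures are listed in the summary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
        "failures": {},
    }

    if config.structure_dir is not None:
        _stage(summary, "superpose", _run_superpose, config, out_dir)
        _stage(summary, "surface", _run_surface, config, out_dir)
    if config.fasta_path is not None:
        _stage(summary, "conservation", _run_conservation, config, out_dir)
    _stage(summary, "regions", _run_regions, config, out_dir)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=_jsonable) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _stage(summary: dict, name: str, fn, config: AuditConfig, out_dir: Path) -> None:
    t0 = time.perf_counter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = fn(config, out_dir)
        summary["warnings"] += [f"{name}: {w.message}" for w in caught]
        summary["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            **result,
        }
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        summary["failures"][name] = str(exc)
        summary["stages"][name] = {
            "status": "failed",
            "seconds": round(time.perf_counter() - t0, 3),
        }


def _run_superpose(config: AuditConfig, out_dir: Path) -> dict:
    monomers, stage_warnings = _load_monomers(config)
    if len(monomers) < 2:
        raise ValueError(f"need >= 2 parseable structures, got {len(monomers)}")
    matrix = all_pairs_rmsd(monomers, trim_cutoff=config.trim_cutoff)
    bins = bin_rmsds(matrix, edges=config.bin_edges)

    lines = ["id\t" + "\t".join(matrix.ids)]
    for i, rid in enumerate(matrix.ids):
        lines.append(rid + "\t" + "\t".join(f"{v:.4f}" for v in matrix.values[i]))
    (out_dir / "matrix.tsv").write_text("\n".join(lines) + "\n")

    bins_out = {"config": config.to_dict(), **bins,
                "n_structures": len(monomers), "skipped": stage_warnings}
    (out_dir / "bins.json").write_text(json.dumps(bins_out, indent=2) + "\n")
    return {"n_structures": len(monomers), "n_pairs": bins["n_pairs"],
            "bin_counts": bins["counts"], "max_rmsd": bins["max_rmsd"]}


def _run_surface(config: AuditConfig, out_dir: Path) -> dict:
    structure = None
    for path in sorted(Path(config.structure_dir).glob("*.pdb")):
        try:
            structure = read_structure(path)
            break
        except Exception as exc:
            warnings.warn(f"surface stage skipped {path.name}: {exc}")
    if structure is None:
        raise ValueError(f"no parseable structure in {config.structure_dir!r}")
    max_table = surface.load_max_asa(config.max_asa_path)
    profile = surface.classify_external(
        surface.sasa(structure, probe_radius=config.probe_radius,
                     n_sphere_points=config.n_sphere_points,
                     include_het=config.include_het),
        max_table=max_table,
    )
    rows = [
        {"chain": cid, "res_seq": num, "res_name": name,
         "asa_A2": round(float(profile.asa[i]), 3),
         "rel_asa": round(float(profile.rel_asa[i]), 4)
         if np.isfinite(profile.rel_asa[i]) else "NA",
         "external": bool(profile.external[i])}
        for i, (cid, num, name) in enumerate(profile.residue_ids)
    ]
    write_table(rows, out_dir / "profile.tsv", format="tsv")
    rows_summary = [s.as_dict() for s in surface.burial_summary(profile)]
    (out_dir / "burial.json").write_text(json.dumps(
        {"config": config.to_dict(), "structure": structure.id,
         "classes": rows_summary}, indent=2) + "\n")
    charged = next(r for r in rows_summary if r["class"] == "charged")
    return {"structure": structure.id, "n_residues": len(profile),
            "charged_fraction_external": charged["fraction_external"]}


def _run_conservation(config: AuditConfig, out_dir: Path) -> dict:
    records = read_fasta(config.fasta_path)
    seqs = [s for _, s in records]
    msa = seqs if len({len(s) for s in seqs}) == 1 else seqstats.star_align(seqs)
    profile = seqstats.column_conservation(msa)
    rows = [
        {"column_index": i + 1,
         "score": round(float(profile.column_scores[i]), 4),
         "gap_fraction": round(float(profile.gap_fractions[i]), 4)}
        for i in range(len(profile))
    ]
    write_table(rows, out_dir / "conservation.tsv", format="tsv")
    return {"n_sequences": profile.n_sequences, "n_columns": len(profile),
            "mean_score": float(profile.column_scores.mean())}


def _run_regions(config: AuditConfig, out_dir: Path) -> dict:
    if config.region_path is not None:
        groups = regions_mod.load_region_file(config.region_path)
    else:
        groups = regions_mod.actin_default_regions()
    exons = groups.get("exons", [])
    subdomains = groups.get("subdomains", [])
    report = regions_mod.overlap_report(exons, subdomains)
    report.to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
    flagged = report[report["corresponds"]]
    return {
        "n_pairs": len(report),
        "n_corresponding": int(report["corresponds"].sum()),
        "corresponding": [f"{r.exon}->{r.subdomain}"
                          for r in flagged.itertuples()],
    }
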