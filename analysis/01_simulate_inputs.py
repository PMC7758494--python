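#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes to scratch/synthetic/ (bulky PDB/FASTA, regenerable at will):
  ensemble/   20 near-identical structures (60 residues, sigma 0.3 A noise,
              random rigid motions) standing in for independently solved
              depositions of one protein
  filament.pdb  a 3-copy helical-symmetry entry (rise 27.5 A, twist -166.7
              degrees, the canonical actin filament parameters)
  family.fasta  50 sequences of length 375 at per-site substitution rate
              25/375 -- the <= 25-substitution divergence scale of actin
  burial_*.pdb  pseudo-globules with charged residues at designed burial
"""

from pathlib import Path

from actin_audit import synthetic as syn
from actin_audit.structio import write_fasta, write_structure

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "scratch" / "synthetic"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = syn.EnsembleSpec(n_structures=20, n_res=60, sigma=0.3, seed=SEED)
    paths = syn.write_ensemble(spec, OUT / "ensemble")
    print(f"ensemble: {len(paths)} structures, {spec.n_res} residues, "
          f"sigma {spec.sigma} A -> {OUT / 'ensemble'}")

    filament = syn.make_filament_entry(syn.make_backbone(40), n_copies=3)
    write_structure(filament, OUT / "filament.pdb",
                    remarks=[f"SYNTHETIC FILAMENT SEED {SEED}"])
    print(f"filament: 3 helical copies of a 40-residue monomer -> filament.pdb")

    family = syn.make_family(
        syn.FamilySpec(n_sequences=50, length=375, subst_rate=25 / 375,
                       seed=SEED))
    write_fasta([(f"seq{i:03d}", s) for i, s in enumerate(family)],
                OUT / "family.fasta")
    print(f"family: 50 sequences, length 375, rate 25/375 -> family.fasta")

    for n_surface, n_core in ((6, 2), (2, 6)):
        fx = syn.make_burial_fixture(n_surface, n_core, seed=SEED)
        write_structure(fx, OUT / f"{fx.id}.pdb",
                        remarks=[f"SYNTHETIC BURIAL SEED {SEED}"])
        print(f"burial fixture: {n_surface} surface / {n_core} core charged "
              f"residues -> {fx.id}.pdb")


if __name__ == "__main__":
    main()
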