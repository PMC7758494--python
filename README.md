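# actin-audit

Structural audit of a single-protein structure ensemble.

## The problem

When one protein has been solved hundreds of times over decades — the
motivating case is skeletal-muscle α-actin, with ~155 PDB depositions of the
rabbit protein between 1991 and 2020 — it is worth asking what all those
depositions actually add. This package implements the audit that answers
that question at desk scale:

* **Ensemble homogeneity.** Every unordered pair of monomers is superposed
  by the Kabsch/SVD solution after residue correspondence by global
  sequence alignment, with iterative trimming of pairs deviating > 3.5 Å;
  the RMSD distribution is binned per 1 Å band. For a 154-member ensemble
  that is n(n−1)/2 = 11,781 pairs.
* **Surface burial of charges.** Shrake–Rupley solvent-accessible surface
  area (probe 1.4 Å, deterministic golden-spiral quadrature), relative
  accessibility against a per-residue-type maximum table, and the rule that
  a residue is *external* iff its relative accessibility exceeds 0.5 —
  applied to the charged types Arg/Lys/Glu/Asp, whose burial pattern is the
  audit's headline surface statistic.
* **Sequence statistics.** Net charge (+1 per Arg/Lys, −1 per Glu/Asp, His
  neutral: 18 R + 19 K − 28 E − 22 D = **−13** for α-actin), composition
  enrichment against a proteome-wide reference, and per-column conservation
  (modal-residue fraction) of a star-aligned family.
* **Exon → subdomain mapping.** Containment and Jaccard of every exon
  segment against every structural subdomain; containment ≥ 0.95 flags a
  correspondence. On the canonical α-actin ranges exactly two pairs are
  flagged: exon IV (205–269) ⊂ subdomain 4 (181–269) and exon V (270–329)
  ⊂ subdomain 3 (145–180, 270–337).

A synthetic-data module generates every input class — perturbed ensembles,
helical-symmetry filament entries, hinge pairs, designed-burial globules,
and sequence families at a controlled substitution rate — so the full
pipeline runs and is verified without any downloads.

## Worked example

```python
from actin_audit import (all_pairs_rmsd, bin_rmsds, extract_monomer,
                         charge_inventory, synthetic as syn)

# 20 near-identical structures: 60 residues, 0.3 A coordinate noise
ens = syn.make_ensemble(syn.EnsembleSpec(20, 60, sigma=0.3, seed=8))
bins = bin_rmsds(all_pairs_rmsd([extract_monomer(s, "A") for s in ens]))
print(bins["n_pairs"], bins["counts"], round(bins["max_rmsd"], 3))
# 190 [190, 0, 0] 0.859

inv = charge_inventory("R"*18 + "K"*19 + "E"*28 + "D"*22 + "A"*288)
print(inv.net_charge, round(inv.charged_fraction, 3))
# -13 0.232
```

All 190 pairs of the ensemble land in the 0–1 Å bin (independently
perturbing each coordinate by σ = 0.3 Å makes the expected pairwise RMSD
σ√6 ≈ 0.73 Å), and the charge inventory of a chain with α-actin's printed
residue counts reproduces the net charge of −13 with a charged fraction of
87/375 = 0.232.

The same stages are exposed as numbered drivers under `analysis/`
(01 simulate → 05 exon map; each prints its finding and writes tables under
`results/`) and as a CLI:

```bash
actin-audit simulate ensemble --n 20 --n-res 60 --sigma 0.3 --out scratch/ens
actin-audit superpose-all --in scratch/ens --out audit_out
actin-audit audit --in scratch/ens --out audit_out   # every stage at once
```

## Layout

```
src/actin_audit/    library: structio, superpose, surface, seqstats,
                    regions, synthetic, audit, cli (+ packaged data tables)
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
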