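#!/usr/bin/env python
"""All-vs-all trimmed Calpha RMSD over the synthetic ensemble.

Reads scratch/synthetic/ensemble/ (run 01_simulate_inputs.py first),
superposes every unordered pair, bins the RMSD distribution per 1-A band
and reports how tightly the ensemble clusters -- the synthetic analogue of
asking whether 30 years of depositions of one protein actually differ.

Writes results/rmsd_bins.json and results/rmsd_matrix.tsv.
"""

import json
from pathlib import Path

from actin_audit import all_pairs_rmsd, bin_rmsds, extract_monomer, read_structure

ROOT = Path(__file__).resolve().parent.parent
ENSEMBLE = ROOT / "scratch" / "synthetic" / "ensemble"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    monomers = [extract_monomer(read_structure(p))
                for p in sorted(ENSEMBLE.glob("*.pdb"))]
    print(f"parsed {len(monomers)} monomers "
          f"({monomers[0].sequence[:10]}..., {len(monomers[0])} residues)")

    matrix = all_pairs_rmsd(monomers)
    bins = bin_rmsds(matrix)

    lines = ["id\t" + "\t".join(matrix.ids)]
    for i, rid in enumerate(matrix.ids):
        lines.append(rid + "\t" + "\t".join(f"{v:.4f}" for v in matrix.values[i]))
    (RESULTS / "rmsd_matrix.tsv").write_text("\n".join(lines) + "\n")
    (RESULTS / "rmsd_bins.json").write_text(json.dumps(bins, indent=2) + "\n")

    print(f"evaluated {bins['n_pairs']} pairs; "
          f"bins {bins['edges']}: {bins['counts']} "
          f"(overflow {bins['overflow']}, missing {bins['n_missing']})")
    print(f"max RMSD {bins['max_rmsd']:.3f} A, median {bins['median_rmsd']:.3f} A")
    if bins["max_rmsd"] < 1.0:
        print("finding: the ensemble is structurally homogeneous -- every "
              "pair falls in the 0-1 A band, as expected for per-coordinate "
              "noise of 0.3 A")


if __name__ == "__main__":
    main()
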