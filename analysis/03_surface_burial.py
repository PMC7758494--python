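#!/usr/bin/env python
"""SASA burial audit of the designed-burial fixtures and one ensemble member.

For each structure: Shrake-Rupley SASA at probe 1.4 A, relative
accessibility against the per-residue maximum table, external = rel > 0.5,
then external/buried counts per charged class.  The two fixtures have
charged residues placed at designed burial (6 surface / 2 core and the
reverse), so the recovered fractions demonstrate that the classification
resolves the geometry it is meant to measure.

Writes results/burial_audit.json.
"""

import json
from pathlib import Path

from actin_audit import (
    burial_summary,
    classify_external,
    compare_burial,
    read_structure,
    sasa,
)

ROOT = Path(__file__).resolve().parent.parent
SYNTH = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"


def audit(path: Path) -> list:
    profile = classify_external(sasa(read_structure(path)))
    rows = burial_summary(profile)
    charged = next(r for r in rows if r.class_name == "charged")
    frac = ("undefined" if charged.fraction_external is None
            else f"{charged.fraction_external:.2f}")
    print(f"{path.name}: {len(profile)} residues, charged external "
          f"fraction {frac}")
    return rows


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    surface_heavy = audit(SYNTH / "burial_s6_c2.pdb")
    core_heavy = audit(SYNTH / "burial_s2_c6.pdb")
    member = audit(sorted((SYNTH / "ensemble").glob("*.pdb"))[0])

    table = compare_burial(surface_heavy, core_heavy)
    diff = next(r for r in table if r["class"] == "charged")["difference"]
    print(f"designed burial contrast recovered: charged external fraction "
          f"differs by {diff:+.2f} (designed +0.50)")

    out = {
        "burial_s6_c2": [r.as_dict() for r in surface_heavy],
        "burial_s2_c6": [r.as_dict() for r in core_heavy],
        "ensemble_member": [r.as_dict() for r in member],
        "designed_contrast": table,
    }
    (RESULTS / "burial_audit.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
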