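"""Named residue-range bookkeeping: exons, subdomains, loops, residue sets.

All ranges are 1-based inclusive on the mature-chain coordinate (the
convention used throughout the actin literature); an integer offset can be
applied when projecting onto a structure whose author numbering is shifted
(His-tags, cleaved initiators).  The module's main product is the
exon-by-subdomain overlap table: for every pair it reports the containment
fraction and Jaccard index and flags pairs whose containment reaches the
"corresponds" threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegionSet",
    "containment",
    "jaccard",
    "overlap_report",
    "residues_in_set",
    "load_region_file",
    "actin_default_regions",
    "CORRESPONDS_THRESHOLD",
]

#: Containment at or above this flags an exon as "corresponding" to a subdomain.
CORRESPONDS_THRESHOLD = 0.95


@dataclass(slots=True)
class RegionSet:
    """A named set of 1-based inclusive residue ranges."""

    name: str
    ranges: list[tuple[int, int]]
    offset: int = 0

    def __post_init__(self) -> None:
        norm: list[tuple[int, int]] = []
        for start, end in sorted(self.ranges):
            if start > end:
                raise ValueError(f"{self.name}: range {start}-{end} has start > end")
            if norm and start <= norm[-1][1] + 1:
                norm[-1] = (norm[-1][0], max(norm[-1][1], end))
            else:
                norm.append((start, end))
        self.ranges = norm

    @classmethod
    def from_string(cls, name: str, spec: str, offset: int = 0) -> "RegionSet":
        """Parse '205-269' or '1-32,70-144,338-372' (single residues allowed)."""
        ranges = []
        for part in spec.split(","):
            part = part.strip()
            if not part:
                continue
            if "-" in part:
                lo, hi = part.split("-")
                ranges.append((int(lo), int(hi)))
            else:
                ranges.append((int(part), int(part)))
        return cls(name=name, ranges=ranges, offset=offset)

    def residues(self) -> frozenset[int]:
        """Member residues on the mature-chain coordinate (offset applied)."""
        out: set[int] = set()
        for start, end in self.ranges:
            out.update(range(start + self.offset, end + self.offset + 1))
        return frozenset(out)

    def __len__(self) -> int:
        return sum(end - start + 1 for start, end in self.ranges)


def containment(a: RegionSet, b: RegionSet) -> float | None:
    """Fraction of residues of ``a`` that lie in ``b``; None if ``a`` empty."""
    ra = a.residues()
    if not ra:
        return None
    return len(ra & b.residues()) / len(ra)


def jaccard(a: RegionSet, b: RegionSet) -> float | None:
    """|intersection| / |union|; None when both sets are empty."""
    ra, rb = a.residues(), b.residues()
    union = ra | rb
    if not union:
        return None
    return len(ra & rb) / len(union)


def overlap_report(exons: list[RegionSet], subdomains: list[RegionSet],
                   corresponds_threshold: float = CORRESPONDS_THRESHOLD
                   ) -> pd.DataFrame:
    """Containment and Jaccard for every exon x subdomain pair.

    Exon-major row order; the ``corresponds`` flag marks containment at or
    above the threshold.
    """
    rows = []
    for exon in exons:
        for sub in subdomains:
            c = containment(exon, sub)
            rows.append({
                "exon": exon.name,
                "subdomain": sub.name,
                "containment": c,
                "jaccard": jaccard(exon, sub),
                "corresponds": (c is not None and c >= corresponds_threshold),
            })
    return pd.DataFrame(rows, columns=["exon", "subdomain", "containment",
                                       "jaccard", "corresponds"])


def residues_in_set(seq_len: int, region: RegionSet) -> np.ndarray:
    """Boolean membership mask of length ``seq_len`` (index 0 = residue 1)."""
    mask = np.zeros(seq_len, dtype=bool)
    for start, end in region.ranges:
        lo, hi = start + region.offset, end + region.offset
        if lo < 1 or hi > seq_len:
            raise ValueError(
                f"{region.name}: range {start}-{end} (offset {region.offset}) "
                f"falls outside 1..{seq_len}"
            )
        mask[lo - 1:hi] = True
    return mask


def load_region_file(path: str | Path) -> dict[str, list[RegionSet]]:
    """Load grouped region definitions from a YAML file.

    Layout: top-level group names (e.g. exons, subdomains) mapping region
    names to range strings; an optional top-level ``offset`` integer applies
    to every region.
    """
    data = yaml.safe_load(Path(path).read_text())
    offset = int(data.pop("offset", 0))
    groups: dict[str, list[RegionSet]] = {}
    for group, entries in data.items():
        groups[group] = [
            RegionSet.from_string(name, spec, offset=offset)
            for name, spec in entries.items()
        ]
    return groups


def actin_default_regions() -> dict[str, list[RegionSet]]:
    """The packaged alpha-actin exon/subdomain/loop definitions."""
    from importlib import resources
    with resources.as_file(
        resources.files("actin_audit.data").joinpath("actin_regions.yaml")
    ) as p:
        return load_region_file(p)
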