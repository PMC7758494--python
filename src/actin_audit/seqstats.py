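"""Sequence-level statistics for a near-identical protein family.

Covers the charge bookkeeping of a single chain (net charge at neutral pH
with His treated as neutral), amino-acid composition enrichment against a
proteome-wide reference, star multiple alignment of a family against one
reference sequence, and per-column conservation scoring of the resulting
alignment.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from actin_audit.superpose import align_sequences

__all__ = [
    "ChargeInventory",
    "CompositionProfile",
    "ConservationProfile",
    "STANDARD_AA",
    "charge_inventory",
    "find_residue_positions",
    "composition_enrichment",
    "star_align",
    "column_conservation",
    "load_reference_composition",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

POSITIVE = "RK"
NEGATIVE = "DE"


@dataclass(slots=True)
class ChargeInventory:
    """Counts and positions of the four charged residue types.

    Net charge is the simple integer convention: +1 per Arg/Lys, -1 per
    Glu/Asp, His and the termini neutral.
    """

    n_arg: int
    n_lys: int
    n_glu: int
    n_asp: int
    length: int
    positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def net_charge(self) -> int:
        return (self.n_arg + self.n_lys) - (self.n_glu + self.n_asp)

    @property
    def n_charged(self) -> int:
        return self.n_arg + self.n_lys + self.n_glu + self.n_asp

    @property
    def charged_fraction(self) -> float:
        return self.n_charged / self.length if self.length else 0.0


@dataclass(slots=True)
class CompositionProfile:
    counts: dict[str, int]
    frequencies: dict[str, float]
    enrichment: dict[str, float]  # frequency / reference frequency


@dataclass(slots=True)
class ConservationProfile:
    column_scores: np.ndarray  # fraction in [0, 1] per column
    gap_fractions: np.ndarray
    n_sequences: int

    def __len__(self) -> int:
        return len(self.column_scores)


def charge_inventory(seq: str) -> ChargeInventory:
    """Charged-residue inventory of a 1-letter sequence, positions 1-based."""
    seq = seq.upper()
    positions: dict[str, list[int]] = {aa: [] for aa in "RKED"}
    for i, aa in enumerate(seq, start=1):
        if aa in positions:
            positions[aa].append(i)
    return ChargeInventory(
        n_arg=len(positions["R"]),
        n_lys=len(positions["K"]),
        n_glu=len(positions["E"]),
        n_asp=len(positions["D"]),
        length=len(seq),
        positions=positions,
    )


def find_residue_positions(seq: str, residue: str) -> list[int]:
    """1-based positions of ``residue`` in ``seq`` (strictly increasing)."""
    residue = residue.upper()
    return [i for i, aa in enumerate(seq.upper(), start=1) if aa == residue]


def load_reference_composition(path: str | Path | None = None) -> dict[str, float]:
    """Reference per-type frequencies; packaged human-proteome table by default."""
    if path is None:
        text = resources.files("actin_audit.data").joinpath(
            "proteome_composition.tsv").read_text()
    else:
        text = Path(path).read_text()
    freqs: dict[str, float] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        freqs[row[0].strip().upper()] = float(row[1])
    total = sum(freqs.values())
    if not 0.9 < total < 1.1:
        raise ValueError(f"reference composition sums to {total:.4f}, not ~1")
    return {aa: v / total for aa, v in freqs.items()}


def composition_enrichment(seq: str,
                           reference: dict[str, float] | None = None
                           ) -> CompositionProfile:
    """Per-type frequency of ``seq`` relative to a reference composition.

    The reference must have positive frequencies for all 20 standard types
    summing to 1 (checked to 1e-6).  Letters outside the standard alphabet
    are pooled as 'X' (frequency reported, enrichment undefined).
    """
    if reference is None:
        reference = load_reference_composition()
    missing = [aa for aa in STANDARD_AA if reference.get(aa, 0) <= 0]
    if missing:
        raise ValueError(f"reference lacks positive frequencies for {missing}")
    ref_sum = sum(reference[aa] for aa in STANDARD_AA)
    if abs(ref_sum - 1.0) > 1e-6:
        raise ValueError(f"reference frequencies sum to {ref_sum!r}, not 1")

    seq = seq.upper()
    raw = Counter(seq)
    counts = {aa: raw.get(aa, 0) for aa in STANDARD_AA}
    counts["X"] = len(seq) - sum(counts.values())
    total = len(seq)
    frequencies = {aa: (c / total if total else 0.0) for aa, c in counts.items()}
    enrichment = {aa: frequencies[aa] / reference[aa] for aa in STANDARD_AA}
    return CompositionProfile(counts=counts, frequencies=frequencies,
                              enrichment=enrichment)


def star_align(family: list[str], reference_index: int = 0,
               identity_floor: float = 0.5) -> list[str]:
    """Star multiple alignment: every sequence aligned to one reference.

    Each family member is globally aligned to the reference with
    :func:`align_sequences`; insertion columns relative to the reference are
    merged by reference position (taking the maximum insertion length at
    each position over the family), giving equal-length rows padded with
    '-'.  Deterministic.  Sequences below the pairwise identity floor are
    aligned anyway, with a warning.
    """
    if not family:
        return []
    ref = family[reference_index]
    n_ref = len(ref)

    # per-sequence: gapped reference insertions and the aligned row pieces
    aligned: list[tuple[list[str], list[str]]] = []
    for idx, seq in enumerate(family):
        if idx == reference_index:
            aligned.append(([""] * (n_ref + 1), list(ref)))
            continue
        corr = align_sequences(ref, seq)
        ident = sum(ref[i] == seq[j] for i, j in corr.pairs)
        if n_ref and ident / min(n_ref, len(seq)) < identity_floor:
            warnings.warn(f"sequence {idx} is below {identity_floor:.0%} identity "
                          "to the reference; star alignment may be unreliable")
        # walk the implied alignment: ins[k] = residues of seq inserted
        # before reference position k (0..n_ref)
        ins = [""] * (n_ref + 1)
        row = ["-"] * n_ref
        prev_i, prev_j = -1, -1
        for i, j in corr.pairs:
            ins[i] += seq[prev_j + 1:j]  # unpaired seq residues -> insertion
            row[i] = seq[j]
            prev_i, prev_j = i, j
        ins[n_ref] += seq[prev_j + 1:]
        aligned.append((ins, row))

    # merged insertion length before each reference position
    ins_len = [max(len(a[0][k]) for a in aligned) for k in range(n_ref + 1)]

    rows: list[str] = []
    for ins, row in aligned:
        parts: list[str] = []
        for k in range(n_ref):
            parts.append(ins[k].ljust(ins_len[k], "-"))
            parts.append(row[k])
        parts.append(ins[n_ref].ljust(ins_len[n_ref], "-"))
        rows.append("".join(parts))
    return rows


def column_conservation(msa: list[str]) -> ConservationProfile:
    """Modal-residue fraction per column of an MSA.

    Score = count of the most common non-gap residue over the count of
    non-gap entries; an all-gap column scores 0 with gap fraction 1.
    """
    if len(msa) < 2:
        raise ValueError("need >= 2 aligned sequences")
    lengths = {len(row) for row in msa}
    if len(lengths) != 1:
        raise ValueError(f"ragged MSA rows: lengths {sorted(lengths)}")
    n_cols = lengths.pop()
    n_rows = len(msa)
    scores = np.zeros(n_cols)
    gaps = np.zeros(n_cols)
    for c in range(n_cols):
        column = [row[c] for row in msa]
        non_gap = [ch for ch in column if ch != "-"]
        gaps[c] = 1.0 - len(non_gap) / n_rows
        if non_gap:
            scores[c] = Counter(non_gap).most_common(1)[0][1] / len(non_gap)
    return ConservationProfile(column_scores=scores, gap_fractions=gaps,
                               n_sequences=n_rows)
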