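"""Rigid-body superposition and ensemble RMSD statistics.

The correspondence between two monomers is established by global sequence
alignment (the ensembles this package targets are near-identical in
sequence), the optimal rotation comes from the Kabsch/SVD solution, and the
reported RMSD is computed after iteratively discarding residue pairs that
deviate beyond a cutoff -- so the headline number describes the conserved
core, with the discarded fraction reported alongside it as
``fraction_aligned``.  ``all_pairs_rmsd`` applies this to every unordered
pair of an ensemble and ``bin_rmsds`` summarises the distribution the way
ensemble audits usually present it (counts per 1-angstrom band).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from actin_audit.structio import MonomerRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CorrespondenceMap",
    "SuperpositionResult",
    "RMSDMatrix",
    "DegenerateGeometryError",
    "TrimCollapseError",
    "align_sequences",
    "kabsch",
    "trimmed_superpose",
    "all_pairs_rmsd",
    "bin_rmsds",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear points; no unique rigid superposition exists."""


class TrimCollapseError(RuntimeError):
    """Trimming removed so many pairs that fewer than 3 remain."""

    def __init__(self, msg: str, last_result: "SuperpositionResult | None" = None):
        super().__init__(msg)
        self.last_result = last_result


@dataclass(slots=True)
class CorrespondenceMap:
    """Residue correspondence from a global alignment.

    ``pairs`` holds 0-based index pairs into the two monomers' parallel
    lists; only match/mismatch columns appear (gap columns are excluded), so
    indices are strictly increasing in both coordinates.
    """

    pairs: list[tuple[int, int]]
    score: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(slots=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector (angstrom)
    rmsd: float  # angstrom, over the retained pair set
    n_aligned: int
    fraction_aligned: float
    n_iterations: int = 1

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


@dataclass(slots=True)
class RMSDMatrix:
    """Symmetric all-vs-all RMSD matrix with matching aligned fractions.

    Failed pairs are NaN in both matrices and listed in ``missing``.
    """

    ids: list[str]
    values: np.ndarray
    fractions: np.ndarray
    missing: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        n = len(self.ids)
        return n * (n - 1) // 2

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def align_sequences(a: str, b: str, match: int = 1, mismatch: int = -1,
                    gap: int = -2) -> CorrespondenceMap:
    """Global (Needleman-Wunsch) alignment with a linear gap penalty.

    Traceback ties are broken deterministically: diagonal over a-gap ("up")
    over b-gap ("left").  Returns only the match/mismatch columns as index
    pairs.  Empty input yields an empty map with score 0.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return CorrespondenceMap(pairs=[], score=0)

    a_arr = np.frombuffer(a.encode("latin-1"), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode("latin-1"), dtype=np.uint8)
    sub = np.where(a_arr[:, None] == b_arr[None, :], match, mismatch)

    score = np.empty((n + 1, m + 1), dtype=np.int64)
    # pointer codes: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        row = score[i]
        prev = score[i - 1]
        # vectorising the column recurrence is impossible (each cell depends
        # on its left neighbour), so walk the row in python
        left = row[0]
        for j in range(1, m + 1):
            d = diag[j - 1]
            u = prev[j] + gap
            l = left + gap
            # preference diag > up > left on ties
            if d >= u and d >= l:
                best, code = d, 0
            elif u >= l:
                best, code = u, 1
            else:
                best, code = l, 2
            row[j] = best
            ptr[i, j] = code
            left = best

    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        code = ptr[i, j]
        if code == 0:
            i -= 1
            j -= 1
            pairs.append((i, j))
        elif code == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return CorrespondenceMap(pairs=pairs, score=int(score[n, m]))


def kabsch(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    """Least-RMSD proper rotation and translation mapping ``p`` onto ``q``.

    Centroids are aligned, the covariance matrix is decomposed by SVD, and
    the sign of the smallest singular vector is corrected so the rotation is
    proper (det = +1).  Requires >= 3 non-collinear point pairs.
    """
    p = np.asarray(p, dtype=float).reshape(-1, 3)
    q = np.asarray(q, dtype=float).reshape(-1, 3)
    if p.shape != q.shape:
        raise ValueError(f"point sets differ in length: {p.shape[0]} vs {q.shape[0]}")
    n = p.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 point pairs, got {n}")

    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2 or np.linalg.matrix_rank(q0, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set; rotation not unique")

    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = qc - rotation @ pc

    diff = p0 @ rotation.T - q0
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        n_aligned=n,
        fraction_aligned=1.0,
        n_iterations=1,
    )


def trimmed_superpose(a: MonomerRecord, b: MonomerRecord,
                      trim_cutoff: float = 3.5,
                      max_iter: int = 10) -> SuperpositionResult:
    """Iterative superposition that discards outlier residue pairs.

    Correspondence comes from :func:`align_sequences`.  Each round refits
    the Kabsch solution on the retained pairs and drops pairs whose post-fit
    deviation exceeds ``trim_cutoff`` (angstrom); iteration stops when the
    retained set is stable or after ``max_iter`` rounds.  The reported RMSD
    covers the retained set only; ``fraction_aligned`` is retained count
    over the shorter chain length.
    """
    corr = align_sequences(a.sequence, b.sequence)
    if len(corr) < 3:
        raise DegenerateGeometryError(
            f"{a.source_id} vs {b.source_id}: alignment yields "
            f"{len(corr)} paired residues (< 3)"
        )
    ia = np.array([i for i, _ in corr.pairs])
    ib = np.array([j for _, j in corr.pairs])
    pa = a.ca_coords[ia]
    pb = b.ca_coords[ib]

    denom = min(len(a), len(b))
    keep = np.ones(len(corr), dtype=bool)
    result: SuperpositionResult | None = None
    for iteration in range(1, max_iter + 1):
        if keep.sum() < 3:
            raise TrimCollapseError(
                f"{a.source_id} vs {b.source_id}: trimming left "
                f"{int(keep.sum())} pairs (< 3)",
                last_result=result,
            )
        fit = kabsch(pa[keep], pb[keep])
        dev = np.linalg.norm(pa @ fit.rotation.T + fit.translation - pb, axis=1)
        # every pair is re-tested against the current fit, so pairs trimmed
        # in an early round can re-enter once the fit settles on the core;
        # if no pair is inside the cutoff yet (large-amplitude motion), only
        # the worst decile of the current set is shed, so the fit walks
        # gradually toward the most self-consistent rigid core
        new_keep = dev <= trim_cutoff
        if new_keep.sum() < 3:
            new_keep = keep & (dev <= np.quantile(dev[keep], 0.9))
        result = SuperpositionResult(
            rotation=fit.rotation,
            translation=fit.translation,
            rmsd=fit.rmsd,
            n_aligned=int(keep.sum()),
            fraction_aligned=float(keep.sum()) / denom,
            n_iterations=iteration,
        )
        if np.array_equal(new_keep, keep):
            return result
        keep = new_keep
    return result  # max_iter reached; report the last fit


def all_pairs_rmsd(monomers: list[MonomerRecord],
                   trim_cutoff: float = 3.5,
                   max_iter: int = 10) -> RMSDMatrix:
    """Trimmed superposition over every unordered pair of an ensemble.

    Pairs that fail (alignment too short, trim collapse) are recorded as
    NaN with a logged warning rather than aborting the batch.
    """
    n = len(monomers)
    if n < 2:
        raise ValueError("need at least 2 monomers")
    ids = [m.source_id for m in monomers]
    values = np.zeros((n, n))
    fractions = np.ones((n, n))
    missing: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = trimmed_superpose(monomers[i], monomers[j],
                                        trim_cutoff=trim_cutoff,
                                        max_iter=max_iter)
                values[i, j] = values[j, i] = res.rmsd
                fractions[i, j] = fractions[j, i] = res.fraction_aligned
            except (DegenerateGeometryError, TrimCollapseError) as exc:
                logger.warning("pair (%s, %s) failed: %s", ids[i], ids[j], exc)
                warnings.warn(f"pair ({ids[i]}, {ids[j]}) failed: {exc}")
                values[i, j] = values[j, i] = np.nan
                fractions[i, j] = fractions[j, i] = np.nan
                missing.append((ids[i], ids[j]))
    return RMSDMatrix(ids=ids, values=values, fractions=fractions, missing=missing)


def bin_rmsds(m: RMSDMatrix, edges: list[float] | None = None) -> dict:
    """Histogram the upper-triangle RMSDs into half-open bins [lo, hi).

    Values at or beyond the last edge land in ``overflow``.  Counts, missing
    pairs and overflow always sum to n(n-1)/2.
    """
    if edges is None:
        edges = [0.0, 1.0, 2.0, 3.0]
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    tri = m.upper_triangle()
    finite = tri[np.isfinite(tri)]
    counts = []
    for lo, hi in zip(edges, edges[1:]):
        counts.append(int(((finite >= lo) & (finite < hi)).sum()))
    overflow = int((finite >= edges[-1]).sum())
    underflow = int((finite < edges[0]).sum())
    return {
        "edges": edges,
        "counts": counts,
        "overflow": overflow,
        "underflow": underflow,
        "n_missing": len(m.missing),
        "n_pairs": m.n_pairs,
        "max_rmsd": float(np.max(finite)) if finite.size else math.nan,
        "median_rmsd": float(np.median(finite)) if finite.size else math.nan,
    }
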