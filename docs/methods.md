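# Methods

## Superposition and RMSD

**Correspondence.** Residue pairing between two monomers comes from global
Needleman–Wunsch alignment of their one-letter sequences (match +1,
mismatch −1, linear gap −2). Traceback ties are broken deterministically
(diagonal, then gap-in-second, then gap-in-first), so the correspondence —
and everything downstream — is reproducible bit for bit. Structure-based
alignment (DALI/TM-align style) is deliberately out of scope: the ensembles
this package targets are near-identical in sequence, where sequence
alignment is both sufficient and far more transparent.

**Kabsch fit.** For paired Cα sets the least-RMSD proper rotation is the
SVD solution of the centred covariance matrix with the usual sign
correction (det = +1). Degenerate inputs (< 3 pairs, or a point set of rank
< 2, i.e. collinear) raise instead of returning an ill-defined rotation.

**Trimming.** The reported RMSD is computed after iterative outlier
rejection: fit on the current pair set, re-test *every* pair against the
fit, retain those deviating ≤ 3.5 Å, repeat until stable (≤ `max_iter`,
default 10). Two details matter:

* pairs are re-tested from the full set each round, so a pair shed while
  the fit was still contaminated can re-enter once the fit settles on the
  rigid core;
* if no pair is inside the cutoff (large-amplitude motion, e.g. a hinge),
  only the worst decile of the current set is shed that round, walking the
  fit gradually toward the most self-consistent rigid substructure instead
  of collapsing to an empty set.

`fraction_aligned` is the retained count over the shorter chain length, so
identical chains give exactly 1.0. The 3.5 Å cutoff follows common
superposition practice and is a parameter everywhere it appears. One
behavioural note: for a hinge exactly at the chain midpoint the two rigid
halves are equally valid cores and the retained set depends on the
iteration path; with the larger part unmoved, the trimmed fit recovers it
exactly.

**Ensemble statistics.** `all_pairs_rmsd` evaluates all n(n−1)/2 unordered
pairs; a failing pair (alignment too short, trim collapse) becomes a NaN
entry with a warning, never a crash, and the binning reports
counts + overflow + underflow + missing = n(n−1)/2 as an explicit
invariant. Bins are half-open [lo, hi): a value exactly at an edge joins
the upper bin.

## Solvent-accessible surface area

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points/atom; no RNG, so SASA is bit-reproducible). Each heavy atom carries
a test sphere of radius r_vdw + probe (probe default 1.4 Å, a water
molecule); a point is exposed iff it lies outside every neighbour's
expanded sphere; atom area = sphere area × exposed fraction; residue area
= sum over its heavy atoms. Hydrogens are ignored. Van der Waals radii:
C 1.70, N 1.55, O 1.52, S 1.80, default 1.80 Å (configurable table, not
hard-coded).

HETATM records (ligands, ions, waters) are excluded from the occluding set
by default and never reported as residues; `include_het=True` lets them
occlude. Both conventions are defensible for a ligand-bound structure and
the choice is surfaced as a flag.

**Relative accessibility.** Residue ASA divided by a per-residue-type
maximum. The shipped table is the Tien et al. (2013) *empirical* maximum
ASA set — the closest published analogue of "the maximum observed in the
PDB" — and any two-column TSV can be substituted. A residue is *external*
iff rel_asa > 0.5 strictly; exactly 0.5 is buried. Residue types absent
from the table are flagged not-classifiable and excluded from summaries
rather than silently defaulted.

**Quadrature behaviour.** A lone atom is exact at any point count (every
point is exposed), so convergence is only meaningful where spheres
interact; on the two-overlapping-spheres case the quadrature error against
the analytic cap formula is largest at 60 points (~1.1%) and below 2% at
every tested count. The independent cross-check in the test suite is
biotite's SASA implementation on a 20-residue synthetic helix (agreement
within 5% with matched radii).

## Sequence statistics

Net charge uses the simple integer convention: +1 per Arg/Lys, −1 per
Glu/Asp, histidine and the termini neutral, modified residues outside the
20-letter alphabet ignored. This is the convention under which α-actin's
printed counts (18 R, 19 K, 28 E, 22 D) give −13. The exact charged
fraction of those counts is 87/375 = 0.232; the commonly quoted rounded
figure is 24%, and the pipeline reports the exact value.

Composition enrichment divides the sequence's per-type frequency by a
reference composition. The packaged reference is an approximate
SwissProt/human average (renormalised on load); it stands in for a
proteome-wide background so no download is required, and any two-column
TSV can replace it.

Conservation is the modal-residue fraction per column, gaps excluded
(all-gap columns score 0 with gap fraction 1). This is chosen for
transparency over entropy- or similarity-matrix-based scores; it is exactly
1.0 on identical ungapped columns and invariant under row permutation. The
star alignment aligns every family member to one reference and merges
insertion columns by reference position (taking the maximum insertion
length per position), which is deterministic and adequate in the
near-identical regime the generator produces; it is *not* a general MSA
method and degrades below ~50% identity (a warning fires there).

## Synthetic data

The generators define the study conditions:

* **Backbone:** ideal Cα helix, radius 2.3 Å, rise 1.5 Å/residue,
  100°/residue (Cα–Cα chord ≈ 3.83 Å, inside the 3.8 ± 0.1 Å band), with
  N/C/O placed by fixed local offsets. This is deliberately not
  Ramachandran-realistic: superposition and SASA arithmetic see only atom
  positions, and a closed-form chain keeps every generator a pure function
  of (spec, seed).
* **Ensembles:** iid Gaussian noise per coordinate (default study
  condition σ = 0.3 Å, n = 20 structures of 60 residues) plus random rigid
  motions. E[RMSD] to the base is σ√3; between two members σ√6 ≈ 0.73 Å at
  σ = 0.3, so the whole ensemble lands in the 0–1 Å bin — the synthetic
  analogue of a homogeneous deposition history.
* **Filaments:** exact helical symmetry copies (defaults 27.5 Å rise,
  −166.7° twist, the canonical actin filament parameters) labelled as
  chains A, B, C…; inter-copy RMSD is zero by construction, which is the
  signature of entries built by copying one monomer rather than refining
  each independently.
* **Hinge pairs:** residues beyond the hinge rotated about an axis through
  the hinge Cα perpendicular to the helix axis; deviation grows with
  distance from the hinge, which is what outlier trimming must resolve.
* **Burial fixtures:** a solid ball of single-atom filler residues (cubic
  grid, 1.8 Å spacing, radius 8 Å) with charged residues either as
  three-atom aspartates poking radially out of the surface (rel_asa far
  above 0.5) or single atoms at the ball's centre (rel_asa ≈ 0). The design
  tolerance is ±1 residue per class.
* **Families:** per-site substitution with probability p to a uniformly
  random different residue. The default rate 25/375 matches the
  ≤ 25-substitution divergence scale of actin isoforms; expected
  substitutions per sequence is the binomial mean np.

What the generators do **not** emulate: real side chains and packing,
ligands and ions, crystallographic disorder, resolution-dependent noise
structure, phylogenetic correlation between family members (sites and
sequences are iid). Passing tests therefore demonstrate the *operations*
are correct under stated conditions, not that real depositions are
homogeneous — the real-data checks activate only when the user supplies
the files (see `tests/test_integration_external.py`).

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 154-member pair count
(11,781 trimmed superpositions) on 10-residue monomers, which preserves the
combinatorics while keeping each fit trivial; the richer geometric checks
use 20–100-residue chains. SASA tests use 120–960 points per atom as noted.
The Kabsch optimality oracle is a 5°-spaced Euler grid over SO(3) (~190k
rotations), refined locally to 0.25° where a tight bound is asserted; grid
search is independent of the SVD path it checks. Region arithmetic is
integer set enumeration — no floating point is involved, so containment
1.0 and Jaccard 65/89 are exact.

## Known limitations

* Legacy PDB format only (mmCIF is a v2 hook); multi-model files keep
  MODEL 1; altloc other than blank/'A' dropped.
* First-chain selection is file order; no biological-assembly expansion.
* SASA is accessible-surface (probe-centre) area, not molecular (Connolly)
  surface; no polar/apolar split, no electrostatics.
* The star alignment is reference-anchored; insertions relative to the
  reference at the same position are left-padded rather than re-aligned
  against each other.
* Charge model has no pKa, no termini, no phosphorylation.
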