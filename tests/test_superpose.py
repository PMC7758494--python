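"""Alignment, Kabsch superposition, trimming and ensemble RMSD statistics.

The Kabsch solution is checked against an independent rotation-grid oracle
(dense search over SO(3)), and the alignment against brute-force
enumeration of all global alignments of tiny strings.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from actin_audit import (
    align_sequences,
    all_pairs_rmsd,
    bin_rmsds,
    extract_monomer,
    kabsch,
    trimmed_superpose,
)
from actin_audit import synthetic as syn
from actin_audit.superpose import DegenerateGeometryError


# --- independent oracles ---------------------------------------------------

def brute_force_global_alignments(a, b, match=1, mismatch=-1, gap=-2):
    """Enumerate every global alignment of two tiny strings; return best score."""
    best = -10**9

    def rec(i, j, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            rec(i + 1, j, score + gap)
        if j < len(b):
            rec(i, j + 1, score + gap)

    rec(0, 0, 0)
    return best


def grid_min_rmsd(p, q, coarse_deg=5.0, refine_deg=0.25):
    """Min RMSD over a dense SO(3) grid (coarse scan + local refinement)."""
    p0 = p - p.mean(axis=0)
    q0 = q - q.mean(axis=0)
    n = len(p)

    def scan(alphas, betas, gammas):
        angles = np.array(list(itertools.product(alphas, betas, gammas)))
        mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        rotated = np.einsum("kij,nj->kni", mats, p0)
        rmsds = np.sqrt(((rotated - q0) ** 2).sum(axis=(1, 2)) / n)
        k = int(np.argmin(rmsds))
        return rmsds[k], angles[k]

    coarse = np.arange(0.0, 360.0, coarse_deg)
    coarse_beta = np.arange(0.0, 180.0 + coarse_deg, coarse_deg)
    best_rmsd, (a, b, g) = scan(coarse, coarse_beta, coarse)
    span = np.arange(-coarse_deg, coarse_deg + refine_deg, refine_deg)
    fine_rmsd, _ = scan(a + span, b + span, g + span)
    return min(best_rmsd, fine_rmsd)


# --- align_sequences -------------------------------------------------------

class TestAlignSequences:
    def test_identity(self):
        c = align_sequences("ACDEFG", "ACDEFG")
        assert c.pairs == [(i, i) for i in range(6)]
        assert c.score == 6

    @pytest.mark.parametrize("a,b,expected_pairs", [
        ("ACD", "AD", [(0, 0), (2, 1)]),
        ("AAAA", "CCCC", [(0, 0), (1, 1), (2, 2), (3, 3)]),
    ])
    def test_optimum_matches_brute_force(self, a, b, expected_pairs):
        c = align_sequences(a, b)
        assert c.score == brute_force_global_alignments(a, b)
        assert c.pairs == expected_pairs

    def test_empty_input(self):
        c = align_sequences("", "ACD")
        assert c.pairs == [] and c.score == 0

    def test_pairs_strictly_increasing(self):
        c = align_sequences("MKTAYIAKQR", "MKTAYIKQR")
        ia = [i for i, _ in c.pairs]
        ib = [j for _, j in c.pairs]
        assert ia == sorted(set(ia)) and ib == sorted(set(ib))

    @given(st.text(alphabet="ACDEF", min_size=1, max_size=7),
           st.text(alphabet="ACDEF", min_size=1, max_size=7))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_score_is_global_optimum(self, a, b):
        assert align_sequences(a, b).score == brute_force_global_alignments(a, b)


# --- kabsch ----------------------------------------------------------------

class TestKabsch:
    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(8, 3)) * 5
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        q = p @ rot.T + np.array([5.0, 0.0, 0.0])
        res = kabsch(p, q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.rotation, rot, atol=1e-8)

    def test_identity_case(self):
        p = np.random.default_rng(3).normal(size=(5, 3))
        res = kabsch(p, p)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(6, 3))
        q = p + rng.normal(scale=0.5, size=(6, 3))
        r = kabsch(p, q).rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_oracle_on_noisy_cloud(self):
        rng = np.random.default_rng(7)
        p = rng.normal(size=(6, 3)) * 3
        q = p + rng.normal(scale=0.3, size=(6, 3))
        res = kabsch(p, q)
        assert res.rmsd == pytest.approx(grid_min_rmsd(p, q), abs=1e-3)

    def test_never_beaten_by_grid_rotation(self):
        # optimality: no rotation on a 5-degree SO(3) grid does better
        rng = np.random.default_rng(8)
        for trial in range(3):
            p = rng.normal(size=(5 + trial, 3)) * 2
            q = p + rng.normal(scale=0.4, size=p.shape)
            res = kabsch(p, q)
            p0, q0 = p - p.mean(0), q - q.mean(0)
            angles = np.array(list(itertools.product(
                np.arange(0, 360, 5.0), np.arange(0, 185, 5.0),
                np.arange(0, 360, 5.0))))
            mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
            rotated = np.einsum("kij,nj->kni", mats, p0)
            rmsds = np.sqrt(((rotated - q0) ** 2).sum(axis=(1, 2)) / len(p))
            assert res.rmsd <= rmsds.min() + 1e-9

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        p = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(p, p)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        p = rng.normal(size=(10, 3))
        q = p + rng.normal(scale=0.2, size=(10, 3))
        assert kabsch(p, q).rmsd == pytest.approx(kabsch(q, p).rmsd, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(10)
        p = rng.normal(size=(12, 3))
        q = p + rng.normal(scale=0.3, size=(12, 3))
        base = kabsch(p, q).rmsd
        rot = Rotation.random(rng=rng).as_matrix()
        q2 = q @ rot.T + np.array([3.0, -7.0, 1.0])
        assert kabsch(p, q2).rmsd == pytest.approx(base, abs=1e-6)


# --- trimmed_superpose -----------------------------------------------------

class TestTrimmedSuperpose:
    def test_rigid_pair_fully_aligned(self, helix_pair):
        a, b = helix_pair
        res = trimmed_superpose(a, b)
        assert res.fraction_aligned == 1.0
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_self_pair_one_iteration(self, helix_monomer):
        res = trimmed_superpose(helix_monomer, helix_monomer)
        assert res.n_iterations == 1
        assert res.n_aligned == len(helix_monomer)

    def test_hinge_pair_trims_moved_domain(self):
        # 100-residue helix hinged 60 degrees after residue 60: the rigid
        # core (residues 1-60) must be recovered exactly
        s1, s2 = syn.make_hinge_pair(syn.make_backbone(100), hinge_res=60,
                                     angle=60)
        m1 = extract_monomer(s1, "A")
        m2 = extract_monomer(s2, "A")
        untrimmed = kabsch(m1.ca_coords, m2.ca_coords)
        trimmed = trimmed_superpose(m1, m2, max_iter=30)
        assert untrimmed.rmsd > 2.0
        assert trimmed.rmsd < 0.5
        dev = np.linalg.norm(
            m1.ca_coords @ trimmed.rotation.T + trimmed.translation
            - m2.ca_coords, axis=1)
        retained = set(np.nonzero(dev <= 3.5)[0])
        assert retained <= set(range(60))  # unmoved domain is 0-based 0..59

    def test_trimmed_rmsd_symmetry(self):
        base = syn.make_backbone(80)
        a = extract_monomer(syn.perturb_structure(base, 0.4, seed=1), "A")
        b = extract_monomer(syn.perturb_structure(base, 0.4, seed=2), "A")
        r_ab = trimmed_superpose(a, b).rmsd
        r_ba = trimmed_superpose(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=0.05)


# --- all_pairs_rmsd + bin_rmsds --------------------------------------------

class TestEnsembleStatistics:
    def test_two_monomers_one_pair(self):
        ens = syn.make_ensemble(syn.EnsembleSpec(2, 20, 0.1, seed=1))
        matrix = all_pairs_rmsd([extract_monomer(s, "A") for s in ens])
        assert matrix.n_pairs == 1
        assert matrix.values[0, 1] == matrix.values[1, 0] > 0
        assert matrix.values[0, 0] == 0

    def test_permutation_invariance(self):
        ens = syn.make_ensemble(syn.EnsembleSpec(4, 20, 0.2, seed=2))
        monomers = [extract_monomer(s, "A") for s in ens]
        m1 = all_pairs_rmsd(monomers)
        m2 = all_pairs_rmsd(monomers[::-1])
        assert m2.ids == m1.ids[::-1]
        tri1 = np.sort(m1.upper_triangle())
        tri2 = np.sort(m2.upper_triangle())
        np.testing.assert_allclose(tri1, tri2, atol=1e-9)

    def test_bin_counts_conserve_pairs(self):
        ens = syn.make_ensemble(syn.EnsembleSpec(6, 20, 0.2, seed=3))
        matrix = all_pairs_rmsd([extract_monomer(s, "A") for s in ens])
        bins = bin_rmsds(matrix)
        total = sum(bins["counts"]) + bins["overflow"] + bins["underflow"] \
            + bins["n_missing"]
        assert total == matrix.n_pairs == 15

    def test_bin_convention(self):
        # half-open [lo, hi): a value exactly at an edge joins the upper bin
        class FakeMatrix:
            ids = ["a", "b", "c", "d"]
            missing = []
            n_pairs = 6

            def upper_triangle(self):
                return np.array([0.5, 1.0, 1.5, 2.5, 2.999, 3.0])

        bins = bin_rmsds(FakeMatrix())
        assert bins["counts"] == [1, 2, 2]
        assert bins["overflow"] == 1

    def test_tight_ensemble_all_first_bin(self):
        # sigma small enough that every pairwise rmsd stays below 0.1
        ens = syn.make_ensemble(syn.EnsembleSpec(15, 50, 0.01, seed=4))
        matrix = all_pairs_rmsd([extract_monomer(s, "A") for s in ens])
        bins = bin_rmsds(matrix, edges=[0.0, 0.1, 1.0])
        assert bins["counts"] == [105, 0]

    def test_perturbation_magnitude_recovered(self):
        # mean untrimmed rmsd to the base must track sigma * sqrt(3)
        sigma = 0.5
        base = syn.make_backbone(600)
        base_coords = np.array([a.coord for a in base.atoms])
        rmsds = [
            kabsch(base_coords,
                   np.array([a.coord for a in
                             syn.perturb_structure(base, sigma, seed=s).atoms])).rmsd
            for s in range(20)
        ]
        expected = sigma * np.sqrt(3.0)
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.05)
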