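"""Kabsch superposition, rotation angles, and the domain-shift measurement."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from butenolide_scout import structcompare, synthetic
from butenolide_scout.structcompare import (
    CaTrace,
    DomainRanges,
    domain_shift,
    kabsch,
    read_ca_trace,
    rotation_angle,
    write_ca_trace,
)

FIVE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA AGLY A   2       8.502   5.382  -3.815  0.50  0.00           C
ATOM      4  CA BGLY A   2       8.600   5.400  -3.900  0.50  0.00           C
ATOM      5  CA  SER A   3       5.605   7.784  -3.170  1.00  0.00           C
ATOM      6  CA  THR A   4       4.000   4.500  -2.000  1.00  0.00           C
ATOM      7  CA  VAL A   5       1.500   3.000  -1.000  1.00  0.00           C
ATOM      8  CB  VAL A   5       1.900   2.500  -0.200  1.00  0.00           C
END
"""


class TestReadCaTrace:
    def test_five_residue_file(self, tmp_path):
        p = tmp_path / "five.pdb"
        p.write_text(FIVE_RESIDUE_PDB)
        trace = read_ca_trace(p, chain="A")
        assert len(trace.residues) == 5
        assert trace.numbers() == [1, 2, 3, 4, 5]

    def test_first_altloc_kept(self, tmp_path):
        p = tmp_path / "five.pdb"
        p.write_text(FIVE_RESIDUE_PDB)
        trace = read_ca_trace(p, chain="A")
        num, _, (x, _, _) = trace.residues[1]
        assert num == 2 and x == pytest.approx(8.502)

    def test_absent_chain_rejected(self, tmp_path):
        p = tmp_path / "five.pdb"
        p.write_text(FIVE_RESIDUE_PDB)
        with pytest.raises(ValueError, match="absent"):
            read_ca_trace(p, chain="Z")

    def test_write_read_roundtrip_preserves_coordinates(self, tmp_path):
        apo, _, _ = synthetic.make_two_domain(0.0, seed=3)
        p = tmp_path / "apo.pdb"
        write_ca_trace(apo, p)
        reread = read_ca_trace(p)
        assert reread.numbers() == apo.numbers()
        np.testing.assert_allclose(reread.coords(), apo.coords(), atol=5e-4)


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        P = np.random.default_rng(0).normal(size=(10, 3))
        sup = kabsch(P, P)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_constructed_rotation(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(12, 3))
        R10 = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        P = Q @ R10.T + np.array([1.0, -2.0, 3.0])
        sup = kabsch(P, Q)
        assert rotation_angle(sup.rotation) == pytest.approx(10.0, abs=1e-6)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation_enforced_on_reflected_cloud(self):
        rng = np.random.default_rng(2)
        Q = rng.normal(size=(8, 3))
        P = Q.copy()
        P[:, 0] *= -1  # mirror image
        sup = kabsch(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch(P, P)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_beats_random_rotation_oracle(self):
        # brute force: RMSD at the Kabsch optimum must not exceed the best
        # of many random rotations with optimal translation
        rng = np.random.default_rng(3)
        rand_rots = Rotation.random(2000, random_state=7).as_matrix()
        for _ in range(10):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))
            best = kabsch(P, Q).rmsd
            P0 = P - P.mean(axis=0)
            Q0 = Q - Q.mean(axis=0)
            rotated = np.einsum("kij,nj->kni", rand_rots, Q0)
            rmsds = np.sqrt(((rotated - P0) ** 2).sum(axis=2).mean(axis=1))
            assert best <= rmsds.min() + 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(4)
        P, Q = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        sup = kabsch(P, Q)
        ref, _ = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        np.testing.assert_allclose(sup.rotation, ref.as_matrix(), atol=1e-8)


class TestRotationAngle:
    def test_identity_is_zero(self):
        assert rotation_angle(np.eye(3)) == 0.0

    def test_half_turn(self):
        assert rotation_angle(np.diag([1.0, -1.0, -1.0])) == pytest.approx(180.0)

    def test_composition_about_common_axis_adds(self):
        r30 = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        r40 = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        assert rotation_angle(r40 @ r30) == pytest.approx(70.0, abs=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.diag([2.0, 1.0, 1.0]))


class TestDomainShift:
    def test_self_comparison_is_zero(self):
        apo, _, _ = synthetic.make_two_domain(0.0, seed=5)
        res = domain_shift(apo, apo)
        # arccos((tr-1)/2) is sqrt(eps)-conditioned at identity, so "zero"
        # means < 1e-4 degrees in double precision
        assert res.angle == pytest.approx(0.0, abs=1e-4)
        assert res.rmsd_lbd == pytest.approx(0.0, abs=1e-9)
        assert res.rmsd_dbd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [2.0, 5.0, 10.0, 20.0, 45.0])
    def test_planted_angle_recovered_noiseless(self, angle):
        apo, holo, _ = synthetic.make_two_domain(angle, noise_sd=0.0, seed=8)
        res = domain_shift(apo, holo)
        assert res.angle == pytest.approx(angle, abs=0.5)

    def test_planted_angle_bias_small_under_noise(self):
        errors = [
            domain_shift(*synthetic.make_two_domain(10.0, noise_sd=0.3, seed=s)[:2]).angle - 10.0
            for s in range(12)
        ]
        assert abs(np.mean(errors)) < 1.0

    def test_invariant_to_rigid_pretransform_of_either_input(self):
        apo, holo, _ = synthetic.make_two_domain(10.0, seed=9)
        R = Rotation.from_euler("xyz", [15, -40, 77], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])

        def transform(trace):
            new = trace.coords() @ R.T + t
            return CaTrace(
                chain_id=trace.chain_id,
                residues=[(n, aa, tuple(c)) for (n, aa, _), c in zip(trace.residues, new)],
            )

        base = domain_shift(apo, holo).angle
        assert domain_shift(transform(apo), holo).angle == pytest.approx(base, abs=1e-6)
        assert domain_shift(apo, transform(holo)).angle == pytest.approx(base, abs=1e-6)

    def test_insufficient_shared_residues_rejected(self):
        apo, holo, _ = synthetic.make_two_domain(10.0, seed=10)
        tiny = CaTrace(chain_id="A", residues=holo.residues[:4])
        with pytest.raises(ValueError, match="insufficient"):
            domain_shift(apo, tiny)


def test_domain_ranges_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        DomainRanges(dbd=[(1, 70)], lbd=[(66, 220)])
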