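"""Kabsch superposition: optimality, invariances, pocket RMSD and outlier rejection."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from degronkit.errors import SuperpositionError
from degronkit.structure import build_structure
from degronkit.superpose import PocketSpec, kabsch, pocket_rmsd, random_rotation
from degronkit.synthetic import ToyComplexSpec, make_toy_complex, perturb_structure


def _cloud(rng, n=12):
    return rng.normal(scale=5.0, size=(n, 3))


class TestKabsch:
    def test_self_superposition(self):
        P = _cloud(np.random.default_rng(0))
        res = kabsch(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_applied_rigid_transform(self):
        rng = np.random.default_rng(1)
        P = _cloud(rng)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        Q = P @ R.T + t  # Q = R P + t, so the fit onto P must apply R⁻¹
        res = kabsch(P, Q)
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.rotation, R.T, atol=1e-6)

    def test_result_is_proper_rotation(self):
        rng = np.random.default_rng(2)
        # a mirror image forces the reflection-correction branch
        P = _cloud(rng)
        Q = P.copy()
        Q[:, 0] *= -1
        res = kabsch(P, Q)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_optimality_against_random_rotations(self):
        """No rotation perturbation of the Kabsch solution scores better."""
        rng = np.random.default_rng(3)
        P = _cloud(rng, n=20)
        Q = P + rng.normal(scale=0.5, size=P.shape)
        res = kabsch(P, Q)
        Qc, Pc = Q.mean(0), P.mean(0)
        for _ in range(100):
            R = random_rotation(rng)
            rot = res.rotation @ R
            fitted = (Q - Qc) @ rot.T + Pc
            rmsd = np.sqrt(np.mean(np.sum((P - fitted) ** 2, axis=1)))
            assert rmsd >= res.rmsd - 1e-12

    def test_matches_numerical_minimization(self):
        """Closed form equals direct optimization over rotation space (±1e-4)."""
        rng = np.random.default_rng(4)
        P = _cloud(rng, n=5)
        Q = P + rng.normal(scale=0.8, size=P.shape)
        res = kabsch(P, Q)

        P0 = P - P.mean(0)
        Q0 = Q - Q.mean(0)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return float(np.sqrt(np.mean(np.sum((P0 - Q0 @ R.T) ** 2, axis=1))))

        best = min(
            minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}).fun
            for x0 in [np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 2.0, 1.0])]
        )
        assert res.rmsd == pytest.approx(best, abs=1e-4)

    def test_pre_transform_invariance(self):
        rng = np.random.default_rng(5)
        P = _cloud(rng)
        Q = P + rng.normal(scale=0.3, size=P.shape)
        base = kabsch(P, Q).rmsd
        R = random_rotation(rng)
        assert kabsch(P @ R.T + 3.0, Q).rmsd == pytest.approx(base, abs=1e-8)
        assert kabsch(P, Q @ R.T - 1.0).rmsd == pytest.approx(base, abs=1e-8)

    def test_guards(self):
        P = np.zeros((2, 3))
        with pytest.raises(SuperpositionError, match="at least 3"):
            kabsch(P, P)
        with pytest.raises(SuperpositionError, match="shape"):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(SuperpositionError, match="collinear"):
            kabsch(line, line)


def _pocket_structure(n=100, seed=0):
    receptor, _, _ = make_toy_complex(ToyComplexSpec(n_receptor=n, peptide_len=1, seed=seed))
    return receptor


class TestPocketRMSD:
    def test_identity_in_both_modes(self):
        s = _pocket_structure(30)
        for mode in ("all_pairs", "reject"):
            res = pocket_rmsd(s, s, PocketSpec(1, 30), mode=mode)
            assert res.rmsd == pytest.approx(0.0, abs=1e-10)
            assert res.n_pairs == 30

    def test_rigid_copy_scores_zero(self):
        s = _pocket_structure(30)
        moved = perturb_structure(s, (0.5, 1.0, -0.7), (8.0, 1.0, -2.0), 0.0, seed=1)
        res = pocket_rmsd(moved, s, PocketSpec(1, 30))
        assert res.rmsd <= 1e-6

    def test_noise_rmsd_matches_expectation(self):
        """Fitted RMSD under isotropic noise matches the Monte-Carlo expectation.

        For per-atom Gaussian noise of σ on n atoms, the optimally fitted
        RMSD concentrates near σ·√(3·(1−7/(2n))); the mean over 20 seeds
        must fall within 20% of that value for n = 100.
        """
        sigma, n = 0.3, 100
        s = _pocket_structure(n=n, seed=3)
        values = []
        for seed in range(20):
            noisy = perturb_structure(s, (0.2, 0.1, 0.3), (1.0, 2.0, 3.0), sigma, seed=seed)
            values.append(pocket_rmsd(noisy, s, PocketSpec(1, n)).rmsd)
        expected = sigma * np.sqrt(3.0 * (1.0 - 7.0 / (2.0 * n)))
        assert 0.8 * expected <= np.mean(values) <= 1.2 * expected

    def test_mapping_pairs_across_numbering(self):
        """A reference→model number offset is bridged by an explicit mapping."""
        s = _pocket_structure(20)
        shifted = build_structure(
            "shifted",
            [
                (
                    r.rid.chain,
                    r.rid.number + 50,
                    r.rid.res_name,
                    [(a.name, a.element, a.coords) for a in r.atoms],
                )
                for r in s.residues
            ],
        )
        mapping = {i: i + 50 for i in range(1, 21)}
        res = pocket_rmsd(shifted, s, PocketSpec(1, 20), mapping=mapping)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.n_pairs == 20

    def test_reject_mode_discards_planted_outliers(self):
        s = _pocket_structure(40, seed=7)
        noisy = perturb_structure(s, noise_sigma=0.1, seed=9)
        # displace three Cα far away
        coords = noisy.all_coords()
        ca_rows = []
        k = 0
        for r in noisy.residues:
            ca_rows.append(k)
            k += len(r.atoms)
        for row in ca_rows[:3]:
            coords[row] += np.array([25.0, 0.0, 0.0])
        outliered = noisy.with_coords(coords)

        all_pairs = pocket_rmsd(outliered, s, PocketSpec(1, 40), mode="all_pairs")
        reject = pocket_rmsd(outliered, s, PocketSpec(1, 40), mode="reject")
        assert reject.n_pairs <= all_pairs.n_pairs
        assert reject.rmsd < all_pairs.rmsd
        assert reject.n_pairs >= 37 - 3  # never collapses below the honest core

    def test_too_few_pairs_raises(self):
        s = _pocket_structure(5)
        with pytest.raises(SuperpositionError, match="at least 3"):
            pocket_rmsd(s, s, PocketSpec(1, 2))

    def test_unknown_mode_rejected(self):
        s = _pocket_structure(5)
        with pytest.raises(ValueError):
            pocket_rmsd(s, s, PocketSpec(1, 5), mode="magic")
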