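import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from bolakit.geometry import (
    atom_distance,
    element_rmsd,
    ensemble_rmsd,
    kabsch_superpose,
    mean_structure_coords,
    pairwise_rmsd,
    per_residue_rmsd,
)
from bolakit.structure_io import ResidueRange
from bolakit.synth import make_toy_ensemble

from tests.conftest import ensemble_from_coords


def brute_force_min_rmsd(ref, mov):
    """Independent oracle: minimum RMSD over rotations via a quaternion grid
    followed by local polish on the rotation vector (never uses
    kabsch_superpose or align_vectors)."""
    ref = ref - ref.mean(axis=0)
    mov = mov - mov.mean(axis=0)

    def rmsd_of_rotvec(v):
        R = Rotation.from_rotvec(v).as_matrix()
        return np.sqrt(((mov @ R.T - ref) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(0)
    quats = rng.normal(size=(4000, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_v, best = None, np.inf
    for q in quats:
        v = Rotation.from_quat(q).as_rotvec()
        r = rmsd_of_rotvec(v)
        if r < best:
            best, best_v = r, v
    sol = minimize(rmsd_of_rotvec, best_v, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return sol.fun


class TestKabsch:
    def test_identical_sets(self):
        coords = np.random.default_rng(0).normal(size=(5, 3))
        sup = kabsch_superpose(coords, coords)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-7)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ R.T + np.array([3.0, -2.0, 7.0])
        sup = kabsch_superpose(coords, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.transform(moved), coords, atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar sets invite the reflection branch; det must stay +1
        a = rng.normal(size=(6, 3)) * np.array([1.0, 1.0, 1e-3])
        b = rng.normal(size=(6, 3)) * np.array([1.0, 1.0, 1e-3])
        sup = kabsch_superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_rotation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(6, 3))
        mov = rng.normal(size=(6, 3))
        assert kabsch_superpose(ref, mov).rmsd == pytest.approx(
            brute_force_min_rmsd(ref, mov), abs=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_weights_change_the_fit(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(6, 3))
        mov = rng.normal(size=(6, 3))
        w = np.array([10.0, 1, 1, 1, 1, 1])
        fitted = kabsch_superpose(ref, mov, weights=w).transform(mov)
        unweighted = kabsch_superpose(ref, mov).transform(mov)
        assert np.linalg.norm(fitted[0] - ref[0]) < np.linalg.norm(unweighted[0] - ref[0])


class TestMeanStructure:
    def test_identical_models(self):
        coords = np.random.default_rng(0).normal(size=(4, 3))
        mean, _ = mean_structure_coords(np.stack([coords, coords]))
        np.testing.assert_allclose(mean, coords, atol=1e-9)

    def test_rigid_motions_of_one_shape(self):
        rng = np.random.default_rng(1)
        shape = rng.normal(size=(6, 3))
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        stack = np.stack([shape, shape @ R.T + 5.0])
        mean, _ = mean_structure_coords(stack)
        assert kabsch_superpose(shape, mean).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_gaussian_noise_mean_recovers_template(self):
        rng = np.random.default_rng(2)
        sigma, m, n = 0.3, 10, 200
        template = rng.normal(size=(n, 3)) * 10
        stack = template + rng.normal(0, sigma, size=(m, n, 3))
        mean, _ = mean_structure_coords(stack)
        aligned = kabsch_superpose(template, mean).transform(mean)
        dev = np.abs(aligned - template)
        se = sigma / np.sqrt(m)
        assert np.quantile(dev, 0.95) < 2.2 * se
        assert dev.max() < 5 * se


def noisy_ensemble(sigma, m=10, n=60, seed=0, spread=20.0):
    rng = np.random.default_rng(seed)
    template = rng.normal(size=(n, 3)) * spread
    stack = template + rng.normal(0, sigma, size=(m, n, 3))
    res = [i // 3 + 1 for i in range(n)]
    names = ["N", "CA", "C"] * (n // 3)
    return ensemble_from_coords(stack, atom_names=names, res_per_atom=res)


class TestEnsembleRmsd:
    def test_identical_models_give_zero(self):
        ens = noisy_ensemble(sigma=0.0)
        assert ensemble_rmsd(ens) == pytest.approx(0.0, abs=1e-9)

    def test_single_model_is_undefined(self):
        ens = noisy_ensemble(sigma=0.0)
        ens.models = ens.models[:1]
        with pytest.raises(ValueError, match="single-model"):
            ensemble_rmsd(ens)

    def test_isotropic_noise_law(self):
        # for iid noise sigma the model-to-mean RMSD tends to sigma*sqrt(3)*sqrt((m-1)/m)
        sigma, m = 0.5, 10
        vals = [
            ensemble_rmsd(noisy_ensemble(sigma, m=m, n=300, seed=s), combine="rms")
            for s in range(3)
        ]
        expected = sigma * np.sqrt(3.0) * np.sqrt((m - 1) / m)
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_invariant_under_common_rigid_motion(self):
        ens = noisy_ensemble(sigma=0.4, seed=3)
        before = ensemble_rmsd(ens)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        for mdf in ens.models:
            xyz = mdf[["x", "y", "z"]].to_numpy() @ R.T + np.array([1.0, 2.0, 3.0])
            mdf[["x", "y", "z"]] = xyz
        ens._keyed = []
        assert ensemble_rmsd(ens) == pytest.approx(before, abs=1e-9)

    def test_pairwise_convention_also_defined(self):
        ens = noisy_ensemble(sigma=0.4, seed=4)
        assert pairwise_rmsd(ens) > ensemble_rmsd(ens) > 0


class TestPerResidueRmsd:
    def test_identical_models_all_zero(self):
        profile = per_residue_rmsd(noisy_ensemble(0.0))
        assert (profile["rmsd"] < 1e-9).all()

    def test_loop_noise_exceeds_core(self):
        ens, loop = make_toy_ensemble(
            n_models=10, sigma_core=0.3, sigma_loop=1.5, seed=5
        )
        profile = per_residue_rmsd(ens, "backbone")
        in_loop = profile["res_seq"].between(loop.start, loop.end)
        assert profile.loc[in_loop, "rmsd"].median() > profile.loc[~in_loop, "rmsd"].median()

    def test_heavy_at_least_backbone_with_sidechain_noise(self):
        ens, _ = make_toy_ensemble(n_models=8, sigma_core=0.2, sigma_loop=1.0, seed=6)
        assert ensemble_rmsd(ens, None, "heavy") >= 0.8 * ensemble_rmsd(ens, None, "backbone")

    def test_profile_aggregates_to_global_rms(self):
        ens = noisy_ensemble(sigma=0.5, seed=7)
        profile = per_residue_rmsd(ens, "backbone")
        agg = np.sqrt(
            (profile["n_atoms"] * profile["rmsd"] ** 2).sum() / profile["n_atoms"].sum()
        )
        assert agg == pytest.approx(ensemble_rmsd(ens, None, "backbone", combine="rms"), abs=1e-9)


class TestElementRmsd:
    def test_identical_models_zero_for_any_range(self):
        ens = noisy_ensemble(0.0)
        assert element_rmsd(ens, ResidueRange(2, 6)) == pytest.approx(0.0, abs=1e-9)

    def test_local_superposition_not_larger_than_global(self):
        ens, loop = make_toy_ensemble(n_models=10, sigma_core=0.3, sigma_loop=1.5, seed=8)
        rng = ResidueRange(loop.start, loop.end)
        local = element_rmsd(ens, rng, local_superposition=True)
        global_ = element_rmsd(ens, rng, local_superposition=False)
        assert local <= global_ + 1e-9


class TestAtomDistance:
    def test_same_atom_twice_is_zero(self):
        ens = noisy_ensemble(0.0)
        assert atom_distance(ens.model(1), 1, "CA", 1, "CA") == 0.0

    def test_unit_separation(self):
        ens = ensemble_from_coords(
            np.array([[[0.0, 0, 0], [0, 0, 1.0]]]), atom_names=["CA", "CA"], res_per_atom=[1, 2]
        )
        assert atom_distance(ens.model(1), 1, "CA", 2, "CA") == pytest.approx(1.0)

    def test_missing_atom_raises(self):
        ens = noisy_ensemble(0.0)
        with pytest.raises(KeyError, match="not found"):
            atom_distance(ens.model(1), 1, "OG", 2, "CA")
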