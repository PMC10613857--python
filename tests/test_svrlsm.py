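"""SVR-LSM core: residualization, beta maps, permutation inference, smoothing."""

import numpy as np
import pandas as pd
import pytest

from psdlsm.lesion_io import build_lesion_matrix
from psdlsm.svrlsm import (
    PMap,
    SvrLsmConfig,
    cross_validate,
    fit_beta_map,
    permutation_pmap,
    residualize,
    threshold_and_smooth,
)
from tests.conftest import random_blob_mask


def make_matrix(seed=0, n=40, shape=(10, 10, 10), min_overlap=3, voxel_mm=1.0):
    rng = np.random.default_rng(seed)
    masks = [
        random_blob_mask(rng, shape=shape, n_voxels=int(rng.integers(5, 60)),
                         voxel_mm=voxel_mm, patient_id=f"p{i}")
        for i in range(n)
    ]
    return build_lesion_matrix(masks, min_overlap=min_overlap)


def signal_voxel_data(seed=0, noise=0.05):
    """A matrix plus behaviour that is a noiseless-ish function of one voxel."""
    matrix = make_matrix(seed=seed)
    rng = np.random.default_rng(seed + 1000)
    prevalence = matrix.data.mean(axis=0)
    j = int(np.argmin(np.abs(prevalence - 0.5)))
    y = 3.0 * matrix.data[:, j].astype(float) + rng.normal(0, noise, matrix.n_patients)
    return matrix, y, j


class TestResidualize:
    def test_behaviour_proportional_to_volume_vanishes(self):
        matrix = make_matrix()
        y = 2.5 * matrix.lesion_volumes + 1.0
        corrected = residualize(matrix, y)
        assert np.abs(corrected.behaviour_resid).max() < 1e-10

    def test_behaviour_orthogonal_to_design_is_returned_centered(self):
        matrix = make_matrix()
        rng = np.random.default_rng(1)
        n = matrix.n_patients
        confounds = pd.DataFrame(
            {"nihss": rng.integers(0, 25, n), "age": rng.uniform(45, 90, n),
             "sex": rng.integers(0, 2, n)}
        )
        D = np.column_stack(
            [np.ones(n), matrix.lesion_volumes, confounds.to_numpy(float)]
        )
        y = rng.normal(size=n)
        y -= D @ np.linalg.lstsq(D, y, rcond=None)[0]  # orthogonalize
        y_off = y + 7.0  # re-add a constant; centering must remove it
        corrected = residualize(matrix, y_off, confounds)
        np.testing.assert_allclose(corrected.behaviour_resid, y, atol=1e-10)

    def test_residual_columns_match_closed_form_ols(self):
        rng = np.random.default_rng(2)
        matrix = make_matrix(seed=2)
        corrected = residualize(matrix, rng.normal(size=matrix.n_patients))
        vol = matrix.lesion_volumes
        vc = vol - vol.mean()
        for j in rng.choice(matrix.n_voxels, size=min(50, matrix.n_voxels), replace=False):
            x = matrix.data[:, j].astype(float)
            beta = (vc @ (x - x.mean())) / (vc @ vc)
            expected = x - x.mean() - beta * vc
            np.testing.assert_allclose(corrected.lesion_matrix_resid[:, j], expected, atol=1e-10)

    def test_behaviour_residual_orthogonal_to_volume(self):
        matrix = make_matrix(seed=3)
        rng = np.random.default_rng(3)
        y = rng.normal(size=matrix.n_patients) + 0.1 * matrix.lesion_volumes
        corrected = residualize(matrix, y)
        assert abs(np.corrcoef(corrected.behaviour_resid, matrix.lesion_volumes)[0, 1]) < 1e-10

    def test_constant_volume_advises_skipping_correction(self):
        matrix = make_matrix()
        matrix.lesion_volumes = np.ones(matrix.n_patients)
        with pytest.raises(ValueError, match="skip volume correction"):
            residualize(matrix, np.arange(matrix.n_patients, dtype=float))

    def test_rank_deficient_confounds_rejected(self):
        matrix = make_matrix()
        n = matrix.n_patients
        confounds = pd.DataFrame({"a": np.arange(n, dtype=float), "b": 2.0 * np.arange(n)})
        with pytest.raises(ValueError, match="rank"):
            residualize(matrix, np.random.default_rng(0).normal(size=n), confounds)


class TestBetaMap:
    def test_single_signal_voxel_attains_largest_beta(self):
        """Across 20 replicates the voxel that drives behaviour carries the
        largest-magnitude positive weight in the clear majority."""
        config = SvrLsmConfig(n_permutations=100)
        wins = 0
        for rep in range(20):
            matrix, y, j = signal_voxel_data(seed=rep)
            corrected = residualize(matrix, y)
            beta = fit_beta_map(corrected, config)
            if np.argmax(beta.values) == j:
                wins += 1
        assert wins >= 14

    def test_joint_patient_permutation_leaves_beta_unchanged(self):
        matrix, y, _ = signal_voxel_data(seed=5)
        config = SvrLsmConfig(n_permutations=100)
        corrected = residualize(matrix, y)
        beta = fit_beta_map(corrected, config)
        perm = np.random.default_rng(0).permutation(matrix.n_patients)
        matrix2 = make_matrix(seed=5)
        matrix2.data = matrix2.data[perm]
        matrix2.lesion_volumes = matrix2.lesion_volumes[perm]
        corrected2 = residualize(matrix2, y[perm])
        np.testing.assert_allclose(beta.values, fit_beta_map(corrected2, config).values, atol=1e-8)

    def test_duplicating_every_patient_preserves_sign_pattern(self):
        matrix, y, _ = signal_voxel_data(seed=6)
        config = SvrLsmConfig(n_permutations=100)
        corrected = residualize(matrix, y)
        beta = fit_beta_map(corrected, config)
        matrix2 = make_matrix(seed=6)
        matrix2.data = np.vstack([matrix2.data, matrix2.data])
        matrix2.lesion_volumes = np.concatenate([matrix2.lesion_volumes] * 2)
        corrected2 = residualize(matrix2, np.concatenate([y, y]))
        beta2 = fit_beta_map(corrected2, config)
        strong = np.abs(beta.values) > 0.25 * np.abs(beta.values).max()
        assert (np.sign(beta.values[strong]) == np.sign(beta2.values[strong])).mean() > 0.9

    def test_constant_behaviour_rejected(self):
        matrix = make_matrix()
        corrected = residualize(matrix, np.arange(matrix.n_patients, dtype=float))
        corrected.behaviour_resid = np.zeros(matrix.n_patients)
        with pytest.raises(ValueError, match="constant"):
            fit_beta_map(corrected, SvrLsmConfig())


class TestPermutationPMap:
    def test_strong_signal_reaches_smallest_attainable_p(self):
        matrix, y, j = signal_voxel_data(seed=7, noise=0.01)
        config = SvrLsmConfig(n_permutations=200, seed=7)
        corrected = residualize(matrix, y)
        pmap = permutation_pmap(corrected, config)
        assert pmap.p.min() == pytest.approx(1.0 / 201.0)
        assert pmap.p[j] == pytest.approx(1.0 / 201.0)
        assert pmap.p.max() <= 1.0 and pmap.p.min() > 0.0

    def test_null_p_values_centre_on_half(self):
        matrix = make_matrix(seed=8)
        y = np.random.default_rng(8).normal(size=matrix.n_patients)
        config = SvrLsmConfig(n_permutations=200, seed=8)
        pmap = permutation_pmap(residualize(matrix, y), config)
        assert 0.35 < np.median(pmap.p) < 0.65

    def test_seeded_reproducibility(self):
        matrix, y, _ = signal_voxel_data(seed=9)
        config = SvrLsmConfig(n_permutations=100, seed=9)
        p1 = permutation_pmap(residualize(matrix, y), config).p
        p2 = permutation_pmap(residualize(matrix, y), config).p
        np.testing.assert_array_equal(p1, p2)


class TestThresholdAndSmooth:
    def _pmap_with(self, p_vector, matrix, config):
        return PMap(p=p_vector, beta_observed=np.zeros_like(p_vector), matrix=matrix, config=config)

    def test_empty_significant_set_stays_empty(self):
        matrix = make_matrix(seed=10)
        config = SvrLsmConfig(n_permutations=100)
        pmap = self._pmap_with(np.ones(matrix.n_voxels), matrix, config)
        assert threshold_and_smooth(pmap).n_significant == 0

    def test_solid_block_interior_survives_smoothing(self):
        matrix = make_matrix(seed=11, min_overlap=1)
        config = SvrLsmConfig(n_permutations=100)
        # mark every analyzed voxel significant: a solid region's interior
        # must be untouched by the despeckling smooth
        p = np.zeros(matrix.n_voxels)
        pmap = self._pmap_with(p, matrix, config)
        sig = threshold_and_smooth(pmap)
        grid = matrix.embed(np.ones(matrix.n_voxels)).astype(bool)
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(grid, np.ones((3, 3, 3)))
        assert sig.grid.astype(bool)[interior].all()

    def test_isolated_voxel_removed_by_rebinarization(self):
        """At 1 mm voxels a single significant voxel cannot survive a 2 mm
        FWHM smooth re-binarized at 0.5."""
        matrix = make_matrix(seed=12, voxel_mm=1.0)
        config = SvrLsmConfig(n_permutations=100, smoothing_fwhm_mm=2.0)
        p = np.ones(matrix.n_voxels)
        # choose an analyzed voxel with no analyzed 26-neighbour if possible;
        # any isolated-at-threshold voxel works since only it is significant
        p[0] = 1e-4
        pmap = self._pmap_with(p, matrix, config)
        sig = threshold_and_smooth(pmap)
        assert sig.n_significant == 0

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            SvrLsmConfig(p_threshold=0.0)


class TestCrossValidate:
    def test_planted_signal_gives_positive_cv_correlation(self):
        """With the hyperparameter tuner enabled, cohorts carrying a strong
        planted region effect predict out-of-fold in the clear majority of
        20 replicates."""
        import dataclasses

        from psdlsm.madrs import score_table
        from psdlsm.synthetic import generate_cohort, recovery_benchmark_spec

        grid = {"C": [1.0, 30.0], "gamma": [0.3, 1.0, 5.0]}
        wins = 0
        for seed in range(20):
            cohort = generate_cohort(recovery_benchmark_spec(seed=seed))
            matrix = build_lesion_matrix(cohort.masks, min_overlap=5)
            scored = score_table(cohort.behaviour)
            corrected = residualize(
                matrix, scored["motivational"].to_numpy(float), scored[["nihss", "age", "sex"]]
            )
            res = cross_validate(
                corrected, SvrLsmConfig(n_permutations=100, seed=seed), param_grid=grid
            )
            wins += res.correlation > 0
            assert set(res.best_params) == {"C", "gamma"}
        assert wins >= 14

    def test_null_cv_correlation_centred_on_zero(self):
        """Pure-noise behaviour on realistic cohorts: the out-of-fold
        correlation is distributed around zero (|mean| < 0.1, 50 runs)."""
        import dataclasses

        from psdlsm.madrs import score_table
        from psdlsm.synthetic import generate_cohort, recovery_benchmark_spec

        rs = []
        for seed in range(50):
            spec = dataclasses.replace(
                recovery_benchmark_spec(seed=seed),
                effect_sizes={"motivational": 0.0},
                volume_effect=0.0,
            )
            cohort = generate_cohort(spec)
            matrix = build_lesion_matrix(cohort.masks, min_overlap=5)
            scored = score_table(cohort.behaviour)
            corrected = residualize(
                matrix, scored["motivational"].to_numpy(float), scored[["nihss", "age", "sex"]]
            )
            rs.append(
                cross_validate(corrected, SvrLsmConfig(n_permutations=100, seed=seed)).correlation
            )
        assert abs(np.mean(rs)) < 0.1

    def test_leave_one_out_returns_finite_value(self):
        matrix, y, _ = signal_voxel_data(seed=13)
        corrected = residualize(matrix, y)
        config = SvrLsmConfig(n_permutations=100, cv_folds=matrix.n_patients)
        assert np.isfinite(cross_validate(corrected, config).correlation)

    def test_too_many_folds_rejected(self):
        matrix, y, _ = signal_voxel_data(seed=14)
        corrected = residualize(matrix, y)
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(corrected, SvrLsmConfig(n_permutations=100, cv_folds=1000))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(C=0.0), dict(gamma=-1.0), dict(epsilon=0.0), dict(n_permutations=50),
         dict(p_threshold=1.5), dict(tail="both"), dict(cv_folds=1)],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SvrLsmConfig(**kwargs)
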