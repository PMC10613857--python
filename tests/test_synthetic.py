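"""The synthetic cohort generator: determinism, geometry, planted structure."""

import numpy as np
import pandas as pd
import pytest

from psdlsm.lesion_io import lesion_volume_cm3
from psdlsm.madrs import DEFAULT_DOMAIN_SCHEME
from psdlsm.synthetic import (
    VOLUME_MEAN_CM3,
    CohortSpec,
    ball_region,
    damage_fraction,
    generate_behaviour,
    generate_cohort,
    generate_lesions,
    lognormal_params_for_volume,
    write_cohort,
)


def _null_spec(**kw):
    effects = {d: 0.0 for d in ("motivational", "emotional", "cognitive", "somatic", "anxiety")}
    return CohortSpec(effect_sizes=effects, volume_effect=0.0, **kw)


class TestSpecValidation:
    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)
        with pytest.raises(ValueError):
            CohortSpec(grid_shape=(4, 32, 32))
        with pytest.raises(ValueError):
            CohortSpec(hemisphere_ratio=1.5)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            CohortSpec(
                grid_shape=(16, 16, 16),
                critical_regions={"motivational": np.array([[20, 2, 2]])},
                effect_sizes={"motivational": 1.0},
                factor_loadings=np.zeros((10, 1)),
            )

    def test_loadings_shape_enforced(self):
        with pytest.raises(ValueError, match="factor_loadings"):
            CohortSpec(factor_loadings=np.zeros((10, 3)))


class TestLesions:
    def test_forced_single_voxel_volume(self):
        spec = CohortSpec(
            n_patients=1,
            volume_lognormal_params=(0.0, 1e-12),
            volume_range_cm3=(1e-9, 268.11),
            seed=3,
        )
        (mask,) = generate_lesions(spec)
        assert mask.n_lesioned == 1

    def test_same_seed_bitwise_identical_cohorts(self):
        spec = CohortSpec(n_patients=10, seed=42)
        a = generate_lesions(spec)
        b = generate_lesions(spec)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.grid, mb.grid)

    def test_full_right_ratio_puts_all_centroids_right(self):
        spec = CohortSpec(n_patients=100, hemisphere_ratio=1.0, seed=5)
        masks = generate_lesions(spec)
        mid = spec.grid_shape[0] / 2
        for m in masks:
            centroid_x = np.argwhere(m.grid)[:, 0].mean()
            assert centroid_x >= mid - 1  # growth may cross the midline slightly

    def test_volume_calibration_against_target(self):
        """Monte-Carlo volume of a default cohort is within 25% of the
        33.58 cm^3 calibration target."""
        spec = CohortSpec(n_patients=200, seed=8)
        masks = generate_lesions(spec)
        mean_vol = np.mean([lesion_volume_cm3(m) for m in masks])
        assert abs(mean_vol - VOLUME_MEAN_CM3) / VOLUME_MEAN_CM3 < 0.25

    def test_masks_are_connected(self):
        from scipy import ndimage

        spec = CohortSpec(n_patients=20, seed=9)
        for m in generate_lesions(spec):
            _, n_comp = ndimage.label(m.grid)
            assert n_comp == 1

    def test_impossible_volume_raises(self):
        spec = CohortSpec(
            n_patients=1,
            grid_shape=(8, 8, 8),
            voxel_size_mm=1.0,
            volume_lognormal_params=(15.0, 1e-12),
            volume_range_cm3=(1e-9, 1e9),
            seed=0,
        )
        with pytest.raises(ValueError, match="capacity"):
            generate_lesions(spec)

    def test_lognormal_moment_matching(self):
        mu, sigma = lognormal_params_for_volume(10.0, 5.0, voxel_volume_mm3=1000.0)
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.exp(sigma**2) - 1.0)
        assert mean == pytest.approx(10.0)  # in 1 cm^3 voxels
        assert sd == pytest.approx(5.0)


class TestBehaviour:
    def test_zero_effects_give_constant_items(self):
        spec = _null_spec(n_patients=5, noise_sd=0.0, seed=1)
        cohort = generate_cohort(spec)
        items = cohort.behaviour[[f"item_{i}" for i in range(1, 11)]].to_numpy()
        # latent scores are all zero; every item equals the clipped affine constant
        assert len(np.unique(items)) == 1
        assert cohort.latent_scores.to_numpy().max() == 0.0

    def test_strong_effect_orders_latent_scores_by_damage(self):
        spec = CohortSpec(
            n_patients=100,
            effect_sizes={d: (100.0 if d == "motivational" else 0.0)
                          for d in ("motivational", "emotional", "cognitive", "somatic", "anxiety")},
            noise_sd=0.01,
            volume_effect=0.0,
            seed=2,
        )
        cohort = generate_cohort(spec)
        dmg = cohort.damage_fractions["motivational"].to_numpy()
        latent = cohort.latent_scores["motivational"].to_numpy()
        if (dmg > 0).any() and (dmg == 0).any():
            assert latent[dmg > 0].min() > latent[dmg == 0].max()

    def test_planted_block_structure_in_item_correlations(self):
        """Within-domain item correlations exceed between-domain ones."""
        cohort = generate_cohort(CohortSpec(n_patients=2000, seed=4))
        items = cohort.behaviour[[f"item_{i}" for i in range(1, 11)]].to_numpy(float)
        R = np.corrcoef(items, rowvar=False)
        scheme = DEFAULT_DOMAIN_SCHEME
        within, between = [], []
        for a in range(10):
            for b in range(a + 1, 10):
                same = any(
                    {a + 1, b + 1} <= set(scheme.mapping[d]) for d in scheme.domains
                )
                (within if same else between).append(R[a, b])
        assert min(within) > max(between)

    def test_damage_fraction_matches_brute_force(self, rng):
        spec = CohortSpec(n_patients=5, seed=6)
        cohort = generate_cohort(spec)
        for name, region in cohort.critical_regions.items():
            region_set = {tuple(v) for v in region}
            for i, mask in enumerate(cohort.masks):
                lesion_set = {tuple(v) for v in np.argwhere(mask.grid)}
                expected = len(lesion_set & region_set) / len(region_set)
                assert damage_fraction(mask, region) == pytest.approx(expected)
                assert 0.0 <= expected <= 1.0

    def test_items_within_scale_bounds(self):
        cohort = generate_cohort(CohortSpec(n_patients=50, seed=10))
        items = cohort.behaviour[[f"item_{i}" for i in range(1, 11)]].to_numpy()
        assert items.min() >= 0 and items.max() <= 6

    def test_grid_mismatch_rejected(self):
        spec = CohortSpec(n_patients=3, seed=0)
        masks = generate_lesions(spec)
        other = CohortSpec(n_patients=3, grid_shape=(16, 16, 16), seed=0)
        with pytest.raises(ValueError, match="shape"):
            generate_behaviour(masks, other)


class TestCohortRoundTrip:
    def test_cohort_determinism_and_outputs(self, tmp_path):
        spec = CohortSpec(n_patients=6, seed=12)
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(c1.behaviour, c2.behaviour)
        write_cohort(c1, tmp_path)
        assert (tmp_path / "behaviour.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        assert len(list((tmp_path / "masks").glob("*.nii.gz"))) == 6

    def test_ball_region_is_clipped_to_grid(self):
        coords = ball_region((0, 0, 0), 2, (8, 8, 8))
        assert (coords >= 0).all()
        assert len(coords) < 33  # clipped at the corner
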