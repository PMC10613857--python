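"""Synthetic stroke cohorts with planted lesion-behaviour ground truth.

Real single-centre lesion cohorts are rarely shareable, so every stage of
the mapping pipeline is exercised on simulated cohorts whose generating
process is fully known.  The generator emulates the salient features of an
acute ischaemic stroke sample:

* spatially coherent, connected lesions grown by stochastic dilation from
  a random seed voxel (an Eden-type growth model, mimicking the compact
  spatial autocorrelation of infarcts);
* a right-hemisphere excess of lesions (aphasic patients with left-sided
  lesions are under-sampled in interview-based depression studies);
* log-normal lesion volumes calibrated to a mean of 33.58 cm^3 with SD
  50.91 cm^3 and range 0.01-268.11 cm^3;
* behaviour driven by damage to planted critical regions: each latent
  symptom domain is ``effect_size * damage_fraction + volume_effect *
  normalized_volume + Gaussian noise``, and the ten MADRS items arise from
  a 10 x 5 loading matrix over the latent domains, affinely mapped and
  rounded to the 0-6 integer scale;
* NIHSS, age and sex drawn independently of the latent symptoms (so any
  downstream association with them is a false positive by construction).

All randomness flows from one integer seed through named substreams; the
same (spec, seed) always reproduces the identical cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from psdlsm.lesion_io import LesionMask, lesion_volume_cm3, write_mask
from psdlsm.madrs import DEFAULT_DOMAIN_SCHEME, N_ITEMS, DomainScheme

#: Lesion-volume summary the volume model is calibrated to (cm^3).
VOLUME_MEAN_CM3 = 33.58
VOLUME_SD_CM3 = 50.91
VOLUME_RANGE_CM3 = (0.01, 268.11)

#: Right:left seeding ratio emulating a 104:81 right:left lesion-side split
#: (bilateral lesions emerge when growth crosses the midline).
DEFAULT_HEMISPHERE_RATIO = 104 / 185

#: Reference range used to rescale latent item values onto the 0-6 scale.
ITEM_REFERENCE_RANGE = (-2.0, 10.0)


def lognormal_params_for_volume(
    mean_cm3: float = VOLUME_MEAN_CM3,
    sd_cm3: float = VOLUME_SD_CM3,
    voxel_volume_mm3: float = 125.0,
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal over lesion volume *in voxels*.

    Moment matching: for target mean m and SD s (in voxels),
    sigma^2 = ln(1 + (s/m)^2) and mu = ln(m) - sigma^2 / 2.
    """
    mean_vox = mean_cm3 * 1000.0 / voxel_volume_mm3
    cv2 = (sd_cm3 / mean_cm3) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean_vox) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def ball_region(center: tuple[int, int, int], radius: int, grid_shape) -> np.ndarray:
    """Voxel coordinates of a discrete ball clipped to the grid."""
    c = np.asarray(center)
    lo = np.maximum(c - radius, 0)
    hi = np.minimum(c + radius + 1, grid_shape)
    coords = np.stack(
        np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    keep = ((coords - c) ** 2).sum(axis=1) <= radius**2
    return coords[keep]


def default_critical_regions(
    grid_shape: tuple[int, int, int], radius: int = 2
) -> dict[str, np.ndarray]:
    """Planted critical regions, one compact ball per symptom domain.

    Four domains are planted in the right half of the grid and anxiety in
    the left half, mirroring the symptom-specific lateralization the
    pipeline is meant to resolve.  The left-right axis is array axis 0.
    """
    nx, ny, nz = grid_shape
    qx_r, qx_l = 3 * nx // 4, nx // 4
    dy, dz = max(2, ny // 8), max(2, nz // 8)
    positions = {
        "motivational": (qx_r, ny // 2 - dy, nz // 2),
        "emotional": (qx_r, ny // 2 + dy, nz // 2),
        "cognitive": (qx_r, ny // 2, nz // 2 + dz),
        "somatic": (qx_r, ny // 2, nz // 2 - dz),
        "anxiety": (qx_l, ny // 2, nz // 2),
    }
    return {name: ball_region(p, radius, grid_shape) for name, p in positions.items()}


def _default_loadings(scheme: DomainScheme = DEFAULT_DOMAIN_SCHEME) -> np.ndarray:
    """Indicator loadings: item i loads 1.0 on the domain that contains it."""
    L = np.zeros((N_ITEMS, len(scheme.domains)))
    for d, name in enumerate(scheme.domains):
        for i in scheme.items_of(name):
            L[i - 1, d] = 1.0
    return L


@dataclass
class CohortSpec:
    """Generating conditions for one synthetic cohort.

    Defaults reproduce the emulated study conditions: 200 patients on a
    32^3 grid of 5 mm voxels (a 160 mm box, brain-like extent at coarse
    resolution), right-lateralized log-normal lesion volumes, and one
    planted critical region per symptom domain with an effect size of
    three latent units at full damage against unit-SD latent noise.
    """

    n_patients: int = 200
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 5.0
    critical_regions: dict[str, np.ndarray] = field(default_factory=dict)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    volume_effect: float = 0.5
    noise_sd: float = 1.0
    hemisphere_ratio: float = DEFAULT_HEMISPHERE_RATIO
    seeding: str = "central"
    seed_spread_voxels: float | None = None
    volume_lognormal_params: tuple[float, float] | None = None
    volume_range_cm3: tuple[float, float] = VOLUME_RANGE_CM3
    factor_loadings: np.ndarray | None = None
    item_reference_range: tuple[float, float] = ITEM_REFERENCE_RANGE
    age_range: tuple[float, float] = (45.0, 90.0)
    p_female: float = 114 / 200
    nihss_mean_sd: tuple[float, float] = (12.85, 4.56)
    nihss_range: tuple[int, int] = (0, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.grid_shape) != 3 or any(d < 8 for d in self.grid_shape):
            raise ValueError("grid_shape must be 3D with every dimension >= 8")
        if not 0.0 <= self.hemisphere_ratio <= 1.0:
            raise ValueError("hemisphere_ratio must be in [0, 1]")
        if self.seeding not in ("central", "uniform"):
            raise ValueError("seeding must be 'central' or 'uniform'")
        if not self.critical_regions:
            self.critical_regions = default_critical_regions(self.grid_shape)
        for name, coords in self.critical_regions.items():
            coords = np.asarray(coords, dtype=int)
            if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
                raise ValueError(f"critical region {name!r} must be a (k, 3) voxel array")
            if (coords < 0).any() or (coords >= np.array(self.grid_shape)).any():
                raise ValueError(f"critical region {name!r} lies outside the grid")
            self.critical_regions[name] = coords
        if not self.effect_sizes:
            self.effect_sizes = {name: 3.0 for name in self.critical_regions}
        if set(self.effect_sizes) != set(self.critical_regions):
            raise ValueError("effect_sizes keys must match critical_regions keys")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.volume_lognormal_params is None:
            self.volume_lognormal_params = lognormal_params_for_volume(
                voxel_volume_mm3=self.voxel_size_mm**3
            )
        if self.factor_loadings is None:
            self.factor_loadings = _default_loadings()
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        if self.factor_loadings.shape != (N_ITEMS, len(self.critical_regions)):
            raise ValueError(
                "factor_loadings must be "
                f"{N_ITEMS} x {len(self.critical_regions)}, got "
                f"{self.factor_loadings.shape}"
            )

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.critical_regions)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclass
class SyntheticCohort:
    """Masks, behaviour table and the ground truth that generated them."""

    masks: list[LesionMask]
    behaviour: pd.DataFrame
    critical_regions: dict[str, np.ndarray]
    damage_fractions: pd.DataFrame
    latent_scores: pd.DataFrame
    spec: CohortSpec


_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _grow_lesion(
    rng: np.random.Generator, grid_shape, seed_voxel: np.ndarray, target: int
) -> np.ndarray:
    """Grow one connected lesion by stochastic dilation (Eden growth).

    Starting from the seed voxel, candidate boundary voxels are added one
    at a time, chosen uniformly from the current frontier; growth stops at
    the target volume or when the grid boundary exhausts the frontier.
    """
    shape = np.asarray(grid_shape)
    grid = np.zeros(tuple(grid_shape), dtype=np.uint8)
    grid[tuple(seed_voxel)] = 1
    frontier: list[tuple[int, int, int]] = []
    in_frontier = np.zeros(tuple(grid_shape), dtype=bool)

    def push_neighbours(vox: np.ndarray) -> None:
        for nb in vox + _NEIGHBOURS:
            if ((nb >= 0) & (nb < shape)).all():
                t = tuple(nb)
                if not grid[t] and not in_frontier[t]:
                    frontier.append(t)
                    in_frontier[t] = True

    push_neighbours(seed_voxel)
    n = 1
    while n < target and frontier:
        k = rng.integers(len(frontier))
        vox = frontier[k]
        frontier[k] = frontier[-1]
        frontier.pop()
        in_frontier[vox] = False
        grid[vox] = 1
        n += 1
        push_neighbours(np.asarray(vox))
    return grid


def generate_lesions(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[LesionMask]:
    """Generate one connected lesion mask per patient.

    Volumes are drawn from the spec's log-normal (clipped to the
    configured cm^3 range and to one voxel minimum); seed voxels fall in
    the right half of axis 0 with probability ``hemisphere_ratio``.
    """
    if rng is None:
        rng = np.random.default_rng([0, spec.seed])
    capacity = int(np.prod(spec.grid_shape))
    voxel_vol = spec.voxel_size_mm**3
    lo = max(1, int(round(spec.volume_range_cm3[0] * 1000.0 / voxel_vol)))
    hi = int(round(spec.volume_range_cm3[1] * 1000.0 / voxel_vol))
    mu, sigma = spec.volume_lognormal_params
    masks = []
    nx = spec.grid_shape[0]
    for i in range(spec.n_patients):
        target = int(round(float(rng.lognormal(mu, sigma))))
        target = min(max(target, lo), hi)
        if target > capacity:
            raise ValueError(
                f"patient {i}: target lesion volume {target} voxels exceeds "
                f"grid capacity {capacity}"
            )
        right = rng.random() < spec.hemisphere_ratio
        x_lo, x_hi = (nx // 2, nx) if right else (0, nx // 2)
        if spec.seeding == "central":
            # Gaussian seeding around the hemisphere centre emulates the
            # clustering of infarcts in the middle-cerebral-artery
            # territory, which concentrates cohort-level lesion overlap
            # centrally (as real overlap maps peak at putamen/insula).
            centre = np.array(
                [(x_lo + x_hi) / 2.0, spec.grid_shape[1] / 2.0, spec.grid_shape[2] / 2.0]
            )
            if spec.seed_spread_voxels is not None:
                spread = np.full(3, float(spec.seed_spread_voxels))
            else:
                spread = np.array([x_hi - x_lo, spec.grid_shape[1], spec.grid_shape[2]]) / 5.0
            seed_voxel = np.round(rng.normal(centre, spread)).astype(int)
            seed_voxel = np.clip(
                seed_voxel,
                [x_lo, 0, 0],
                [x_hi - 1, spec.grid_shape[1] - 1, spec.grid_shape[2] - 1],
            )
        else:
            seed_voxel = np.array(
                [
                    rng.integers(x_lo, x_hi),
                    rng.integers(0, spec.grid_shape[1]),
                    rng.integers(0, spec.grid_shape[2]),
                ]
            )
        grid = _grow_lesion(rng, spec.grid_shape, seed_voxel, target)
        masks.append(
            LesionMask(
                grid=grid,
                affine=spec.affine(),
                voxel_size_mm=(spec.voxel_size_mm,) * 3,
                patient_id=f"sub-{i + 1:04d}",
            )
        )
    return masks


def damage_fraction(mask: LesionMask, region: np.ndarray) -> float:
    """Fraction of a region's voxels covered by the lesion, in [0, 1]."""
    region = np.asarray(region, dtype=int)
    return float(mask.grid[tuple(region.T)].sum() / len(region))


def _discretize_items(latent_items: np.ndarray, reference_range: tuple[float, float]) -> np.ndarray:
    """Rescale latent item values to 0-6, round half up, clip to range."""
    lo, hi = reference_range
    scaled = (latent_items - lo) / (hi - lo) * 6.0
    return np.clip(np.floor(scaled + 0.5), 0, 6).astype(int)


def generate_behaviour(
    masks: list[LesionMask],
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate MADRS items and covariates from planted lesion damage.

    Returns ``(behaviour, damage_fractions, latent_scores)``.  The latent
    score for domain d of patient i is

        effect_size_d * damage_fraction(i, region_d)
        + volume_effect * volume_i / max(volume)
        + N(0, noise_sd),

    and the ten items are ``factor_loadings @ latent`` rescaled to the
    0-6 integer scale.  NIHSS, age and sex are drawn independently of the
    latent scores.
    """
    if not masks:
        raise ValueError("need at least one lesion mask")
    for m in masks:
        if m.grid.shape != tuple(spec.grid_shape):
            raise ValueError(
                f"mask for patient {m.patient_id!r} has shape {m.grid.shape}, "
                f"spec grid is {tuple(spec.grid_shape)}"
            )
    if rng is None:
        rng = np.random.default_rng([1, spec.seed])
    n = len(masks)
    domains = spec.domains
    damage = np.array(
        [[damage_fraction(m, spec.critical_regions[d]) for d in domains] for m in masks]
    )
    volumes = np.array([lesion_volume_cm3(m) for m in masks])
    norm_vol = volumes / volumes.max() if volumes.max() > 0 else volumes
    effects = np.array([spec.effect_sizes[d] for d in domains])
    latent = (
        damage * effects
        + spec.volume_effect * norm_vol[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(n, len(domains)))
    )
    items = _discretize_items(latent @ spec.factor_loadings.T, spec.item_reference_range)

    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.random(n) < spec.p_female).astype(int)
    nihss = np.clip(
        np.round(rng.normal(*spec.nihss_mean_sd, size=n)), *spec.nihss_range
    ).astype(int)
    ids = [m.patient_id for m in masks]
    behaviour = pd.DataFrame({"patient_id": ids})
    for j in range(N_ITEMS):
        behaviour[f"item_{j + 1}"] = items[:, j]
    behaviour["nihss"] = nihss
    behaviour["age"] = np.round(age, 1)
    behaviour["sex"] = sex
    behaviour["lesion_volume_cm3"] = volumes
    damage_df = pd.DataFrame(damage, columns=list(domains), index=ids)
    latent_df = pd.DataFrame(latent, columns=list(domains), index=ids)
    return behaviour, damage_df, latent_df


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full cohort (lesions + behaviour) from one spec/seed."""
    masks = generate_lesions(spec, np.random.default_rng([0, spec.seed]))
    behaviour, damage_df, latent_df = generate_behaviour(
        masks, spec, np.random.default_rng([1, spec.seed])
    )
    return SyntheticCohort(
        masks=masks,
        behaviour=behaviour,
        critical_regions=spec.critical_regions,
        damage_fractions=damage_df,
        latent_scores=latent_df,
        spec=spec,
    )


def recovery_benchmark_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec of the planted-region recovery benchmark.

    A focused power experiment for the mapping machinery: one critical
    region (radius-2 ball, 33 voxels, right hemisphere centre) drives a
    single domain score with a strong focal effect (8x the latent noise
    SD); lesions are small focal infarcts (log-normal, mean ~22 voxels,
    about 2.8 cm^3 at 5 mm voxels) seeded tightly around the region so
    that lesion extent is commensurate with the region.  In this regime
    the lesion status of a voxel decorrelates from region damage within a
    voxel or two of the region surface, so recovery can be scored
    sharply; with cohort-scale lesions (tens of cm^3) every neighbouring
    voxel is genuinely damage-coupled and no voxel-wise method can
    separate them.
    """
    grid = (32, 32, 32)
    region = ball_region((24, 16, 16), 2, grid)
    loadings = np.zeros((N_ITEMS, 1))
    loadings[6] = loadings[7] = 1.0  # lassitude + inability to feel
    return CohortSpec(
        n_patients=200,
        grid_shape=grid,
        critical_regions={"motivational": region},
        effect_sizes={"motivational": 8.0},
        volume_lognormal_params=(3.0, 0.5),
        hemisphere_ratio=1.0,
        seed_spread_voxels=2.0,
        factor_loadings=loadings,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write masks (.nii.gz), behaviour CSV and ground-truth JSON."""
    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    for m in cohort.masks:
        write_mask(m, mask_dir / f"{m.patient_id}_lesion.nii.gz")
    cohort.behaviour.to_csv(out_dir / "behaviour.csv", index=False)
    truth = {
        "critical_regions": {
            name: coords.tolist() for name, coords in cohort.critical_regions.items()
        },
        "damage_fractions": cohort.damage_fractions.round(6).to_dict(orient="index"),
        "seed": cohort.spec.seed,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth))
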