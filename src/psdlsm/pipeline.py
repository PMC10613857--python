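"""Orchestration of the full study replica.

One run executes, in order: MADRS scoring, factor analysis of the items,
eleven SVR-LSM analyses (the global sum, the five conceptual-empirical
domain scores and the five data-driven factor scores), the five
domain-vs-matched-factor Dice comparisons, and the sample-level covariate
statistics.  Every stage draws its randomness from the single study seed,
so a rerun with the same configuration reproduces the identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from psdlsm import lesion_io
from psdlsm.cohort_stats import correlation_report
from psdlsm.factors import FactorSolution, fit_factors, match_factors
from psdlsm.lesion_io import build_lesion_matrix, write_mask
from psdlsm.madrs import DEFAULT_DOMAIN_SCHEME, DomainScheme, score_table
from psdlsm.map_compare import dice
from psdlsm.svrlsm import SignificanceMap, SvrLsmConfig, run_analysis
from psdlsm.synthetic import CohortSpec, generate_cohort
from psdlsm.synthetic import _default_loadings as _scheme_loadings


@dataclass
class StudyConfig:
    """Inputs and settings for one end-to-end study run.

    Either a synthetic ``cohort_spec`` or paths to real data
    (``masks_dir`` with one NIfTI per patient and ``behaviour_csv`` with
    ``patient_id, item_1..item_10, nihss, age, sex``) must be provided.
    """

    cohort_spec: CohortSpec | None = None
    masks_dir: str | None = None
    behaviour_csv: str | None = None
    svr: SvrLsmConfig = field(default_factory=SvrLsmConfig)
    scheme: DomainScheme = DEFAULT_DOMAIN_SCHEME
    n_factors: int = 5
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_spec is None and (self.masks_dir is None or self.behaviour_csv is None):
            raise ValueError("provide either cohort_spec or masks_dir + behaviour_csv")


@dataclass
class RunManifest:
    """Record of one study run sufficient to reproduce and audit it."""

    seed: int
    config_echo: dict
    analyses: dict[str, dict]
    dice_rows: list[dict]
    map_hashes: dict[str, str]
    stats_path: str | None
    elapsed_s: float

    @property
    def n_significance_maps(self) -> int:
        return len(self.analyses)

    @property
    def n_dice(self) -> int:
        return len(self.dice_rows)

    def digest(self) -> str:
        """Single hash over all map hashes and Dice values."""
        h = hashlib.sha256()
        for name in sorted(self.map_hashes):
            h.update(name.encode())
            h.update(self.map_hashes[name].encode())
        for row in self.dice_rows:
            h.update(json.dumps(row, sort_keys=True).encode())
        return h.hexdigest()

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["digest"] = self.digest()
        payload["n_significance_maps"] = self.n_significance_maps
        payload["n_dice"] = self.n_dice
        return json.dumps(payload, indent=2, default=str)


def _hash_grid(grid: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(grid).tobytes()).hexdigest()


def _load_real_cohort(config: StudyConfig):
    mask_paths = sorted(Path(config.masks_dir).glob("*.nii*"))
    if not mask_paths:
        raise FileNotFoundError(f"no NIfTI masks in {config.masks_dir!r}")
    masks = [lesion_io.read_mask(p, patient_id=p.stem) for p in mask_paths]
    behaviour = pd.read_csv(config.behaviour_csv)
    if len(behaviour) != len(masks):
        raise ValueError(
            f"behaviour table has {len(behaviour)} rows but {len(masks)} masks found"
        )
    return masks, behaviour


def run_study(config: StudyConfig) -> RunManifest:
    """Run the complete study replica and return its manifest.

    Emits exactly eleven significance maps (global + five domains + five
    factors) and five Dice comparisons of each conceptual domain map with
    its congruence-matched data-driven factor map.
    """
    t0 = time.time()
    if config.cohort_spec is not None:
        spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
        cohort = generate_cohort(spec)
        masks, behaviour = cohort.masks, cohort.behaviour
    else:
        masks, behaviour = _load_real_cohort(config)

    scored = score_table(behaviour, config.scheme)
    item_cols = [f"item_{i}" for i in range(1, 11)]
    solution: FactorSolution = fit_factors(scored[item_cols], n_factors=config.n_factors)

    matrix = build_lesion_matrix(masks, min_overlap=config.svr.min_overlap)
    confounds = scored[["nihss", "age", "sex"]]

    analysis_scores: dict[str, np.ndarray] = {"global": scored["global_sum"].to_numpy(float)}
    for name in config.scheme.domains:
        analysis_scores[f"domain_{name}"] = scored[name].to_numpy(float)
    for j in range(config.n_factors):
        analysis_scores[f"factor_{j + 1}"] = solution.scores[:, j]

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "maps").mkdir(parents=True, exist_ok=True)

    sig_maps: dict[str, SignificanceMap] = {}
    analyses: dict[str, dict] = {}
    map_hashes: dict[str, str] = {}
    for idx, (name, score) in enumerate(analysis_scores.items()):
        cfg = config.svr.with_seed(config.seed + idx)
        _, pmap, sig = run_analysis(matrix, score, confounds, cfg)
        sig_maps[name] = sig
        map_hashes[name] = _hash_grid(sig.grid)
        analyses[name] = {
            "n_significant_voxels": sig.n_significant,
            "n_permutations": cfg.n_permutations,
            "seed": cfg.seed,
            "map_path": str(out_dir / "maps" / f"{name}_sig.nii.gz") if out_dir else None,
        }
        if out_dir:
            write_mask(sig.grid, out_dir / "maps" / f"{name}_sig.nii.gz", affine=matrix.affine)

    # Pair each conceptual domain with the data-driven factor whose loading
    # column is most congruent with the domain's item-indicator pattern.
    target = _scheme_loadings(config.scheme)
    perm, congruence = match_factors(solution.loadings, target)
    dice_rows: list[dict] = []
    for d, name in enumerate(config.scheme.domains):
        fac = f"factor_{perm[d] + 1}"
        dom = f"domain_{name}"
        row = {"domain": name, "factor": fac, "congruence": round(float(congruence[d]), 4)}
        try:
            res = dice(sig_maps[dom].grid, sig_maps[fac].grid)
            row.update(dc=round(res.dc, 4), category=res.category,
                       n_x=res.n_x, n_y=res.n_y, n_intersection=res.n_intersection)
        except ValueError:
            row.update(dc=float("nan"), category="undefined", n_x=0, n_y=0, n_intersection=0)
        dice_rows.append(row)

    score_cols = ["global_sum"] + list(config.scheme.domains)
    covariates = ["nihss", "age"]
    if "lesion_volume_cm3" not in scored.columns:
        scored = scored.assign(lesion_volume_cm3=matrix.lesion_volumes)
    covariates.append("lesion_volume_cm3")
    stats = correlation_report(scored, score_cols, covariates, sex_col="sex")

    stats_path = None
    if out_dir:
        stats_path = str(out_dir / "cohort_stats.csv")
        stats.to_csv(stats_path, index=False)
        pd.DataFrame(dice_rows).to_csv(out_dir / "dice.csv", index=False)
        scored.to_csv(out_dir / "scored_behaviour.csv", index=False)
        pd.DataFrame(
            solution.loadings,
            index=solution.item_names,
            columns=[f"factor_{j + 1}" for j in range(config.n_factors)],
        ).to_csv(out_dir / "factor_loadings.csv")

    manifest = RunManifest(
        seed=config.seed,
        config_echo={
            "svr": dataclasses.asdict(config.svr),
            "n_factors": config.n_factors,
            "scheme": {k: sorted(v) for k, v in config.scheme.mapping.items()},
            "synthetic": config.cohort_spec is not None,
        },
        analyses=analyses,
        dice_rows=dice_rows,
        map_hashes=map_hashes,
        stats_path=stats_path,
        elapsed_s=round(time.time() - t0, 2),
    )
    if out_dir:
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
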