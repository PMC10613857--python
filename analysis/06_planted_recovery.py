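"""Planted-region recovery benchmark.

One critical region drives the motivational domain score; the benchmark
measures how sharply the pipeline recovers it (Dice with the planted
region, in-region sensitivity, false coverage outside).  Writes per-seed
metrics to ``results/planted_recovery.csv``.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from psdlsm.lesion_io import build_lesion_matrix
from psdlsm.madrs import score_table
from psdlsm.map_compare import dice
from psdlsm.svrlsm import SvrLsmConfig, permutation_pmap, residualize, threshold_and_smooth
from psdlsm.synthetic import generate_cohort, recovery_benchmark_spec

RESULTS = Path("results")
SEEDS = range(1, 6)


def main() -> None:
    rows = []
    for seed in SEEDS:
        spec = recovery_benchmark_spec(seed=seed)
        cohort = generate_cohort(spec)
        matrix = build_lesion_matrix(cohort.masks, min_overlap=5)
        scored = score_table(cohort.behaviour)
        config = SvrLsmConfig(n_permutations=1000, seed=seed)
        corrected = residualize(
            matrix, scored["motivational"].to_numpy(float), scored[["nihss", "age", "sex"]]
        )
        sig = threshold_and_smooth(permutation_pmap(corrected, config), config)
        planted = np.zeros(spec.grid_shape, dtype=bool)
        planted[tuple(spec.critical_regions["motivational"].T)] = True
        rows.append(
            {
                "seed": seed,
                "dice": dice(sig.grid, planted).dc if sig.n_significant else 0.0,
                "sensitivity": float(sig.grid[planted].sum() / planted.sum()),
                "false_coverage_pct": float(
                    (sig.grid.astype(bool) & ~planted).sum() / (~planted).sum() * 100.0
                ),
                "n_significant": sig.n_significant,
            }
        )
    table = pd.DataFrame(rows).round(4)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "planted_recovery.csv", index=False)
    print(table.to_string(index=False))
    print(f"mean Dice {table['dice'].mean():.2f}, "
          f"mean sensitivity {table['sensitivity'].mean():.2f}, "
          f"max false coverage {table['false_coverage_pct'].max():.3f}%")


if __name__ == "__main__":
    main()
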