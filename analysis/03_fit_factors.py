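"""Data-driven corroboration: PCA + oblimin factor solution of the items.

Reads ``results/behaviour.csv`` and writes the rotated loadings, factor
correlations and per-patient factor scores under ``results/``.
"""

from pathlib import Path

import pandas as pd

from psdlsm.factors import explained_variance_at, fit_factors, match_factors
from psdlsm.synthetic import _default_loadings

RESULTS = Path("results")


def main() -> None:
    behaviour = pd.read_csv(RESULTS / "behaviour.csv")
    items = behaviour[[f"item_{i}" for i in range(1, 11)]]
    sol = fit_factors(items, n_factors=5)
    cols = [f"factor_{j + 1}" for j in range(5)]
    pd.DataFrame(sol.loadings, index=sol.item_names, columns=cols).round(3).to_csv(
        RESULTS / "factor_loadings.csv"
    )
    pd.DataFrame(sol.factor_correlations, index=cols, columns=cols).round(3).to_csv(
        RESULTS / "factor_correlations.csv"
    )
    pd.DataFrame(sol.scores, columns=cols).round(4).to_csv(
        RESULTS / "factor_scores.csv", index=False
    )

    print("eigenvalues:", ", ".join(f"{v:.2f}" for v in sol.eigenvalues))
    print(f"cumulative explained variance at 5 components: "
          f"{explained_variance_at(sol, 5):.1f}%")
    _, congruence = match_factors(sol.loadings, _default_loadings())
    print("Tucker congruence with the conceptual domain scheme:",
          ", ".join(f"{c:.2f}" for c in congruence))


if __name__ == "__main__":
    main()
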