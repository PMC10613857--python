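"""Score the cohort's MADRS interviews into domains and severity bands.

Reads ``results/behaviour.csv`` (from 01) and writes the scored table and
a severity summary under ``results/``.
"""

from pathlib import Path

import pandas as pd

from psdlsm.madrs import MadrsRecord, cohort_summary, score_table

RESULTS = Path("results")


def main() -> None:
    behaviour = pd.read_csv(RESULTS / "behaviour.csv")
    scored = score_table(behaviour)
    scored.to_csv(RESULTS / "scored_behaviour.csv", index=False)

    records = [
        MadrsRecord(tuple(int(v) for v in row))
        for row in behaviour[[f"item_{i}" for i in range(1, 11)]].to_numpy()
    ]
    summary = cohort_summary(records)
    pd.DataFrame(
        {"severity": list(summary.counts), "count": list(summary.counts.values()),
         "pct": [summary.percentages[k] for k in summary.counts]}
    ).to_csv(RESULTS / "severity_summary.csv", index=False)

    print(f"global sum: mean {scored['global_sum'].mean():.2f} "
          f"sd {scored['global_sum'].std(ddof=1):.2f}")
    for name in ("anxiety", "somatic", "emotional", "cognitive", "motivational"):
        print(f"  {name:13s} mean {scored[name].mean():.2f} (0-6 scale)")
    print("severity split:", ", ".join(f"{k} {v}%" for k, v in summary.percentages.items()))


if __name__ == "__main__":
    main()
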