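"""MADRS scoring: global sum, five symptom domains, severity categories.

The Montgomery-Asberg Depression Rating Scale has ten interview items,
each rated 0-6, giving a 0-60 global severity sum.  Items are grouped
into five conceptually defined symptom domains (motivational, emotional,
cognitive, somatic, anxiety); a domain's standardized score is its mean
item score, which puts all domains on the same 0-6 scale regardless of
how many items they contain.

Item order (1-based, as administered):
(1) apparent sadness, (2) reported sadness, (3) inner tension,
(4) reduced sleep, (5) reduced appetite, (6) concentration difficulties,
(7) lassitude, (8) inability to feel, (9) pessimistic thoughts,
(10) suicidal thoughts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ITEM_NAMES = (
    "apparent_sadness",
    "reported_sadness",
    "inner_tension",
    "reduced_sleep",
    "reduced_appetite",
    "concentration_difficulties",
    "lassitude",
    "inability_to_feel",
    "pessimistic_thoughts",
    "suicidal_thoughts",
)

N_ITEMS = 10
ITEM_MAX = 6

#: Conventional MADRS severity bands.  The cut-offs are configurable in
#: :func:`severity_category` because different clinical conventions exist.
DEFAULT_SEVERITY_CUTOFFS = {"none": (0, 6), "mild": (7, 19), "moderate": (20, 34), "severe": (35, 60)}
SEVERITY_ORDER = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class DomainScheme:
    """Partition of the ten items (1-based indices) into named domains."""

    mapping: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        all_items: set[int] = set()
        for name, items in self.mapping.items():
            if not items:
                raise ValueError(f"domain {name!r} has no items")
            if all_items & set(items):
                raise ValueError(f"domain {name!r} overlaps another domain")
            all_items |= set(items)
        if all_items != set(range(1, N_ITEMS + 1)):
            raise ValueError(
                f"domains must partition items 1..{N_ITEMS}, covered: {sorted(all_items)}"
            )

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.mapping)

    def items_of(self, domain: str) -> tuple[int, ...]:
        return tuple(sorted(self.mapping[domain]))


#: The conceptual-empirical five-domain scheme: motivational = lassitude +
#: inability to feel; emotional = apparent + reported sadness; cognitive =
#: concentration difficulties + pessimistic + suicidal thoughts; somatic =
#: reduced sleep + appetite; anxiety = inner tension.
DEFAULT_DOMAIN_SCHEME = DomainScheme(
    mapping={
        "motivational": frozenset({7, 8}),
        "emotional": frozenset({1, 2}),
        "cognitive": frozenset({6, 9, 10}),
        "somatic": frozenset({4, 5}),
        "anxiety": frozenset({3}),
    }
)


@dataclass
class MadrsRecord:
    """Ten MADRS item scores for one patient."""

    items: tuple[int, ...]
    patient_id: str = ""

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
        bad = [v for v in items if not 0 <= v <= ITEM_MAX]
        if bad:
            raise ValueError(
                f"MADRS items must be in 0..{ITEM_MAX}; patient "
                f"{self.patient_id!r} has {bad}"
            )
        object.__setattr__(self, "items", items)

    @property
    def global_sum(self) -> int:
        return sum(self.items)


@dataclass
class DomainScores:
    """Raw sums, per-item standardized means, and the global sum."""

    raw: dict[str, int]
    standardized: dict[str, float]
    global_sum: int


def score_domains(record: MadrsRecord, scheme: DomainScheme = DEFAULT_DOMAIN_SCHEME) -> DomainScores:
    """Score one interview into domain raw sums and standardized means.

    The standardized score divides the domain raw sum by its item count so
    that domains with different numbers of items are directly comparable
    on the 0-6 item scale.
    """
    raw: dict[str, int] = {}
    standardized: dict[str, float] = {}
    for name in scheme.domains:
        idx = scheme.items_of(name)
        s = sum(record.items[i - 1] for i in idx)
        raw[name] = s
        standardized[name] = s / len(idx)
    return DomainScores(raw=raw, standardized=standardized, global_sum=record.global_sum)


def score_table(
    items_table: pd.DataFrame, scheme: DomainScheme = DEFAULT_DOMAIN_SCHEME
) -> pd.DataFrame:
    """Score a cohort table with ``item_1..item_10`` columns.

    Returns a DataFrame with ``global_sum``, one standardized column per
    domain, and ``severity`` under the default cut-offs.  Any extra
    columns (``patient_id``, covariates) are carried through.
    """
    item_cols = [f"item_{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in item_cols if c not in items_table.columns]
    if missing:
        raise ValueError(f"behaviour table is missing item columns: {missing}")
    out = items_table.copy()
    records = [
        MadrsRecord(tuple(row), patient_id=str(i))
        for i, row in enumerate(items_table[item_cols].to_numpy())
    ]
    out["global_sum"] = [r.global_sum for r in records]
    for name in scheme.domains:
        out[name] = [score_domains(r, scheme).standardized[name] for r in records]
    out["severity"] = [severity_category(r.global_sum) for r in records]
    return out


def severity_category(
    global_sum: int, cutoffs: dict[str, tuple[int, int]] = DEFAULT_SEVERITY_CUTOFFS
) -> str:
    """Map a global sum to a severity band (closed integer intervals)."""
    if not 0 <= global_sum <= N_ITEMS * ITEM_MAX:
        raise ValueError(f"global sum {global_sum} outside 0..{N_ITEMS * ITEM_MAX}")
    for name, (lo, hi) in cutoffs.items():
        if lo <= global_sum <= hi:
            return name
    raise ValueError(f"severity cut-offs do not cover global sum {global_sum}")


@dataclass
class SeveritySummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


def cohort_summary(
    records: list[MadrsRecord],
    scheme: DomainScheme = DEFAULT_DOMAIN_SCHEME,
    cutoffs: dict[str, tuple[int, int]] = DEFAULT_SEVERITY_CUTOFFS,
) -> SeveritySummary:
    """Severity counts and percentages (to one decimal) for a cohort."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    counts = {name: 0 for name in cutoffs}
    for r in records:
        counts[severity_category(r.global_sum, cutoffs)] += 1
    n = len(records)
    pct = {name: round(100.0 * c / n, 1) for name, c in counts.items()}
    return SeveritySummary(counts=counts, percentages=pct, n=n)
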