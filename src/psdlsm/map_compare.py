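"""Dice overlap of significance maps and atlas-based cluster labelling.

The Dice coefficient DC(X, Y) = 2|X intersect Y| / (|X| + |Y|) quantifies
spatial agreement of two binary voxel sets and is banded into the
conventional similarity categories: low 0-0.19, low-moderate 0.20-0.39,
moderate 0.40-0.59, moderate-high 0.60-0.79, high 0.80-1.00.  Values are
rounded to two decimals before banding, matching the two-decimal band
edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DICE_CATEGORIES = (
    ("low", 0.00, 0.19),
    ("low-moderate", 0.20, 0.39),
    ("moderate", 0.40, 0.59),
    ("moderate-high", 0.60, 0.79),
    ("high", 0.80, 1.00),
)


def dice_category(dc: float) -> str:
    """Similarity band of a Dice value (closed 2-dp bands)."""
    if not 0.0 <= dc <= 1.0:
        raise ValueError(f"Dice coefficient must be in [0, 1], got {dc}")
    r = round(dc, 2)
    for name, lo, hi in DICE_CATEGORIES:
        if lo <= r <= hi:
            return name
    raise AssertionError("unreachable: bands cover [0, 1]")


@dataclass
class DiceResult:
    dc: float
    n_x: int
    n_y: int
    n_intersection: int
    category: str


def _as_binary_grid(mask) -> np.ndarray:
    grid = getattr(mask, "grid", mask)
    return np.asarray(grid) > 0


def dice(mask_x, mask_y) -> DiceResult:
    """Dice coefficient of two binary maps on the same grid.

    Raises if geometries differ or if both maps are empty (the
    coefficient is undefined for two empty sets).
    """
    x, y = _as_binary_grid(mask_x), _as_binary_grid(mask_y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    n_x, n_y = int(x.sum()), int(y.sum())
    if n_x + n_y == 0:
        raise ValueError("Dice coefficient is undefined for two empty masks")
    n_int = int((x & y).sum())
    dc = 2.0 * n_int / (n_x + n_y)
    return DiceResult(dc=dc, n_x=n_x, n_y=n_y, n_intersection=n_int, category=dice_category(dc))


def summarize_dice_set(dcs) -> tuple[float, float]:
    """Mean and sample (n-1) SD of a set of Dice values, to two decimals."""
    arr = np.asarray(list(dcs), dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least two Dice values for a sample SD")
    return round(float(arr.mean()), 2), round(float(arr.std(ddof=1)), 2)


def label_clusters(
    sig_map, atlas_volume: np.ndarray, label_table: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate connected significant clusters against a labelled atlas.

    Connected components use 26-connectivity.  ``label_table`` must map
    integer atlas ``code`` to ``name``; codes absent from the table are
    reported as "unlabelled".  Returns one row per (cluster, region) with
    voxel counts and within-cluster percentages, regions sorted descending
    by count within each cluster.
    """
    grid = _as_binary_grid(sig_map)
    atlas = np.asarray(atlas_volume)
    if atlas.shape != grid.shape:
        raise ValueError(f"atlas shape {atlas.shape} does not match map {grid.shape}")
    names = {int(c): str(n) for c, n in zip(label_table["code"], label_table["name"])}
    structure = np.ones((3, 3, 3), dtype=bool)
    labelled, n_clusters = ndimage.label(grid, structure=structure)
    rows = []
    for k in range(1, n_clusters + 1):
        in_cluster = labelled == k
        size = int(in_cluster.sum())
        codes, counts = np.unique(atlas[in_cluster], return_counts=True)
        order = np.argsort(counts)[::-1]
        for code, count in zip(codes[order], counts[order]):
            rows.append(
                {
                    "cluster": k,
                    "cluster_voxels": size,
                    "region": names.get(int(code), "unlabelled"),
                    "voxels": int(count),
                    "pct_of_cluster": round(100.0 * count / size, 1),
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster", "cluster_voxels", "region", "voxels", "pct_of_cluster"]
    )
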