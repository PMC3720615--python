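"""Moran's I spatial correlograms with permutation significance.

Spatial autocorrelation is summarized per distance class: cell pairs are
binned by planar distance (computed in the equal-area projection, km)
into a fixed number of classes — 10 by default — and within each class
Moran's I is computed with symmetric binary weights,

    I_c = (n / S0_c) * sum_{i!=j} w_ij (x_i - xbar)(x_j - xbar)
                     / sum_i (x_i - xbar)^2 ,

where w_ij = 1 iff pair (i, j) falls in class c and S0_c is the weight
sum.  Significance per class comes from a Monte-Carlo permutation test
(default 200 permutations) that randomly reassigns values to cells; the
two-sided p-value uses the +1 correction, p = (1 + #{|I_perm| >= |I_obs|})
/ (n_perm + 1), so p is never 0 and equals 1/201 when the observed value
beats every permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist


@dataclass
class DistanceClasses:
    """Pairwise cell distances binned into ascending distance classes.

    Stores the class edges (km) and, for every unordered cell pair, its
    indices and class assignment.  Intervals are half-open [e_i, e_{i+1})
    except the last, which is closed so the maximum-distance pair is
    binned.
    """

    edges_km: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_class: np.ndarray
    n_points: int

    @property
    def n_classes(self) -> int:
        return len(self.edges_km) - 1

    @property
    def pair_counts(self) -> np.ndarray:
        return np.bincount(self.pair_class, minlength=self.n_classes)


def make_distance_classes(
    coords_km: np.ndarray, n_classes: int = 10, rule: str = "equal_width"
) -> DistanceClasses:
    """Bin all unordered cell pairs into distance classes.

    rule="equal_width" (default): edges equally spaced from 0 to the
    maximum pairwise distance.  rule="equal_pairs": edges at empirical
    quantiles of the pairwise distances, so classes hold approximately
    equal numbers of pairs.
    """
    coords = np.asarray(coords_km, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 cells with 2-D coordinates")
    d = pdist(coords)
    dmax = float(d.max())
    if dmax == 0.0:
        raise ValueError("all cells coincident")
    if rule == "equal_width":
        edges = np.linspace(0.0, dmax, n_classes + 1)
    elif rule == "equal_pairs":
        qs = np.linspace(0.0, 1.0, n_classes + 1)
        edges = np.quantile(d, qs)
        edges[0], edges[-1] = 0.0, dmax
    else:
        raise ValueError(f"unknown binning rule {rule!r}")
    cls = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_classes - 1)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return DistanceClasses(
        edges_km=edges, pair_i=iu, pair_j=ju,
        pair_class=cls.astype(np.int32), n_points=n,
    )


def _center(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    z = values - values.mean()
    if np.sum(z * z) == 0.0:
        raise ValueError("zero variance: Moran's I undefined")
    return z


def _moran_all_classes(z: np.ndarray, dc: DistanceClasses) -> np.ndarray:
    """Moran's I for every class at once (NaN for empty classes)."""
    n = dc.n_points
    prods = z[dc.pair_i] * z[dc.pair_j]
    num = np.bincount(dc.pair_class, weights=prods, minlength=dc.n_classes)
    counts = dc.pair_counts
    ss = float(np.sum(z * z))
    with np.errstate(invalid="ignore", divide="ignore"):
        # symmetric weights double both the cross-product sum and S0,
        # so the factor 2 cancels
        return np.where(counts > 0, n * num / (counts * ss), np.nan)


def morans_i(values, dc: DistanceClasses, class_index: int) -> float:
    """Moran's I for one distance class (binary symmetric weights)."""
    if not 0 <= class_index < dc.n_classes:
        raise IndexError(f"class index {class_index} out of range")
    if dc.pair_counts[class_index] == 0:
        raise ValueError(f"distance class {class_index} holds no pairs")
    z = _center(values)
    if len(z) != dc.n_points:
        raise ValueError("values length inconsistent with distance classes")
    return float(_moran_all_classes(z, dc)[class_index])


def permutation_test(
    values, dc: DistanceClasses, class_index: int,
    n_perm: int = 200, seed: int = 0, alternative: str = "two-sided",
) -> float:
    """Monte-Carlo permutation p-value for Moran's I in one class."""
    i_obs = morans_i(values, dc, class_index)
    z = _center(values)
    rng = np.random.default_rng(seed)
    mask = dc.pair_class == class_index
    pi, pj = dc.pair_i[mask], dc.pair_j[mask]
    n = dc.n_points
    count = int(mask.sum())
    ss = float(np.sum(z * z))
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    i_perm = n * np.sum(perms[:, pi] * perms[:, pj], axis=1) / (count * ss)
    return _perm_pvalue(i_obs, i_perm, alternative)


def _perm_pvalue(i_obs: float, i_perm: np.ndarray, alternative: str) -> float:
    n_perm = len(i_perm)
    if alternative == "two-sided":
        extreme = np.sum(np.abs(i_perm) >= abs(i_obs) - 1e-15)
    elif alternative == "greater":
        extreme = np.sum(i_perm >= i_obs - 1e-15)
    elif alternative == "less":
        extreme = np.sum(i_perm <= i_obs + 1e-15)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + extreme) / (n_perm + 1))


@dataclass
class Correlogram:
    """Moran's I and permutation p-value per distance class."""

    table: pd.DataFrame  # class_lo_km, class_hi_km, pairs, moran_i, p_value
    meta: dict = field(default_factory=dict)

    @property
    def moran_i(self) -> np.ndarray:
        return self.table["moran_i"].to_numpy()

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def correlogram(
    values,
    coords_km,
    n_classes: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    rule: str = "equal_width",
    max_cells: int = 3000,
    alternative: str = "two-sided",
) -> Correlogram:
    """Full Moran's I correlogram with per-class permutation p-values.

    When more than ``max_cells`` cells are supplied, a seeded random
    subsample of ``max_cells`` cells is analysed (pair storage is
    quadratic in the cell count); the subsampling is recorded in the
    metadata.  Cells whose value is NaN are dropped first.  If the
    remaining values have zero variance, every class is flagged undefined
    (NaN I, NaN p).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords_km, dtype=float)
    keep = np.isfinite(values)
    values, coords = values[keep], coords[keep]
    rng = np.random.default_rng(seed)
    subsampled = False
    if len(values) > max_cells:
        idx = np.sort(rng.choice(len(values), size=max_cells, replace=False))
        values, coords = values[idx], coords[idx]
        subsampled = True
    dc = make_distance_classes(coords, n_classes=n_classes, rule=rule)
    meta = {
        "n_cells": int(len(values)), "n_perm": int(n_perm), "seed": int(seed),
        "subsampled": subsampled, "rule": rule, "alternative": alternative,
    }
    lo, hi = dc.edges_km[:-1], dc.edges_km[1:]
    counts = dc.pair_counts
    degenerate = np.ptp(values) == 0.0
    if degenerate:
        tbl = pd.DataFrame(
            {"class_lo_km": lo, "class_hi_km": hi, "pairs": counts,
             "moran_i": np.nan, "p_value": np.nan}
        )
        meta["degenerate"] = True
        return Correlogram(table=tbl, meta=meta)
    z = _center(values)
    i_all = _moran_all_classes(z, dc)
    n = dc.n_points
    ss = float(np.sum(z * z))
    # one permutation stream reused across classes: permute once, score all
    pvals = np.full(dc.n_classes, np.nan)
    perm_sums = np.zeros((n_perm, dc.n_classes))
    for p in range(n_perm):
        zp = rng.permutation(z)
        prods = zp[dc.pair_i] * zp[dc.pair_j]
        perm_sums[p] = np.bincount(dc.pair_class, weights=prods,
                                   minlength=dc.n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        i_perm = n * perm_sums / (counts[None, :] * ss)
    for c in range(dc.n_classes):
        if counts[c] > 0:
            pvals[c] = _perm_pvalue(float(i_all[c]), i_perm[:, c], alternative)
    tbl = pd.DataFrame(
        {"class_lo_km": lo, "class_hi_km": hi, "pairs": counts,
         "moran_i": i_all, "p_value": pvals}
    )
    return Correlogram(table=tbl, meta=meta)
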