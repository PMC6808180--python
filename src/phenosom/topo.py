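"""Two-sample two-dimensional Kolmogorov-Smirnov test on map coordinates.

Tests whether children holding a categorical label (a referral reason or a
diagnosis) occupy the same region of the trained map as children without
the label.  The statistic D is the largest absolute difference between the
two samples' quadrant fractions, maximized over all candidate origins and
all four quadrant orientations ({x<=x0 or x>x0} x {y<=y0 or y>y0}).
Candidate origins are every combination of an observed x coordinate with
an observed y coordinate, which on a finite grid provably attains the same
maximum as scanning every grid node.  Significance comes from a label
permutation test.

Points form a multiset: children sharing a BMU each contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DIAGNOSIS_FLAGS
from .som import TrainedSOM


@dataclass
class TopoTestResult:
    category_name: str
    D: float
    p_value: float
    n_members: int
    n_nonmembers: int
    n_permutations: int
    seed: int


def _quadrant_counts(points: np.ndarray, xs: np.ndarray, ys: np.ndarray
                     ) -> np.ndarray:
    """Integer counts of ``points`` in the (x<=x0, y<=y0) quadrant for every
    origin (x0, y0) in xs x ys; marginal counts let the other three
    orientations be derived by inclusion-exclusion."""
    ix = (points[:, 0][:, None] <= xs[None, :])     # n x nx
    iy = (points[:, 1][:, None] <= ys[None, :])     # n x ny
    joint = ix.astype(np.int64).T @ iy.astype(np.int64)   # nx x ny
    return joint, ix.sum(axis=0), iy.sum(axis=0)


def _max_quadrant_diff(jA, mxA, myA, nA, jB, mxB, myB, nB) -> float:
    """Max |F_A - F_B| over origins and the four orientations, computed in
    exact integer arithmetic (numerator of the common-denominator form)."""
    # counts for the four orientations per origin
    num = 0
    for cA, cB in (
        (jA, jB),
        (mxA[:, None] - jA, mxB[:, None] - jB),
        (myA[None, :] - jA, myB[None, :] - jB),
        (nA - mxA[:, None] - myA[None, :] + jA,
         nB - mxB[:, None] - myB[None, :] + jB),
    ):
        num = max(num, np.abs(cA * nB - cB * nA).max())
    return num / (nA * nB)


def ks2d_statistic(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Two-sample 2D KS statistic D in [0, 1].

    Origins run over every (observed x, observed y) combination from the
    pooled samples; quadrant membership uses closed boundaries on the
    "<=" sides and open on the ">" sides.
    """
    A = np.atleast_2d(np.asarray(points_a, dtype=float))
    B = np.atleast_2d(np.asarray(points_b, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("both samples must be nonempty")
    allp = np.vstack([A, B])
    xs = np.unique(allp[:, 0])
    ys = np.unique(allp[:, 1])
    jA, mxA, myA = _quadrant_counts(A, xs, ys)
    jB, mxB, myB = _quadrant_counts(B, xs, ys)
    return float(_max_quadrant_diff(jA, mxA, myA, len(A), jB, mxB, myB, len(B)))


def _d_for_memberships(points: np.ndarray, members: np.ndarray) -> np.ndarray:
    """D per membership row of a boolean matrix (B x n), vectorized.

    All rows must have the same member count (true for label permutations).
    """
    xs = np.unique(points[:, 0])
    ys = np.unique(points[:, 1])
    ix = (points[:, 0][:, None] <= xs[None, :]).astype(np.int64)
    iy = (points[:, 1][:, None] <= ys[None, :]).astype(np.int64)
    n = len(points)
    nA = int(members[0].sum())
    nB = n - nA
    # joint counts per permutation: contract over children
    # ind[t, i, j] would be ix[t, i] * iy[t, j]; build via per-threshold pair
    # products lazily to keep memory at (nx*ny) x n
    pair = (ix[:, :, None] * iy[:, None, :]).reshape(n, -1)   # n x (nx*ny)
    jA = members.astype(np.int64) @ pair                      # B x (nx*ny)
    jAll = pair.sum(axis=0)[None, :]
    mxA = members.astype(np.int64) @ ix
    myA = members.astype(np.int64) @ iy
    mxAll = ix.sum(axis=0)[None, :]
    myAll = iy.sum(axis=0)[None, :]
    jB = jAll - jA
    mxB = mxAll - mxA
    myB = myAll - myA
    nx, ny = len(xs), len(ys)
    num = np.zeros(members.shape[0], dtype=np.int64)
    for cA, cB in (
        (jA, jB),
        (np.repeat(mxA, ny, axis=1) - jA, np.repeat(mxB, ny, axis=1) - jB),
        (np.tile(myA, (1, nx)) - jA, np.tile(myB, (1, nx)) - jB),
        (nA - np.repeat(mxA, ny, axis=1) - np.tile(myA, (1, nx)) + jA,
         nB - np.repeat(mxB, ny, axis=1) - np.tile(myB, (1, nx)) + jB),
    ):
        np.maximum(num, np.abs(cA * nB - cB * nA).max(axis=1), out=num)
    return num / float(nA * nB)


def ks2d_permutation_test(
    bmu_coords: np.ndarray,
    membership: np.ndarray,
    n_permutations: int = 9999,
    seed: int = 0,
    category_name: str = "",
) -> TopoTestResult:
    """Permutation test of the 2D KS statistic on map coordinates.

    The null distribution shuffles which children are members;
    p = (1 + #{D_perm >= D_obs}) / (1 + n_permutations).
    """
    pts = np.asarray(bmu_coords, dtype=float)
    memb = np.asarray(membership, dtype=bool)
    if pts.shape[0] != memb.shape[0]:
        raise ValueError("membership length must match coordinate count")
    n_mem = int(memb.sum())
    n_non = int((~memb).sum())
    if n_mem < 2 or n_non < 2:
        raise ValueError(
            f"need >= 2 members and >= 2 nonmembers (got {n_mem}/{n_non})")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_permutations + 1, len(memb)), dtype=bool)
    rows[0] = memb
    for b in range(1, n_permutations + 1):
        rows[b] = rng.permutation(memb)
    d = _d_for_memberships(pts, rows)
    d_obs = d[0]
    # D values share an exact rational grid, so >= comparisons are exact up
    # to float rounding of a common-denominator integer; nudge by epsilon.
    n_ge = int(np.sum(d[1:] >= d_obs - 1e-12))
    p = (1 + n_ge) / (1 + n_permutations)
    return TopoTestResult(category_name, float(d_obs), float(p),
                          n_mem, n_non, n_permutations, seed)


def category_topography(
    som: TrainedSOM, labels: pd.DataFrame, category: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Split children's BMU grid coordinates by category membership.

    ``category`` is either a boolean label column (diagnosis flag) or
    ``"column=value"`` for categorical columns (e.g. referral reasons).
    """
    memb = category_membership(labels, category)
    coords = som.bmu_coords.astype(float)
    return coords[memb], coords[~memb]


def category_membership(labels: pd.DataFrame, category: str) -> np.ndarray:
    if "=" in category:
        col, value = category.split("=", 1)
        if col not in labels.columns:
            raise KeyError(f"unknown category column {col!r}")
        return (labels[col].astype(str) == value).to_numpy()
    if category not in labels.columns:
        raise KeyError(f"unknown category {category!r}")
    return labels[category].astype(bool).to_numpy()


DEFAULT_CATEGORIES = (
    ["referral_reason=attention", "referral_reason=memory",
     "referral_reason=language", "referral_reason=poor_school"]
    + [f for f in DIAGNOSIS_FLAGS if f != "sus_adhd"]
)


def run_topography_tests(
    som: TrainedSOM,
    labels: pd.DataFrame,
    categories: list[str] | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """2D KS permutation test for each category; one row per category."""
    if categories is None:
        categories = list(DEFAULT_CATEGORIES)
    rng = np.random.default_rng(seed)
    out = []
    coords = som.bmu_coords.astype(float)
    for cat in categories:
        memb = category_membership(labels, cat)
        res = ks2d_permutation_test(
            coords, memb, n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)), category_name=cat)
        out.append(dict(category=res.category_name, n_members=res.n_members,
                        n_nonmembers=res.n_nonmembers, D=res.D,
                        p_raw=res.p_value,
                        n_permutations=res.n_permutations, seed=res.seed))
    return pd.DataFrame(out)
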