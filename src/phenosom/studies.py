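"""Validation studies: calibration, recovery and oracle-agreement checks.

Each function here runs one self-contained study of the pipeline on
synthetic data and returns plain numbers.  The oracles (grid-scan 2D KS,
plain-loop Lloyd step) are deliberately written independently of the
implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import (DEFAULT_CLUSTER_MEANS, DEFAULT_CLUSTER_SIZES,
                     CohortGenConfig, CohortMatrix, ConnectomeGroupSpec,
                     generate_cohort, generate_connectomes)
from .connectome import regional_strength, two_stage_region_test
from .consensus import cluster_profile_table, consensus
from .groupstats import category_distribution_chi2, gender_gof_chi2
from .som import SOMConfig, batch_cycle
from .topo import ks2d_permutation_test, ks2d_statistic

#: Published per-cluster membership counts (cluster sizes 146/121/132/131)
#: and the gender splits of the four profile groups; these are inputs, used
#: to exercise the goodness-of-fit statistics.
PUBLISHED_CLUSTER_SIZES = (146, 121, 132, 131)
PUBLISHED_CATEGORY_COUNTS = {
    "attention": (36, 48, 52, 39),
    "memory": (16, 11, 12, 16),
    "language": (25, 7, 12, 15),
    "poor_school": (67, 51, 51, 58),
    "add_adhd": (29, 35, 22, 28),
    "slt": (43, 16, 15, 24),
    "dyslexia": (11, 9, 5, 5),
    "asd": (9, 6, 11, 6),
    "sus_adhd": (15, 14, 18, 10),
}
PUBLISHED_GENDER_SPLITS = {
    "cluster1": (87, 59), "cluster2": (83, 38),
    "cluster3": (105, 27), "cluster4": (91, 40),
}
PUBLISHED_OVERALL_GENDER = (366, 164)


def chi2_worked_examples() -> dict[str, float]:
    """Recompute every categorical chi-square from the published counts."""
    out = {}
    for name, counts in PUBLISHED_CATEGORY_COUNTS.items():
        out[f"{name}_chi2"] = category_distribution_chi2(
            counts, PUBLISHED_CLUSTER_SIZES).chi2
    for name, mf in PUBLISHED_GENDER_SPLITS.items():
        out[f"gender_{name}_chi2"] = gender_gof_chi2(
            mf, PUBLISHED_OVERALL_GENDER)[0]
    return out


# ---------------------------------------------------------------------------
# 2D KS studies


def _grid_scan_d(points_a: np.ndarray, points_b: np.ndarray,
                 grid: int = 10) -> float:
    """Oracle: every grid node as origin, all four quadrant orientations."""
    best = 0.0
    for x0 in range(grid):
        for y0 in range(grid):
            for sx in (True, False):
                for sy in (True, False):
                    def frac(p):
                        inx = (p[:, 0] <= x0) if sx else (p[:, 0] > x0)
                        iny = (p[:, 1] <= y0) if sy else (p[:, 1] > y0)
                        return float(np.mean(inx & iny))
                    best = max(best, abs(frac(points_a) - frac(points_b)))
    return best


def ks2d_oracle_agreement(n_instances: int = 200, seed: int = 0
                          ) -> tuple[int, float]:
    """Compare the statistic with the grid-scan oracle on random instances.

    Returns (number of exactly agreeing instances, max absolute deviation).
    """
    rng = np.random.default_rng(seed)
    n_equal, worst = 0, 0.0
    for _ in range(n_instances):
        na = int(rng.integers(5, 21))
        nb = int(rng.integers(5, 21))
        a = rng.integers(0, 10, (na, 2)).astype(float)
        b = rng.integers(0, 10, (nb, 2)).astype(float)
        d = ks2d_statistic(a, b)
        o = _grid_scan_d(a, b)
        diff = abs(d - o)
        worst = max(worst, diff)
        if diff < 1e-12:
            n_equal += 1
    return n_equal, worst


def ks2d_null_calibration(n_replicates: int = 500, n_points: int = 100,
                          n_permutations: int = 200, alpha: float = 0.05,
                          seed: int = 0) -> float:
    """Empirical type-I error of the permutation test under a true null.

    Membership is assigned independently of map position, so rejections at
    level alpha should occur at rate ~alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        coords = rng.integers(0, 10, (n_points, 2)).astype(float)
        memb = np.zeros(n_points, dtype=bool)
        memb[: n_points // 4] = True
        memb = rng.permutation(memb)
        res = ks2d_permutation_test(coords, memb, n_permutations,
                                    seed=int(rng.integers(2**31)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_replicates


# ---------------------------------------------------------------------------
# Consensus recovery


def _matched_agreement(modal: np.ndarray, truth: np.ndarray, k: int) -> float:
    conf = np.zeros((k, k))
    for a, b in zip(modal, truth):
        conf[int(a), int(b)] += 1
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(modal))


def consensus_recovery_study(
    n_seeds: int = 10, n_iterations: int = 200, seed: int = 0,
    n_label_permutations: int = 999,
) -> dict:
    """Recover the generating clusters at the published sizes and means.

    For each master seed: generate the default cohort (sd 0.5), run the
    consensus pipeline on the seven cognitive measures, measure
    best-matched agreement with the generating clusters together with a
    label-permutation p-value, the fraction of children with a clear
    (p < 0.05) modal cluster, and the aligned cluster-profile table.
    """
    rng = np.random.default_rng(seed)
    gen_means = DEFAULT_CLUSTER_MEANS.to_numpy()
    sizes = np.asarray(DEFAULT_CLUSTER_SIZES)
    agreements, perm_ps, clear_fracs, consistencies, tables = [], [], [], [], []
    for s in range(n_seeds):
        cohort, labels = generate_cohort(
            CohortGenConfig(seed=int(rng.integers(2**31))))
        cols = cohort.family_columns("cognitive")
        cm = CohortMatrix(cohort.scores[cols], {c: "cognitive" for c in cols})
        res = consensus(cm, SOMConfig(init_jitter_sd=0.05), k=4,
                        n_iterations=n_iterations,
                        seed=int(rng.integers(2**31)))
        truth = labels["generating_cluster"].to_numpy() - 1
        agree = _matched_agreement(res.modal_cluster, truth, 4)
        null_ge = 0
        for _ in range(n_label_permutations):
            shuffled = rng.permutation(res.modal_cluster)
            if _matched_agreement(shuffled, truth, 4) >= agree:
                null_ge += 1
        perm_ps.append((1 + null_ge) / (1 + n_label_permutations))
        agreements.append(agree)
        clear_fracs.append(float((res.clarity_p < 0.05).mean()))
        consistencies.append(float(res.consistency.mean()))
        prof = cluster_profile_table(cohort, res.modal_cluster, k=4)
        means = prof[[f"{m}_mean" for m in cohort.measures]].to_numpy()
        cost = ((means[:, None, :] - gen_means[None, :, :]) ** 2).sum(-1)
        r, c = linear_sum_assignment(cost)
        aligned = np.empty_like(means)
        aligned[c] = means[r]
        tables.append(aligned)
    avg_table = np.mean(tables, axis=0)
    se = 0.5 / np.sqrt(sizes)[:, None]
    dev_se = np.abs(avg_table - gen_means) / se
    return {
        "agreements": agreements,
        "perm_ps": perm_ps,
        "clear_fracs": clear_fracs,
        "mean_consistencies": consistencies,
        "avg_profile_dev_se": dev_se,
        "avg_profile_table": avg_table,
    }


# ---------------------------------------------------------------------------
# Lloyd equivalence


def _lloyd_step(centroids: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Independent k-means update oracle written with plain loops."""
    out = centroids.copy()
    assign = []
    for x in X:
        d = [float(np.dot(x - c, x - c)) for c in centroids]
        assign.append(int(np.argmin(d)))
    for i in range(len(centroids)):
        members = [x for x, a in zip(X, assign) if a == i]
        if members:
            out[i] = np.mean(members, axis=0)
    return out


def lloyd_equivalence(n_instances: int = 50, seed: int = 0) -> float:
    """Max |batch_cycle(ND=0) - Lloyd oracle| over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_nodes = int(rng.integers(2, 8))
        n_obs = int(rng.integers(3, 15))
        dim = int(rng.integers(1, 4))
        W = rng.standard_normal((n_nodes, dim))
        X = rng.standard_normal((n_obs, dim))
        gd = np.where(np.eye(n_nodes, dtype=bool), 0.0, np.inf)
        worst = max(worst, float(np.abs(
            batch_cycle(W, X, 0.0, gd) - _lloyd_step(W, X)).max()))
    return worst


# ---------------------------------------------------------------------------
# Two-stage connectome procedure


def planted_deficit_sensitivity(
    n_replicates: int = 100, n_rois: int = 30, deficit_roi: int = 5,
    effect_sd_units: float = 1.5, group_ns: tuple[int, int, int] = (40, 40, 36),
    noise_sd: float = 0.1, seed: int = 0,
) -> float:
    """Fraction of replicates in which a planted single-ROI deficit is
    selected by the two-stage test.

    The edge-level delta is chosen so the ROI's strength drops by
    ``effect_sd_units`` per-child standard deviations (strength sd is
    sqrt(n_rois - 1) * noise_sd for independent edges).
    """
    delta = effect_sd_units * noise_sd / np.sqrt(n_rois - 1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        specs = {
            "deficit": ConnectomeGroupSpec(group_ns[0],
                                           frozenset({deficit_roi}), delta),
            "reference": ConnectomeGroupSpec(group_ns[1]),
            "external": ConnectomeGroupSpec(group_ns[2]),
        }
        mats = generate_connectomes(specs, n_rois=n_rois, noise_sd=noise_sd,
                                    seed=int(rng.integers(2**31)))
        res = two_stage_region_test(
            regional_strength(mats["deficit"]),
            regional_strength(mats["reference"]),
            regional_strength(mats["external"]))
        if bool(res.loc[deficit_roi, "selected"]):
            hits += 1
    return hits / n_replicates


def null_selection_rates(
    n_replicates: int = 500, n_rois: int = 30,
    group_ns: tuple[int, int, int] = (40, 40, 36),
    noise_sd: float = 0.1, seed: int = 0,
) -> tuple[float, float]:
    """(mean selected ROIs, mean screened ROIs) with no planted effect."""
    rng = np.random.default_rng(seed)
    selected, screened = [], []
    for _ in range(n_replicates):
        specs = {"deficit": ConnectomeGroupSpec(group_ns[0]),
                 "reference": ConnectomeGroupSpec(group_ns[1]),
                 "external": ConnectomeGroupSpec(group_ns[2])}
        mats = generate_connectomes(specs, n_rois=n_rois, noise_sd=noise_sd,
                                    seed=int(rng.integers(2**31)))
        res = two_stage_region_test(
            regional_strength(mats["deficit"]),
            regional_strength(mats["reference"]),
            regional_strength(mats["external"]))
        selected.append(int(res["selected"].sum()))
        screened.append(int(res["screened"].sum()))
    return float(np.mean(selected)), float(np.mean(screened))
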