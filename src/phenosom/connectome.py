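"""Regional strength comparison of structural connectomes.

Connectomes are symmetric ROI x ROI matrices whose weights are
log10-transformed streamline counts (log10(1 + count), so zero streamlines
map to weight zero).  A region's strength is the sum of its connection
weights.  Group differences use a two-stage procedure: per ROI, a Welch
two-sample t screens the deficit group against the within-sample
age-appropriate group at uncorrected alpha; screened ROIs are then
confirmed against an external typically developing group with
Benjamini-Hochberg FDR within the screened set.  Lobe-level summaries
average each child's strengths over a lobe's ROIs and compare groups with
a two-sided Mann-Whitney U (reported as min(U1, U2)), FDR-corrected
across the five lobes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOBES = ("frontal", "temporal", "parietal", "occipital", "subcortical")


def weight_from_counts(count_matrix: np.ndarray) -> np.ndarray:
    """Symmetrize a streamline-count matrix and log-transform it.

    Counts are averaged with their transpose (symmetric intersection),
    then weight = log10(1 + count); the diagonal is zeroed.
    """
    counts = np.asarray(count_matrix, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("count matrix must be square")
    if np.any(counts < 0):
        raise ValueError("streamline counts must be nonnegative")
    sym = 0.5 * (counts + counts.T)
    w = np.log10(1.0 + sym)
    np.fill_diagonal(w, 0.0)
    return w


def check_connectome(weights: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("connectome weights must be finite")
    if not np.allclose(w, w.T, atol=atol):
        raise ValueError("connectome must be symmetric")
    if np.abs(np.diag(w)).max() > atol:
        raise ValueError("connectome diagonal must be zero")
    if w.min() < -atol:
        raise ValueError("connectome weights must be nonnegative")
    return w


def regional_strength(weights: np.ndarray) -> np.ndarray:
    """Per-ROI strength: the sum of all connections of that region.

    Accepts a single matrix (returns a vector) or a stack of per-child
    matrices (returns child x ROI).
    """
    w = np.asarray(weights, dtype=float)
    return w.sum(axis=-1)


def two_stage_region_test(
    deficit_group: np.ndarray,
    reference_group: np.ndarray,
    external_group: np.ndarray,
    alpha1: float = 0.05,
    q: float = 0.05,
    roi_names: list[str] | None = None,
) -> pd.DataFrame:
    """Screen-then-confirm regional comparison.

    Inputs are child x ROI strength matrices.  Stage 1: Welch t per ROI,
    deficit vs reference, screened at uncorrected p < ``alpha1``.  Stage 2:
    Welch t of the screened ROIs against the external group,
    Benjamini-Hochberg FDR within the screened set at ``q``.  An ROI is
    selected iff it passes both stages.  An empty screened set is a valid
    result with no selections.
    """
    dg = np.atleast_2d(np.asarray(deficit_group, float))
    rg = np.atleast_2d(np.asarray(reference_group, float))
    eg = np.atleast_2d(np.asarray(external_group, float))
    if min(len(dg), len(rg), len(eg)) < 2:
        raise ValueError("need >= 2 children per group")
    n_roi = dg.shape[1]
    if rg.shape[1] != n_roi or eg.shape[1] != n_roi:
        raise ValueError("ROI counts differ between groups")
    t1, p1 = stats.ttest_ind(dg, rg, axis=0, equal_var=False)
    screened = p1 < alpha1
    t2 = np.full(n_roi, np.nan)
    p2 = np.full(n_roi, np.nan)
    p2_fdr = np.full(n_roi, np.nan)
    selected = np.zeros(n_roi, dtype=bool)
    if screened.any():
        t2s, p2s = stats.ttest_ind(dg[:, screened], eg[:, screened],
                                   axis=0, equal_var=False)
        rej, p_adj, _, _ = multipletests(p2s, alpha=q, method="fdr_bh")
        t2[screened] = t2s
        p2[screened] = p2s
        p2_fdr[screened] = p_adj
        selected[screened] = rej
    names = roi_names if roi_names is not None else [f"roi_{i}" for i in range(n_roi)]
    return pd.DataFrame({
        "roi": names, "stage1_t": t1, "stage1_p": p1, "screened": screened,
        "stage2_t": t2, "stage2_p": p2, "stage2_p_fdr": p2_fdr,
        "selected": selected,
    })


def lobe_scores(strengths: np.ndarray, roi_lobes: pd.Series | np.ndarray,
                ) -> pd.DataFrame:
    """Per-child lobe score: mean strength over the lobe's member ROIs."""
    strengths = np.atleast_2d(np.asarray(strengths, float))
    lobes = pd.Series(np.asarray(roi_lobes))
    unmapped = lobes[~lobes.isin(LOBES)]
    if len(unmapped):
        raise ValueError(
            f"ROI(s) at positions {list(unmapped.index)} map to unknown "
            f"lobe(s) {sorted(set(unmapped))}")
    if len(lobes) != strengths.shape[1]:
        raise ValueError("lobe map length must equal ROI count")
    out = {}
    for lobe in LOBES:
        idx = np.flatnonzero(lobes.to_numpy() == lobe)
        if len(idx) == 0:
            raise ValueError(f"no ROI mapped to lobe {lobe!r}")
        out[lobe] = strengths[:, idx].mean(axis=1)
    return pd.DataFrame(out)


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U reported as min(U1, U2).

    Exact enumeration below combined n = 20 (no-tie assumption), otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    method = "exact" if (len(a) + len(b) < 20 and
                         len(np.unique(np.concatenate([a, b])))
                         == len(a) + len(b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(a) * len(b) - u1)
    return u, float(res.pvalue)


def lobe_comparison(
    strengths_a: np.ndarray, strengths_b: np.ndarray,
    roi_lobes: pd.Series | np.ndarray,
    label_a: str = "A", label_b: str = "B",
    q: float = 0.05,
) -> pd.DataFrame:
    """Lobe-level robust summaries and Mann-Whitney comparison of two groups.

    Reports per-lobe group medians and median absolute deviations, U,
    raw p and Benjamini-Hochberg-corrected p across the five lobes.
    """
    sa = lobe_scores(strengths_a, roi_lobes)
    sb = lobe_scores(strengths_b, roi_lobes)
    rows = []
    for lobe in LOBES:
        u, p = mann_whitney_u(sa[lobe].to_numpy(), sb[lobe].to_numpy())
        rows.append(dict(
            lobe=lobe,
            **{f"median_{label_a}": float(np.median(sa[lobe])),
               f"mad_{label_a}": float(stats.median_abs_deviation(sa[lobe])),
               f"median_{label_b}": float(np.median(sb[lobe])),
               f"mad_{label_b}": float(stats.median_abs_deviation(sb[lobe]))},
            U=u, p_raw=p))
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p_raw"].to_numpy(), alpha=q,
                                   method="fdr_bh")
    out["p_fdr"] = p_adj
    return out
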