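"""Group comparisons on measures inside and outside the machine learning.

Continuous measures are compared across the profile groups with classical
one-way ANOVA and Tukey HSD post hocs (Tukey-Kramer standard errors for
unequal group sizes).  Categorical labels use a one-way Pearson
goodness-of-fit of the member counts across clusters against expectations
proportional to cluster size; gender uses a 1-df goodness-of-fit of a
cluster's male/female split against the full-sample male proportion
(no continuity correction).  Within each data family (cognitive, learning,
behavior) raw p-values receive a Bonferroni correction.  Questionnaire
subscales are reduced to two varimax-rotated principal-component factors
per instrument before group comparison; factor scores use the regression
method and are standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


def oneway_anova(values: np.ndarray, group_labels: np.ndarray) -> AnovaResult:
    """Classical fixed-effects one-way F test, df = (g-1, N-g).

    With zero within-group variance and equal means the F ratio is 0/0;
    it is reported as NaN rather than silently coerced.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in np.unique(group_labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = len(values)
    g = len(groups)
    grand = values.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df_b, df_w = g - 1, n - g
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(np.nan, np.nan, df_b, df_w)
        return AnovaResult(np.inf, 0.0, df_b, df_w)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w)


def tukey_posthoc(values: np.ndarray, group_labels: np.ndarray,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD adjusted p per unordered group pair.

    Uses the studentized-range distribution with Tukey-Kramer standard
    errors, so unequal group sizes are handled.  Pairs involving a
    singleton group are flagged untestable (NaN p).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names = list(np.unique(group_labels))
    groups = {g: values[group_labels == g] for g in names}
    testable = [g for g in names if len(groups[g]) >= 2]
    res = None
    if len(testable) >= 2:
        res = stats.tukey_hsd(*[groups[g] for g in testable])
    pos = {g: i for i, g in enumerate(testable)}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = groups[a].mean() - groups[b].mean()
            if a in pos and b in pos:
                p_adj = float(res.pvalue[pos[a], pos[b]])
            else:
                p_adj = np.nan
            rows.append(dict(group_a=a, group_b=b, mean_diff=float(diff),
                             p_adj=p_adj,
                             significant=bool(p_adj < alpha)
                             if np.isfinite(p_adj) else False))
    return pd.DataFrame(rows)


@dataclass
class CategoryTest:
    category: str
    observed_counts: np.ndarray
    chi2: float
    df: int
    p_raw: float
    p_corrected: float = np.nan


def category_distribution_chi2(member_counts, cluster_sizes,
                               category: str = "") -> CategoryTest:
    """One-way goodness-of-fit of member counts across clusters.

    Expected counts are proportional to cluster size,
    E_c = total_members * n_c / N, on #clusters - 1 degrees of freedom.
    """
    obs = np.asarray(member_counts, dtype=float)
    sizes = np.asarray(cluster_sizes, dtype=float)
    if obs.shape != sizes.shape:
        raise ValueError("member_counts and cluster_sizes must align")
    if np.any(obs > sizes):
        raise ValueError("member counts exceed cluster sizes")
    total = obs.sum()
    if total < 1:
        raise ValueError("need at least one member overall")
    expected = total * sizes / sizes.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count (empty cluster)")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return CategoryTest(category, obs.astype(int), chi2, df, p)


def gender_gof_chi2(cluster_mf: tuple[int, int],
                    overall_mf: tuple[int, int]) -> tuple[float, float]:
    """1-df goodness-of-fit of a cluster's male/female split.

    Expectations come from the overall male proportion; no continuity
    correction.
    """
    m, f = cluster_mf
    M, F = overall_mf
    if M + F <= 0 or M <= 0 or F <= 0:
        raise ValueError("overall male and female counts must be positive")
    n = m + f
    p_male = M / (M + F)
    em, ef = n * p_male, n * (1 - p_male)
    if em == 0 or ef == 0:
        raise ValueError("zero expected gender count")
    chi2 = (m - em) ** 2 / em + (f - ef) ** 2 / ef
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Family-wise correction: p_corrected = min(1, p * m_family)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def _varimax_criterion(loadings: np.ndarray) -> float:
    return float((loadings ** 2).var(axis=0).sum())


def _varimax_loadings(corr: np.ndarray, n_factors: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    loadings = evecs[:, :n_factors] * np.sqrt(np.maximum(evals[:n_factors], 0))
    if n_factors > 1:
        # perfectly symmetric (e.g. exactly low-rank) loadings are a saddle
        # of the varimax criterion; restart from seeded random rotations and
        # keep the best solution
        rng = np.random.default_rng(0)
        starts = [np.eye(n_factors)]
        for _ in range(7):
            q, _ = np.linalg.qr(rng.standard_normal((n_factors, n_factors)))
            starts.append(q)
        best, best_v = None, -np.inf
        for q in starts:
            rotated, _ = rotate_factors(loadings @ q, "varimax")
            v = _varimax_criterion(rotated)
            if v > best_v:
                best, best_v = rotated, v
        loadings = best
    # orient each factor so its largest loading is positive
    for j in range(loadings.shape[1]):
        if loadings[np.abs(loadings[:, j]).argmax(), j] < 0:
            loadings[:, j] *= -1
    return loadings, evals


@dataclass
class FactorSolution:
    loadings: pd.DataFrame             # subscale x factor, rotated
    scores: pd.DataFrame               # child x factor, mean 0 sd 1
    variance_explained: float          # % by the retained factors (pre-rotation)
    variance_per_component: np.ndarray  # % per component, all components


def questionnaire_factors(subscale_matrix: pd.DataFrame,
                          n_factors: int = 2) -> FactorSolution:
    """Rotated PCA factor solution for one questionnaire's subscales.

    PCA runs on the subscale correlation matrix; the retained components
    (default two) are varimax-rotated and per-child factor scores are
    computed by the regression method (S = Z R^-1 L) then standardized.
    """
    df = subscale_matrix.dropna()
    if df.shape[1] < n_factors:
        raise ValueError("need at least as many subscales as factors")
    sds = df.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant subscale(s): {constant}")
    Z = (df - df.mean()) / sds
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    loadings, evals = _varimax_loadings(R, n_factors)
    var_pct = 100.0 * np.maximum(evals, 0) / len(evals)
    var_explained = float(var_pct[:n_factors].sum())
    # pinv tolerates the singular correlation matrix of an exact low-rank model
    S = Z.to_numpy() @ (np.linalg.pinv(R) @ loadings)
    S = S / S.std(axis=0, ddof=1)
    names = [f"factor_{j + 1}" for j in range(n_factors)]
    return FactorSolution(
        loadings=pd.DataFrame(loadings, index=df.columns, columns=names),
        scores=pd.DataFrame(S, index=df.index, columns=names),
        variance_explained=var_explained,
        variance_per_component=var_pct,
    )


def compare_measures(
    scores: pd.DataFrame, modal_cluster: np.ndarray,
    families: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA + Tukey for every measure, Bonferroni within family.

    Returns (omnibus table, pairwise Tukey table).
    """
    modal = np.asarray(modal_cluster)
    omni_rows, pair_rows = [], []
    for measure in scores.columns:
        vals = scores[measure].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        res = oneway_anova(vals[ok], modal[ok])
        omni_rows.append(dict(measure=measure,
                              family=families.get(measure, "other"),
                              F=res.F, df_between=res.df_between,
                              df_within=res.df_within, p_raw=res.p))
        pt = tukey_posthoc(vals[ok], modal[ok])
        pt.insert(0, "measure", measure)
        pair_rows.append(pt)
    omni = pd.DataFrame(omni_rows)
    omni["p_corrected"] = np.nan
    for fam, grp in omni.groupby("family"):
        omni.loc[grp.index, "p_corrected"] = bonferroni(
            grp["p_raw"].to_numpy(), m=len(grp))
    return omni, pd.concat(pair_rows, ignore_index=True)


def compare_categories(
    labels: pd.DataFrame, modal_cluster: np.ndarray,
    categories: list[str],
) -> pd.DataFrame:
    """Goodness-of-fit chi-squares for categorical labels across clusters.

    ``categories`` entries follow the same mini-syntax as the topography
    tests (boolean column, or "column=value").  Bonferroni is applied over
    the listed family.
    """
    from .topo import category_membership

    modal = np.asarray(modal_cluster)
    k = int(modal.max()) + 1
    sizes = np.array([(modal == c).sum() for c in range(k)])
    rows = []
    for cat in categories:
        memb = category_membership(labels, cat)
        counts = np.array([(memb & (modal == c)).sum() for c in range(k)])
        t = category_distribution_chi2(counts, sizes, category=cat)
        rows.append(dict(category=cat,
                         **{f"cluster_{c + 1}": int(counts[c]) for c in range(k)},
                         chi2=t.chi2, df=t.df, p_raw=t.p_raw))
    out = pd.DataFrame(rows)
    out["p_corrected"] = bonferroni(out["p_raw"].to_numpy(), m=len(out))
    return out


def compare_gender(labels: pd.DataFrame, modal_cluster: np.ndarray
                   ) -> pd.DataFrame:
    """Per-cluster gender goodness-of-fit against the overall split."""
    modal = np.asarray(modal_cluster)
    k = int(modal.max()) + 1
    g = labels["gender"].astype(str).to_numpy()
    overall = (int((g == "male").sum()), int((g == "female").sum()))
    rows = []
    for c in range(k):
        sel = modal == c
        mf = (int(((g == "male") & sel).sum()),
              int(((g == "female") & sel).sum()))
        chi2, p = gender_gof_chi2(mf, overall)
        rows.append(dict(cluster=c + 1, male=mf[0], female=mf[1],
                         chi2=chi2, p_raw=p))
    return pd.DataFrame(rows)
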