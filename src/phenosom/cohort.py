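"""Synthetic cohorts for the phenotyping pipeline.

Generates children with the statistical structure the downstream analyses
assume: cognitive and learning z-scores drawn per generating cluster from a
multivariate normal, categorical labels (gender, referral reason, diagnosis
flags) drawn with per-cluster rates, questionnaire subscales driven by a
two-factor latent model, and per-child structural connectomes with optional
planted regional deficits.

Default cluster means and sizes reproduce the four published cognitive
profile groups of a clinic sample of 530 struggling learners (broad
deficits / working-memory deficits / age-appropriate / phonological
deficits); default categorical rates are the published per-cluster counts
divided by cluster size.  Within-cluster dispersion and inter-measure
correlation are not published; the defaults (sd 0.5, exchangeable
correlation 0.3) are declared stand-ins chosen so clusters overlap at their
boundaries yet remain recoverable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COGNITIVE_MEASURES = [
    "matrix_reasoning",
    "vocabulary",
    "phonological_awareness",
    "verbal_stm",
    "spatial_stm",
    "verbal_wm",
    "spatial_wm",
]
LEARNING_MEASURES = ["spelling", "reading", "maths"]

BRIEF_SUBSCALES = [
    "inhibit", "shift", "emotional_control", "initiate",
    "working_memory", "planning", "organization", "monitor",
]
CCC2_SUBSCALES = [
    "speech", "syntax", "semantics", "coherence", "inappropriate_initiation",
    "stereotyped", "context", "nonverbal", "social", "interests",
]

#: Published per-cluster means (cluster order: broad deficits, WM deficits,
#: age appropriate, phonological deficits), z-score units.
DEFAULT_CLUSTER_MEANS = pd.DataFrame(
    {
        "matrix_reasoning": [-1.42, -0.71, 0.04, -0.63],
        "vocabulary": [-1.10, 0.08, 0.87, -0.47],
        "phonological_awareness": [-1.17, -0.41, -0.17, -0.91],
        "verbal_stm": [-1.44, -0.19, 0.44, -0.79],
        "spatial_stm": [-1.24, -1.12, 0.29, -0.11],
        "verbal_wm": [-1.41, -0.55, 0.18, -0.66],
        "spatial_wm": [-0.87, -0.45, 0.45, 0.23],
        "spelling": [-1.58, -1.05, -0.47, -1.17],
        "reading": [-1.60, -0.90, 0.02, -1.09],
        "maths": [-1.77, -1.02, -0.32, -1.13],
    },
    index=[1, 2, 3, 4],
)

DEFAULT_CLUSTER_SIZES = [146, 121, 132, 131]

#: Published counts per cluster; rates are count / cluster size.
DEFAULT_REFERRAL_COUNTS = {
    "attention": [36, 48, 52, 39],
    "memory": [16, 11, 12, 16],
    "language": [25, 7, 12, 15],
    "poor_school": [67, 51, 51, 58],
}
DEFAULT_DIAGNOSIS_COUNTS = {
    "add_adhd": [29, 35, 22, 28],
    "slt": [43, 16, 15, 24],
    "dyslexia": [11, 9, 5, 5],
    "asd": [9, 6, 11, 6],
    "sus_adhd": [15, 14, 18, 10],
}
DEFAULT_MALE_COUNTS = [87, 83, 105, 91]

#: Published questionnaire subscale means per cluster (T-scores for the
#: executive-function questionnaire, scaled scores for the communication
#: checklist).
BRIEF_CLUSTER_MEANS = pd.DataFrame(
    {
        "inhibit": [66.3, 65.4, 64.5, 64.9],
        "shift": [69.6, 68.2, 66.1, 68.5],
        "emotional_control": [65.1, 64.4, 62.7, 65.4],
        "initiate": [68.1, 66.2, 65.9, 66.6],
        "working_memory": [75.9, 74.2, 72.8, 72.9],
        "planning": [72.2, 71.3, 71.9, 71.1],
        "organization": [58.1, 61.4, 61.0, 59.9],
        "monitor": [66.5, 66.4, 64.2, 65.1],
    },
    index=[1, 2, 3, 4],
)
CCC2_CLUSTER_MEANS = pd.DataFrame(
    {
        "speech": [3.6, 6.6, 7.1, 4.6],
        "syntax": [3.0, 6.0, 7.3, 4.2],
        "semantics": [3.5, 5.2, 6.2, 4.3],
        "coherence": [3.3, 4.6, 5.3, 4.3],
        "inappropriate_initiation": [5.0, 5.8, 6.1, 5.8],
        "stereotyped": [4.1, 5.5, 6.6, 5.3],
        "context": [2.7, 4.0, 5.4, 3.7],
        "nonverbal": [4.0, 4.7, 5.3, 4.5],
        "social": [4.1, 4.7, 5.2, 5.2],
        "interests": [5.3, 5.5, 5.8, 5.7],
    },
    index=[1, 2, 3, 4],
)

# Simple-structure loadings of the two latent questionnaire factors
# ("cold"/"hot" executive function; pragmatic/structural communication),
# with the monitor and coherence subscales cross-loading.
BRIEF_LOADINGS = {
    "working_memory": (0.8, 0.1), "initiate": (0.8, 0.1),
    "planning": (0.8, 0.1), "organization": (0.75, 0.1),
    "monitor": (0.5, 0.5),
    "emotional_control": (0.1, 0.8), "shift": (0.1, 0.8),
    "inhibit": (0.1, 0.75),
}
CCC2_LOADINGS = {
    "coherence": (0.5, 0.5),
    "inappropriate_initiation": (0.8, 0.1), "stereotyped": (0.75, 0.1),
    "context": (0.8, 0.1), "nonverbal": (0.75, 0.1),
    "social": (0.7, 0.1), "interests": (0.7, 0.1),
    "speech": (0.1, 0.8), "syntax": (0.1, 0.8), "semantics": (0.1, 0.75),
}
BRIEF_SUBSCALE_SD = 9.0
CCC2_SUBSCALE_SD = 2.5

MEASURE_FAMILY = {m: "cognitive" for m in COGNITIVE_MEASURES}
MEASURE_FAMILY.update({m: "learning" for m in LEARNING_MEASURES})
MEASURE_FAMILY.update({f"brief_{m}": "behavior" for m in BRIEF_SUBSCALES})
MEASURE_FAMILY.update({f"ccc2_{m}": "behavior" for m in CCC2_SUBSCALES})

REFERRAL_REASONS = ["attention", "memory", "language", "poor_school", "none"]
DIAGNOSIS_FLAGS = list(DEFAULT_DIAGNOSIS_COUNTS)


def exchangeable_correlation(n: int, rho: float) -> np.ndarray:
    """Correlation matrix with a common off-diagonal correlation ``rho``."""
    c = np.full((n, n), rho, dtype=float)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class CohortGenConfig:
    """Parameters of the synthetic cohort generator.

    The defaults reproduce the published four-cluster structure: cluster
    sizes 146/121/132/131 and the printed per-cluster means of the seven
    cognitive and three learning z-scores.  ``within_cluster_sd`` and
    ``within_cluster_corr`` are stand-ins (the source reports neither).
    """

    cluster_sizes: list[int] = field(
        default_factory=lambda: list(DEFAULT_CLUSTER_SIZES))
    cluster_means: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_CLUSTER_MEANS.copy())
    within_cluster_sd: float | np.ndarray = 0.5
    within_cluster_corr: np.ndarray | None = None  # None -> exchangeable 0.3
    category_rates: dict[str, list[float]] | None = None  # None -> defaults
    referral_rates: dict[str, list[float]] | None = None
    male_prob_per_cluster: list[float] | None = None
    age_range_months: tuple[int, int] = (65, 215)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    @property
    def measures(self) -> list[str]:
        return list(self.cluster_means.columns)

    def resolved_sd(self) -> np.ndarray:
        sd = np.broadcast_to(
            np.asarray(self.within_cluster_sd, dtype=float),
            (len(self.measures),)).copy()
        if np.any(sd < 0):
            raise ValueError("within_cluster_sd must be nonnegative")
        return sd

    def resolved_corr(self) -> np.ndarray:
        if self.within_cluster_corr is None:
            return exchangeable_correlation(len(self.measures), 0.3)
        corr = np.asarray(self.within_cluster_corr, dtype=float)
        _check_correlation(corr, len(self.measures))
        return corr

    def resolved_referral_rates(self) -> dict[str, list[float]]:
        if self.referral_rates is not None:
            rates = self.referral_rates
        else:
            sizes = np.asarray(DEFAULT_CLUSTER_SIZES, dtype=float)
            rates = {k: list(np.asarray(v) / sizes)
                     for k, v in DEFAULT_REFERRAL_COUNTS.items()}
        _check_rates(rates, self.n_clusters)
        return rates

    def resolved_diagnosis_rates(self) -> dict[str, list[float]]:
        if self.category_rates is not None:
            rates = self.category_rates
        else:
            sizes = np.asarray(DEFAULT_CLUSTER_SIZES, dtype=float)
            rates = {k: list(np.asarray(v) / sizes)
                     for k, v in DEFAULT_DIAGNOSIS_COUNTS.items()}
        _check_rates(rates, self.n_clusters)
        return rates

    def resolved_male_prob(self) -> list[float]:
        if self.male_prob_per_cluster is not None:
            probs = list(self.male_prob_per_cluster)
        else:
            probs = [m / n for m, n in
                     zip(DEFAULT_MALE_COUNTS, DEFAULT_CLUSTER_SIZES)]
        _check_rates({"male": probs}, self.n_clusters)
        return probs

    def validate(self) -> None:
        if any(n <= 0 for n in self.cluster_sizes):
            raise ValueError("cluster_sizes must be positive")
        if self.cluster_means.shape[0] != self.n_clusters:
            raise ValueError(
                "cluster_means must have one row per cluster "
                f"({self.cluster_means.shape[0]} != {self.n_clusters})")
        self.resolved_sd()
        self.resolved_corr()
        lo, hi = self.age_range_months
        if lo > hi:
            raise ValueError("age_range_months must be a nondecreasing interval")


def _check_correlation(corr: np.ndarray, p: int) -> None:
    if corr.shape != (p, p):
        raise ValueError(f"within_cluster_corr must be {p}x{p}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("within_cluster_corr is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("within_cluster_corr must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError(
            "within_cluster_corr is not positive semi-definite")


def _check_rates(rates: dict[str, list[float]], k: int) -> None:
    for name, r in rates.items():
        r = np.asarray(r, dtype=float)
        if r.shape != (k,):
            raise ValueError(f"rates for {name!r} must have one entry per cluster")
        if np.any(r < 0) or np.any(r > 1):
            raise ValueError(f"rates for {name!r} outside [0, 1]")


@dataclass
class CohortMatrix:
    """Children x measures z-score matrix with per-measure family tags."""

    scores: pd.DataFrame                    # index child_id, columns measures
    families: dict[str, str]                # measure -> cognitive|learning|behavior

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise ValueError("measure names must be unique")
        if self.scores.index.duplicated().any():
            raise ValueError("child ids must be unique")

    @property
    def child_ids(self) -> list:
        return list(self.scores.index)

    @property
    def measures(self) -> list[str]:
        return list(self.scores.columns)

    def family_columns(self, family: str) -> list[str]:
        return [m for m in self.measures if self.families.get(m) == family]

    def values_for(self, family: str | None = None) -> np.ndarray:
        cols = self.measures if family is None else self.family_columns(family)
        return self.scores[cols].to_numpy(dtype=float)


def generate_scores(
    config: CohortGenConfig, rng: np.random.Generator | None = None,
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Draw per-cluster multivariate-normal score rows.

    Returns the cohort matrix and a label table holding ``generating_cluster``
    (1-based).  Covariance is diag(sd) @ corr @ diag(sd), shared by clusters.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = config.resolved_sd()
    corr = config.resolved_corr()
    cov = np.diag(sd) @ corr @ np.diag(sd)
    means = config.cluster_means.to_numpy(dtype=float)

    rows, clusters = [], []
    for c, n in enumerate(config.cluster_sizes):
        draw = rng.multivariate_normal(means[c], cov, size=n,
                                       method="svd")
        rows.append(draw)
        clusters.extend([c + 1] * n)
    data = np.vstack(rows)
    ids = [f"child_{i:04d}" for i in range(len(data))]
    scores = pd.DataFrame(data, index=pd.Index(ids, name="child_id"),
                          columns=config.measures)
    families = {m: MEASURE_FAMILY.get(m, "cognitive") for m in config.measures}
    labels = pd.DataFrame({"generating_cluster": clusters},
                          index=scores.index)
    return CohortMatrix(scores, families), labels


def generate_categories(
    labels: pd.DataFrame, config: CohortGenConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill gender, age, referral reason and diagnosis flags per child.

    Each label is drawn independently per child using its generating
    cluster's rate; referral reason is single-valued (multinomial over the
    four reasons plus "none" for the remaining probability mass).
    """
    if "generating_cluster" not in labels:
        raise ValueError("labels must carry generating_cluster")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    out = labels.copy()
    cl = out["generating_cluster"].to_numpy() - 1

    male_p = np.asarray(config.resolved_male_prob())[cl]
    out["gender"] = np.where(rng.random(len(out)) < male_p, "male", "female")

    lo, hi = config.age_range_months
    out["age_months"] = rng.integers(lo, hi + 1, size=len(out))

    ref = config.resolved_referral_rates()
    probs = np.column_stack([np.asarray(ref[r])[cl] for r in REFERRAL_REASONS[:-1]])
    none_p = 1.0 - probs.sum(axis=1)
    if np.any(none_p < -1e-9):
        raise ValueError("referral rates sum to more than 1 in some cluster")
    probs = np.column_stack([probs, np.clip(none_p, 0.0, 1.0)])
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(out))[:, None]
    out["referral_reason"] = [REFERRAL_REASONS[j] for j in (u > cum).sum(axis=1)]

    diag = config.resolved_diagnosis_rates()
    for flag, rates in diag.items():
        out[flag] = rng.random(len(out)) < np.asarray(rates)[cl]
    return out


def generate_cohort(
    config: CohortGenConfig | None = None,
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Scores plus fully populated labels in one call (seeded by config)."""
    if config is None:
        config = CohortGenConfig()
    rng = np.random.default_rng(config.seed)
    cohort, labels = generate_scores(config, rng)
    labels = generate_categories(labels, config, rng)
    return cohort, labels


def generate_questionnaires(
    labels: pd.DataFrame, seed: int = 0,
) -> pd.DataFrame:
    """Questionnaire subscales from a two-factor latent model per instrument.

    Each child draws two latent factor scores per questionnaire; subscale =
    cluster mean + scale_sd * (l1*f1 + l2*f2 + u*noise) with l1^2+l2^2+u^2=1,
    so PCA on the subscale correlations recovers two factors with the
    planted simple structure.
    """
    rng = np.random.default_rng(seed)
    cl = labels["generating_cluster"].to_numpy()
    n = len(labels)
    out = {}
    for prefix, subscales, means, loadings, scale_sd in [
        ("brief", BRIEF_SUBSCALES, BRIEF_CLUSTER_MEANS, BRIEF_LOADINGS,
         BRIEF_SUBSCALE_SD),
        ("ccc2", CCC2_SUBSCALES, CCC2_CLUSTER_MEANS, CCC2_LOADINGS,
         CCC2_SUBSCALE_SD),
    ]:
        factors = rng.standard_normal((n, 2))
        for sub in subscales:
            l1, l2 = loadings[sub]
            u = np.sqrt(max(1.0 - l1 * l1 - l2 * l2, 0.0))
            latent = factors @ np.array([l1, l2]) + u * rng.standard_normal(n)
            mu = means.loc[cl, sub].to_numpy()
            out[f"{prefix}_{sub}"] = mu + scale_sd * latent
    return pd.DataFrame(out, index=labels.index)


# ---------------------------------------------------------------------------
# Connectomes


@dataclass
class ConnectomeGroupSpec:
    """One group's generation settings: size and optional planted deficit."""

    n: int
    deficit_regions: frozenset[int] = frozenset()
    deficit_delta: float = 0.0


def generate_connectomes(
    group_specs: dict[str, ConnectomeGroupSpec],
    n_rois: int = 85,
    base_weight: float = 0.7,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Symmetric nonnegative weighted connectomes with planted deficits.

    Returns, per group, an array of shape (n, n_rois, n_rois): zero
    diagonal, symmetric, every edge ~ N(base_weight, noise_sd^2) truncated
    at 0, with edges incident to a group's deficit regions reduced in mean
    by that group's ``deficit_delta``.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be at least 2")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_rois, k=1)
    out: dict[str, np.ndarray] = {}
    for name, spec in group_specs.items():
        bad = [r for r in spec.deficit_regions if not (0 <= r < n_rois)]
        if bad:
            raise ValueError(f"deficit regions {bad} outside [0, {n_rois})")
        mean = np.full((n_rois, n_rois), base_weight)
        if spec.deficit_regions:
            idx = sorted(spec.deficit_regions)
            mean[idx, :] -= spec.deficit_delta
            mean[:, idx] -= spec.deficit_delta
            # an edge between two deficit regions is reduced once, not twice
            mean[np.ix_(idx, idx)] += spec.deficit_delta
        if mean[iu].min() < 0:
            raise ValueError(
                "deficit_delta drives mean edge weight below zero")
        mats = np.zeros((spec.n, n_rois, n_rois))
        for i in range(spec.n):
            vals = mean[iu] + noise_sd * rng.standard_normal(len(iu[0]))
            np.clip(vals, 0.0, None, out=vals)
            m = np.zeros((n_rois, n_rois))
            m[iu] = vals
            mats[i] = m + m.T
        out[name] = mats
    return out


def default_roi_lobe_map() -> pd.DataFrame:
    """85-region Desikan-Killiany ROI -> lobe table.

    34 cortical regions per hemisphere plus 17 subcortical structures,
    each assigned to one of {frontal, temporal, parietal, occipital,
    subcortical}.  Cingulate subdivisions follow the usual convention
    (anterior -> frontal, posterior/isthmus -> parietal); the insula is
    grouped with the frontal lobe.
    """
    cortical = {
        "superiorfrontal": "frontal", "rostralmiddlefrontal": "frontal",
        "caudalmiddlefrontal": "frontal", "parsopercularis": "frontal",
        "parstriangularis": "frontal", "parsorbitalis": "frontal",
        "lateralorbitofrontal": "frontal", "medialorbitofrontal": "frontal",
        "precentral": "frontal", "paracentral": "frontal",
        "frontalpole": "frontal", "rostralanteriorcingulate": "frontal",
        "caudalanteriorcingulate": "frontal", "insula": "frontal",
        "superiorparietal": "parietal", "inferiorparietal": "parietal",
        "supramarginal": "parietal", "postcentral": "parietal",
        "precuneus": "parietal", "posteriorcingulate": "parietal",
        "isthmuscingulate": "parietal",
        "superiortemporal": "temporal", "middletemporal": "temporal",
        "inferiortemporal": "temporal", "bankssts": "temporal",
        "fusiform": "temporal", "transversetemporal": "temporal",
        "entorhinal": "temporal", "temporalpole": "temporal",
        "parahippocampal": "temporal",
        "lateraloccipital": "occipital", "lingual": "occipital",
        "cuneus": "occipital", "pericalcarine": "occipital",
    }
    sub = ["thalamus", "caudate", "putamen", "pallidum", "hippocampus",
           "amygdala", "accumbens", "ventraldc"]
    rows = []
    for hemi in ("lh", "rh"):
        rows += [(f"{hemi}_{roi}", lobe) for roi, lobe in cortical.items()]
    for hemi in ("lh", "rh"):
        rows += [(f"{hemi}_{roi}", "subcortical") for roi in sub]
    rows.append(("brainstem", "subcortical"))
    return pd.DataFrame(rows, columns=["roi", "lobe"])


def lobe_map_for(n_rois: int) -> pd.DataFrame:
    """ROI->lobe map for an arbitrary ROI count.

    The standard 85-region atlas map when n_rois is 85; otherwise a
    synthetic map cycling through the five lobes so every lobe is
    populated (requires n_rois >= 5).
    """
    if n_rois == 85:
        return default_roi_lobe_map()
    if n_rois < 5:
        raise ValueError("need at least 5 ROIs to populate all five lobes")
    lobes = ["frontal", "temporal", "parietal", "occipital", "subcortical"]
    return pd.DataFrame({"roi": [f"roi_{i:02d}" for i in range(n_rois)],
                         "lobe": [lobes[i % 5] for i in range(n_rois)]})
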