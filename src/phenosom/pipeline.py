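"""End-to-end pipeline: generate -> train/consensus -> tests -> reports.

A single config dict (YAML on disk) drives every stage; all stochastic
stages derive their seeds from one master seed, so a rerun with the same
config is identical.  Every output table carries a comment line with the
config hash and the master seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats as gs
from . import io as pio
from .consensus import ConsensusResult, cluster_profile_table
from .consensus import consensus as run_consensus
from .cohort import (CohortGenConfig, CohortMatrix, ConnectomeGroupSpec,
                     generate_cohort, generate_connectomes,
                     generate_questionnaires, lobe_map_for)
from .connectome import (lobe_comparison, regional_strength,
                         two_stage_region_test)
from .som import SOMConfig, train_som
from .topo import DEFAULT_CATEGORIES, run_topography_tests

log = logging.getLogger("phenosom")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {},              # CohortGenConfig overrides; None -> read inputs
    "inputs": None,               # {"cohort": path, "labels": path}
    "som": {"init_jitter_sd": 0.05},
    "consensus": {"k": 4, "n_iterations": 1000},
    "topo": {"n_permutations": 9999, "categories": None},
    "stats": {"alpha": 0.05},
    "connectome": {"enabled": False, "n_rois": 85, "base_weight": 0.7,
                   "noise_sd": 0.1, "deficit_regions": [], "deficit_delta": 0.0,
                   "n_per_group": 40, "inputs": None},
}


def merged_config(cfg: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (cfg or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineResult:
    cohort: CohortMatrix
    labels: pd.DataFrame
    consensus: ConsensusResult
    topo_table: pd.DataFrame
    profile_table: pd.DataFrame
    omnibus: pd.DataFrame
    pairwise: pd.DataFrame
    category_table: pd.DataFrame
    gender_table: pd.DataFrame
    factor_solutions: dict = field(default_factory=dict)
    connectome_tables: dict = field(default_factory=dict)


def _load_or_generate(cfg: dict, rng: np.random.Generator
                      ) -> tuple[CohortMatrix, pd.DataFrame]:
    if cfg.get("inputs"):
        cohort, _ = pio.read_cohort(cfg["inputs"]["cohort"])
        labels = pio.read_labels(cfg["inputs"]["labels"])
        labels = labels.loc[cohort.scores.index]
        return cohort, labels
    gen_cfg = CohortGenConfig(**(cfg.get("generator") or {}),
                              seed=int(rng.integers(0, 2**31 - 1)))
    return generate_cohort(gen_cfg)


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None,
                 ) -> PipelineResult:
    """Execute every enabled stage; write reports if ``out_dir`` is given."""
    cfg = merged_config(config)
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    note = f"config={pio.config_hash(cfg)} seed={seed}"
    timings = {}

    t0 = time.perf_counter()
    cohort, labels = _load_or_generate(cfg, rng)
    timings["data"] = time.perf_counter() - t0
    log.info("cohort: %d children x %d measures",
             len(cohort.child_ids), len(cohort.measures))

    cognitive = CohortMatrix(
        cohort.scores[cohort.family_columns("cognitive")],
        {m: "cognitive" for m in cohort.family_columns("cognitive")})

    t0 = time.perf_counter()
    som_cfg = SOMConfig(**{**cfg["som"], "seed": int(rng.integers(0, 2**31 - 1))})
    result = run_consensus(
        cognitive, som_cfg, k=int(cfg["consensus"]["k"]),
        n_iterations=int(cfg["consensus"]["n_iterations"]),
        seed=int(rng.integers(0, 2**31 - 1)))
    timings["consensus"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    topo_cats = cfg["topo"]["categories"] or [
        c for c in DEFAULT_CATEGORIES
        if "=" in c or c in labels.columns]
    topo_table = run_topography_tests(
        result.reference_som, labels, topo_cats,
        n_permutations=int(cfg["topo"]["n_permutations"]),
        seed=int(rng.integers(0, 2**31 - 1)))
    timings["topo"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    modal = result.modal_cluster
    profile = cluster_profile_table(cohort, modal, labels, k=result.k)
    omni, pairwise = gs.compare_measures(cohort.scores, modal, cohort.families)
    cat_table = gs.compare_categories(labels, modal, topo_cats)
    gender_table = gs.compare_gender(labels, modal)

    factor_solutions = {}
    factor_rows = []
    quest = generate_questionnaires(labels, seed=int(rng.integers(0, 2**31 - 1)))
    for prefix in ("brief", "ccc2"):
        cols = [c for c in quest.columns if c.startswith(prefix)]
        sol = gs.questionnaire_factors(quest[cols], n_factors=2)
        factor_solutions[prefix] = sol
        for fac in sol.scores.columns:
            res = gs.oneway_anova(sol.scores[fac].to_numpy(), modal)
            factor_rows.append(dict(questionnaire=prefix, factor=fac,
                                    F=res.F, p_raw=res.p))
    factor_table = pd.DataFrame(factor_rows)
    for q, grp in factor_table.groupby("questionnaire"):
        factor_table.loc[grp.index, "p_corrected"] = gs.bonferroni(
            grp["p_raw"].to_numpy(), m=len(grp))
    timings["stats"] = time.perf_counter() - t0

    conn_tables = {}
    ccfg = cfg["connectome"]
    if ccfg.get("enabled"):
        t0 = time.perf_counter()
        n_rois = int(ccfg["n_rois"])
        lobe_map = lobe_map_for(n_rois)
        n = int(ccfg["n_per_group"])
        specs = {
            "deficit": ConnectomeGroupSpec(
                n, frozenset(ccfg["deficit_regions"]),
                float(ccfg["deficit_delta"])),
            "reference": ConnectomeGroupSpec(n),
            "external": ConnectomeGroupSpec(n),
        }
        mats = generate_connectomes(
            specs, n_rois=n_rois, base_weight=float(ccfg["base_weight"]),
            noise_sd=float(ccfg["noise_sd"]),
            seed=int(rng.integers(0, 2**31 - 1)))
        strengths = {g: regional_strength(m) for g, m in mats.items()}
        conn_tables["regions"] = two_stage_region_test(
            strengths["deficit"], strengths["reference"],
            strengths["external"], roi_names=list(lobe_map["roi"]))
        conn_tables["lobes"] = lobe_comparison(
            strengths["deficit"], strengths["reference"],
            lobe_map["lobe"], label_a="deficit", label_b="reference")
        timings["connectome"] = time.perf_counter() - t0

    for stage, dt in timings.items():
        log.info("stage %-10s %.2fs", stage, dt)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.dump_config(cfg, out_dir / "config.yml")
        pio.write_table(cohort.scores.reset_index(), out_dir / "cohort.csv", note)
        pio.write_table(labels.reset_index(), out_dir / "labels.csv", note)
        pio.write_table(result.per_child_table().reset_index(),
                        out_dir / "consensus_children.csv", note)
        pio.write_table(profile.reset_index(), out_dir / "cluster_profiles.csv",
                        note)
        pio.write_table(topo_table, out_dir / "topography_tests.csv", note)
        pio.write_table(omni, out_dir / "measure_anova.csv", note)
        pio.write_table(pairwise, out_dir / "measure_tukey.csv", note)
        pio.write_table(cat_table, out_dir / "category_chi2.csv", note)
        pio.write_table(gender_table, out_dir / "gender_chi2.csv", note)
        pio.write_table(factor_table, out_dir / "factor_anova.csv", note)
        for name, tbl in conn_tables.items():
            pio.write_table(tbl, out_dir / f"connectome_{name}.csv", note)

    return PipelineResult(
        cohort=cohort, labels=labels, consensus=result,
        topo_table=topo_table, profile_table=profile, omnibus=omni,
        pairwise=pairwise, category_table=cat_table,
        gender_table=gender_table, factor_solutions=factor_solutions,
        connectome_tables=conn_tables)
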