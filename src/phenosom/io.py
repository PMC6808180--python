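"""Delimited-text readers and writers for every pipeline artifact.

Conventions: cohort scores and label tables are comma-separated with a
header row and one child per row, keyed by ``child_id``; connectomes are
whitespace-delimited square matrices, one file per child (filename =
child_id), with a shared ROI-names file and a two-column ROI->lobe map;
configs are YAML.  Result files written by the pipeline start with a
comment line embedding the config hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COGNITIVE_MEASURES, MEASURE_FAMILY, CohortMatrix

log = logging.getLogger("phenosom")


def write_cohort(cohort: CohortMatrix, path: str | Path,
                 float_format: str | None = None) -> None:
    """Scores as CSV; default full precision for exact round trips."""
    cohort.scores.to_csv(path, float_format=float_format)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path)


def read_cohort(
    path: str | Path,
    required_measures: list[str] | None = None,
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Read a cohort score table, excluding incomplete children.

    Children missing any of the required (default: the seven cognitive)
    measures are dropped and logged with counts; the returned frame holds
    the included children.  Duplicate child ids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    if "child_id" not in df.columns:
        raise ValueError(f"{path} lacks a child_id column")
    if df["child_id"].duplicated().any():
        dupes = df.loc[df["child_id"].duplicated(), "child_id"].tolist()
        raise ValueError(f"duplicate child_id(s): {dupes[:5]}")
    df = df.set_index("child_id")
    if required_measures is None:
        required_measures = [m for m in COGNITIVE_MEASURES if m in df.columns]
        missing_cols = [m for m in COGNITIVE_MEASURES if m not in df.columns]
        if missing_cols:
            raise ValueError(f"{path} lacks cognitive measures {missing_cols}")
    complete = df[required_measures].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        log.info("excluded %d of %d children with missing scores on the "
                 "required measures; %d included",
                 n_excluded, len(df), int(complete.sum()))
    kept = df.loc[complete]
    families = {m: MEASURE_FAMILY.get(m, "other") for m in kept.columns}
    excluded = df.loc[~complete]
    return CohortMatrix(kept, families), excluded


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#").set_index("child_id")


def write_connectomes(mats: dict[str, np.ndarray], out_dir: str | Path,
                      roi_names: list[str]) -> None:
    """One whitespace-delimited square matrix file per child."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "roi_names.txt").write_text("\n".join(roi_names) + "\n")
    for child_id, m in mats.items():
        np.savetxt(out_dir / f"{child_id}.txt", m, fmt="%.6g")


def read_connectomes(in_dir: str | Path) -> tuple[dict[str, np.ndarray], list[str]]:
    in_dir = Path(in_dir)
    roi_names = (in_dir / "roi_names.txt").read_text().split()
    mats = {}
    for f in sorted(in_dir.glob("*.txt")):
        if f.name == "roi_names.txt":
            continue
        mats[f.stem] = np.loadtxt(f)
    return mats, roi_names


def write_lobe_map(lobe_map: pd.DataFrame, path: str | Path) -> None:
    lobe_map.to_csv(path, sep="\t", index=False)


def read_lobe_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_som(som, path: str | Path) -> None:
    """Structured text serialization: config echo, weights, BMU table."""
    payload = {
        "config": vars(som.config) | {"topology": som.config.topology},
        "grid_rows": som.config.grid_rows,
        "grid_cols": som.config.grid_cols,
        "schedule_trace": list(map(float, som.schedule_trace)),
        "measures": list(som.measures),
        "weights": som.weights.tolist(),
        "bmu": {str(c): int(b) for c, b in
                zip(som.child_ids or range(len(som.bmu)), som.bmu)},
        "quantization_errors": list(map(float, som.quantization_errors)),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, header_note: str = "",
                index: bool = False) -> None:
    """CSV with an optional leading comment line (config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=index, float_format="%.6g")
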