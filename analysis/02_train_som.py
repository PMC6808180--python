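"""Train the batch self-organizing map on the cognitive measures.

Fits a 10x10 hexagonal map (PCA-plane init, 5 ordering cycles with the
shrinking bubble neighborhood, 1 fine-tuning cycle at ND=0) and writes the
per-measure weight planes and their correlation matrix.  Highly correlated
planes mark tasks that separate children in similar ways.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phenosom import io as pio
from phenosom.cohort import CohortMatrix
from phenosom.som import SOMConfig, train_som

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main() -> None:
    cohort, _ = pio.read_cohort(BASE / "cohort" / "cohort.csv")
    cols = cohort.family_columns("cognitive")
    cm = CohortMatrix(cohort.scores[cols], {c: "cognitive" for c in cols})
    som = train_som(cm, SOMConfig(seed=SEED))
    out = BASE / "som"
    out.mkdir(parents=True, exist_ok=True)
    pio.write_som(som, out / "trained_som.json")
    for name, plane in som.weight_planes().items():
        np.savetxt(out / f"plane_{name}.txt", plane, fmt="%.5f")
    corr = pd.DataFrame(som.weight_plane_correlations(), index=cols,
                        columns=cols)
    pio.write_table(corr.round(3).reset_index(), out / "plane_correlations.csv",
                    f"seed={SEED}")
    print("quantization error per cycle:",
          [round(q, 3) for q in som.quantization_errors])
    iu = np.triu_indices(len(cols), 1)
    top = np.argsort(corr.to_numpy()[iu])[::-1][:3]
    print("most correlated weight planes:")
    for t in top:
        i, j = iu[0][t], iu[1][t]
        print(f"  {cols[i]} ~ {cols[j]}: r = {corr.iloc[i, j]:.2f}")


if __name__ == "__main__":
    main()
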