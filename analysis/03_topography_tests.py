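"""Test whether referral reason or diagnosis predicts map position.

For each category of children, compares the 2D distribution of members'
best-matching units against nonmembers' with the two-sample 2D KS
statistic and a label-permutation test.  Because the generator assigns
categories independently of the score profile within cluster structure
only via per-cluster rates, categories whose rates barely differ across
clusters should be nonsignificant.
"""

from pathlib import Path

from phenosom import io as pio
from phenosom.cohort import CohortMatrix
from phenosom.som import SOMConfig, train_som
from phenosom.topo import run_topography_tests

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 13


def main() -> None:
    cohort, _ = pio.read_cohort(BASE / "cohort" / "cohort.csv")
    labels = pio.read_labels(BASE / "cohort" / "labels.csv")
    labels = labels.loc[cohort.scores.index]
    cols = cohort.family_columns("cognitive")
    cm = CohortMatrix(cohort.scores[cols], {c: "cognitive" for c in cols})
    som = train_som(cm, SOMConfig(seed=SEED))
    tbl = run_topography_tests(som, labels, n_permutations=9999, seed=SEED)
    out = BASE / "topography"
    pio.write_table(tbl, out / "topography_tests.csv", f"seed={SEED}")
    print(tbl.round(4).to_string(index=False))
    sig = tbl[tbl.p_raw < 0.05]
    if len(sig):
        print("significant category topographies:", list(sig.category))
    else:
        print("no category significantly predicts map position")


if __name__ == "__main__":
    main()
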