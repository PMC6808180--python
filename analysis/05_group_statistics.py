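"""Compare the consensus groups on measures inside and outside the map.

One-way ANOVA with Tukey post hocs per measure (Bonferroni within the
cognitive/learning/behavior families), goodness-of-fit chi-squares for
referral reasons and diagnosis flags across clusters, per-cluster gender
splits against the overall proportion, and two varimax-rotated factors
per questionnaire compared across groups.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phenosom import io as pio
from phenosom.cohort import generate_questionnaires
from phenosom.groupstats import (bonferroni, compare_categories,
                                 compare_gender, compare_measures,
                                 oneway_anova, questionnaire_factors)
from phenosom.topo import DEFAULT_CATEGORIES

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 19


def main() -> None:
    cohort, _ = pio.read_cohort(BASE / "cohort" / "cohort.csv")
    labels = pio.read_labels(BASE / "cohort" / "labels.csv")
    labels = labels.loc[cohort.scores.index]
    children = pd.read_csv(BASE / "consensus" / "consensus_children.csv",
                           comment="#").set_index("child_id")
    modal = children.loc[cohort.scores.index, "modal_cluster"].to_numpy() - 1

    out = BASE / "stats"
    omni, pairwise = compare_measures(cohort.scores, modal, cohort.families)
    pio.write_table(omni.round(4), out / "measure_anova.csv", f"seed={SEED}")
    pio.write_table(pairwise.round(4), out / "measure_tukey.csv",
                    f"seed={SEED}")
    n_sig = int((omni.p_corrected < 0.001).sum())
    print(f"{n_sig}/{len(omni)} measures differ across groups at "
          "corrected p < 0.001")

    cats = compare_categories(labels, modal, DEFAULT_CATEGORIES)
    pio.write_table(cats.round(4), out / "category_chi2.csv", f"seed={SEED}")
    sig = cats[cats.p_corrected < 0.05]
    print("categories predicting group membership:",
          list(sig.category) or "none")

    gender = compare_gender(labels, modal)
    pio.write_table(gender.round(4), out / "gender_chi2.csv", f"seed={SEED}")

    quest = generate_questionnaires(labels, seed=SEED)
    rows = []
    for prefix, label in (("brief", "executive function"),
                          ("ccc2", "communication")):
        cols = [c for c in quest.columns if c.startswith(prefix)]
        sol = questionnaire_factors(quest[cols], n_factors=2)
        print(f"{label}: two factors explain "
              f"{sol.variance_explained:.1f}% of subscale variance")
        for fac in sol.scores.columns:
            res = oneway_anova(sol.scores[fac].to_numpy(), modal)
            rows.append(dict(questionnaire=prefix, factor=fac, F=res.F,
                             p_raw=res.p))
    factors = pd.DataFrame(rows)
    for q, grp in factors.groupby("questionnaire"):
        factors.loc[grp.index, "p_corrected"] = bonferroni(
            grp["p_raw"].to_numpy(), m=len(grp))
    pio.write_table(factors.round(4), out / "factor_anova.csv", f"seed={SEED}")


if __name__ == "__main__":
    main()
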