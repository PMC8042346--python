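"""Extract the 18 behavioral variables from the raw task logs and BIT scores.

Produces features.csv (N x 18) and reports group means of the variables that
define the subtype contrasts (reaction time, left/right ratio, reselection).
"""

import pandas as pd

from common import RUN_DIR, RESULTS, run_stage

if __name__ == "__main__":
    run_stage("metrics", copy=["features.csv", "features.meta.json"])
    table = pd.read_csv(RESULTS / "features.csv", index_col="patient_id")
    truth = pd.read_csv(RUN_DIR / "cohort" / "truth.csv", index_col="patient_id")
    by = table.groupby(truth["subtype"])
    print("Feature table:", table.shape, "->", RESULTS / "features.csv")
    print("\nPer-subtype means of headline variables:")
    print(by[["RTmean", "LRratio", "ReSel_pct", "InitialPos", "MSc_Ex"]]
          .mean().round(2).to_string())
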