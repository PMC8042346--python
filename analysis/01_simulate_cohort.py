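"""Simulate the default 122-patient six-subtype cohort.

Writes the raw cohort (task logs, BIT scores, lesion volumes, ground-truth
labels) into the shared run directory and reports the subtype composition.
"""

import pandas as pd

from common import RUN_DIR, run_stage

if __name__ == "__main__":
    run_stage("simulate", copy=[])
    truth = pd.read_csv(RUN_DIR / "cohort" / "truth.csv")
    counts = truth["subtype"].value_counts().sort_index()
    print("Simulated cohort written to", RUN_DIR / "cohort")
    print("Planted subtype counts:")
    print(counts.to_string())
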