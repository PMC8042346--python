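"""Project simulated recovery cases through the frozen models and summarize
their cluster-to-cluster transitions.
"""

import pandas as pd

from common import RUN_DIR, RESULTS, run_stage

if __name__ == "__main__":
    run_stage("longitudinal", copy=["trajectories.csv", "transitions.csv"])
    traj = pd.read_csv(RESULTS / "trajectories.csv")
    print("Cluster label sequences per simulated case:")
    for case, rows in traj.groupby("patient_id"):
        labels = " -> ".join(str(v) for v in rows.sort_values("day")["label"])
        print(f"  {case}: {labels}")
    print("\nTransition count matrix:")
    print(pd.read_csv(RESULTS / "transitions.csv", index_col=0).to_string())
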