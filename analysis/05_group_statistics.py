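"""Nonparametric comparison of PC scores across the discovered clusters.

Kruskal-Wallis per component with Steel-Dwass all-pairs post hoc.
"""

import pandas as pd

from common import RUN_DIR, RESULTS, run_stage

if __name__ == "__main__":
    run_stage("stats", copy=["kruskal_wallis.csv", "steel_dwass_*.csv"])
    kw = pd.read_csv(RESULTS / "kruskal_wallis.csv")
    print("Kruskal-Wallis by component:")
    print(kw.to_string(index=False))
    sd = pd.read_csv(RESULTS / "steel_dwass_PC1.csv", index_col=0)
    n_sig = (sd.to_numpy() < 0.05).sum() // 2
    print(f"\nSteel-Dwass on PC1: {n_sig} of {sd.shape[0]*(sd.shape[0]-1)//2} "
          "pairs significant at 0.05")
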