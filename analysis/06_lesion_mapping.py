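"""Lesion overlap, cluster subtraction with the >=50-point criterion, cosine
similarity among cluster maps, and VLSM of the PC scores.

Volumes stay under scratch/; the region tables and similarity matrix are
copied into results/.
"""

import pandas as pd

from common import RUN_DIR, RESULTS, run_stage

if __name__ == "__main__":
    run_stage("lesions", copy=["cosine_similarity.csv", "subtraction_regions.csv"])
    cos = pd.read_csv(RESULTS / "cosine_similarity.csv", index_col=0)
    print("Pairwise cosine similarity among cluster overlap maps:")
    print(cos.round(3).to_string())
    regions = pd.read_csv(RESULTS / "subtraction_regions.csv")
    dominant = regions[regions["dominant"]]
    print("\nDominant (>=50 percentage-point) regions per subtraction contrast:")
    cols = ["contrast", "region", "max_pct"]
    print(dominant[cols].to_string(index=False) if len(dominant)
          else "  none reached the criterion")
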