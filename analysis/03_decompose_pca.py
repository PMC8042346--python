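"""Correlation-scale PCA of the 18 variables.

Reports the eigenvalue spectrum, the retained component count, and the
variables loading most strongly on each retained component.
"""

import json

import numpy as np
import pandas as pd

from common import RUN_DIR, RESULTS, run_stage

if __name__ == "__main__":
    run_stage("pca", copy=["pca_model.json", "scores.csv", "correlation.csv"])
    model = json.loads((RESULTS / "pca_model.json").read_text())
    eig = np.array(model["eigenvalues"])
    cum = np.array(model["cumulative"])
    k = model["retained"]
    print(f"Retained {k} components; cumulative variance {100*cum[k-1]:.2f}%")
    print("Eigenvalues:", eig.round(2)[:8], "...")
    load = np.array(model["loadings"])
    cols = model["columns"]
    for j in range(k):
        top = np.argsort(-np.abs(load[:, j]))[:4]
        desc = ", ".join(f"{cols[i]} ({load[i, j]:+.2f})" for i in top)
        print(f"PC{j+1} strongest loadings: {desc}")
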