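"""Shared plumbing for the numbered analysis drivers.

Each driver runs one pipeline stage into a shared run directory under
scratch/ (which also holds the NIfTI volumes), then copies that stage's
tables into results/ for inspection.  Drivers accept ``--seed`` (default 1).
"""

from __future__ import annotations

import argparse
import shutil
from pathlib import Path

from neglectmap.pipeline import STAGES, RunConfig, run

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def run_stage(stage: str, copy: list[str]) -> Path:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed, stages={s: s == stage for s in STAGES})
    # upstream stages must exist; run them on demand the first time
    order = STAGES[: STAGES.index(stage)]
    for prereq in order:
        marker = {
            "simulate": RUN_DIR / "cohort" / "task_logs.jsonl",
            "metrics": RUN_DIR / "features.csv",
            "pca": RUN_DIR / "scores.csv",
            "cluster": RUN_DIR / "assignments.csv",
            "stats": RUN_DIR / "kruskal_wallis.csv",
            "lesions": RUN_DIR / "cosine_similarity.csv",
        }[prereq]
        if not marker.exists():
            pre = RunConfig(seed=args.seed, stages={s: s == prereq for s in STAGES})
            run(pre, RUN_DIR)
    run(cfg, RUN_DIR)
    RESULTS.mkdir(exist_ok=True)
    for pattern in copy:
        for f in RUN_DIR.glob(pattern):
            if f.is_file():
                shutil.copy(f, RESULTS / f.name)
    return RUN_DIR
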