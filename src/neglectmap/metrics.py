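"""The 18 behavioral variables computed from raw attention-task logs and BIT scores.

Six variables come from the endogenous attention task (EndoAT: the patient
freely selects all 35 targets), six from the exogenous attention task (ExoAT:
the patient responds to single flashed targets, one flash per target), and six
are the conventional Behavioural Inattention Test (BIT) subtest scores.

Undefined quantities (ratios with an empty denominator, statistics of an empty
log) are propagated as NaN, never as infinity, so that downstream stages can
apply an explicit complete-case policy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import grid

#: Fixed column order of the feature table.
FEATURE_COLUMNS = [
    "MSc_En",
    "LRdiff_En",
    "ReSel_pct",
    "ReSelL_pct",
    "InitialPos",
    "CrossMid",
    "MSc_Ex",
    "LRdiff_Ex",
    "RTmean",
    "RTstd",
    "LRratio",
    "EndlineLR",
    "BIT_Line",
    "BIT_Letter",
    "BIT_Star",
    "BIT_Copy",
    "BIT_Bisect",
    "BIT_Draw",
]

#: Per-variable metadata: task of origin, valid range (None = unbounded),
#: and whether larger values indicate worse performance.
VARIABLE_INFO: dict[str, dict] = {
    "MSc_En": {"task": "EndoAT", "range": (0, 35), "higher_is_worse": True},
    "LRdiff_En": {"task": "EndoAT", "range": (-15, 15), "higher_is_worse": True},
    "ReSel_pct": {"task": "EndoAT", "range": (0, 100), "higher_is_worse": True},
    "ReSelL_pct": {"task": "EndoAT", "range": (0, 100), "higher_is_worse": True},
    "InitialPos": {"task": "EndoAT", "range": (1, 35), "higher_is_worse": False},
    "CrossMid": {"task": "EndoAT", "range": (0, None), "higher_is_worse": False},
    "MSc_Ex": {"task": "ExoAT", "range": (0, 35), "higher_is_worse": True},
    "LRdiff_Ex": {"task": "ExoAT", "range": (-15, 15), "higher_is_worse": True},
    "RTmean": {"task": "ExoAT", "range": (0, None), "higher_is_worse": True},
    "RTstd": {"task": "ExoAT", "range": (0, None), "higher_is_worse": True},
    "LRratio": {"task": "ExoAT", "range": (0, None), "higher_is_worse": True},
    "EndlineLR": {"task": "ExoAT", "range": (0, None), "higher_is_worse": True},
    "BIT_Line": {"task": "BIT", "range": (0, 36), "higher_is_worse": False},
    "BIT_Letter": {"task": "BIT", "range": (0, 40), "higher_is_worse": False},
    "BIT_Star": {"task": "BIT", "range": (0, 54), "higher_is_worse": False},
    "BIT_Copy": {"task": "BIT", "range": (0, 4), "higher_is_worse": False},
    "BIT_Bisect": {"task": "BIT", "range": (0, 9), "higher_is_worse": False},
    "BIT_Draw": {"task": "BIT", "range": (0, 3), "higher_is_worse": False},
}

BIT_MAXIMA = (36, 40, 54, 4, 9, 3)


@dataclass
class EndoATLog:
    """Ordered sequence of selected target indices (1..35); repeats and
    omissions are allowed, an empty log means no target was ever selected."""

    selections: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.selections:
            if not 1 <= s <= grid.N_TARGETS:
                raise ValueError(f"selection {s} outside 1..{grid.N_TARGETS}")


@dataclass
class ExoATLog:
    """One trial per flashed target: (target index, responded flag, RT in ms).

    ``rt`` must be positive when ``responded`` is True and is NaN otherwise.
    """

    trials: list[tuple[int, bool, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for target, responded, rt in self.trials:
            if not 1 <= target <= grid.N_TARGETS:
                raise ValueError(f"target {target} outside 1..{grid.N_TARGETS}")
            if target in seen:
                raise ValueError(f"duplicate trial for target {target}")
            seen.add(target)
            if responded and not rt > 0:
                raise ValueError(f"non-positive RT {rt} for responded target {target}")


@dataclass
class BITScores:
    """Six conventional BIT subtest scores."""

    line_cancel: int
    letter_cancel: int
    star_cancel: int
    copy: int
    bisect: int
    draw: int

    def __post_init__(self) -> None:
        vals = (self.line_cancel, self.letter_cancel, self.star_cancel,
                self.copy, self.bisect, self.draw)
        for v, hi, name in zip(vals, BIT_MAXIMA,
                               ("line", "letter", "star", "copy", "bisect", "draw")):
            if not 0 <= v <= hi:
                raise ValueError(f"BIT {name} score {v} outside 0..{hi}")

    def as_dict(self) -> dict[str, int]:
        return {
            "BIT_Line": self.line_cancel,
            "BIT_Letter": self.letter_cancel,
            "BIT_Star": self.star_cancel,
            "BIT_Copy": self.copy,
            "BIT_Bisect": self.bisect,
            "BIT_Draw": self.draw,
        }


def _first_occurrences(selections: Sequence[int]) -> list[int]:
    seen: set[int] = set()
    out = []
    for s in selections:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def endoat_variables(log: EndoATLog, resel_left_denominator: str = "left") -> dict[str, float]:
    """Compute the six EndoAT variables.

    MSc_En        : 35 minus the number of distinct targets selected.
    LRdiff_En     : unselected left-hemispace targets minus unselected right.
    ReSel_pct     : 100 * reselections / total selections (a reselection is a
                    selection of a target selected earlier in the log).
    ReSelL_pct    : the same restricted to left-hemispace targets; the
                    denominator counts left-target selections when
                    ``resel_left_denominator == "left"`` (default) or all
                    selections when ``"all"``.
    InitialPos    : first selected index.
    CrossMid      : hemispace alternations along the deduplicated
                    (first-occurrence) sequence; midline-column targets are
                    skipped since they belong to neither hemispace.
    """
    if resel_left_denominator not in ("left", "all"):
        raise ValueError("resel_left_denominator must be 'left' or 'all'")
    sel = log.selections
    distinct = set(sel)
    total = len(sel)

    msc = grid.N_TARGETS - len(distinct)
    left_missed = sum(1 for t in grid.left_targets() if t not in distinct)
    right_missed = sum(1 for t in grid.right_targets() if t not in distinct)

    reselections = total - len(distinct)
    resel_pct = 100.0 * reselections / total if total else math.nan

    left_sel = [s for s in sel if grid.hemispace(s) == grid.LEFT]
    seen: set[int] = set()
    left_resel = 0
    for s in sel:
        if s in seen and grid.hemispace(s) == grid.LEFT:
            left_resel += 1
        seen.add(s)
    denom = len(left_sel) if resel_left_denominator == "left" else total
    resel_left_pct = 100.0 * left_resel / denom if denom else math.nan

    initial = float(sel[0]) if sel else math.nan

    dedup = [s for s in _first_occurrences(sel) if grid.hemispace(s) != grid.MID]
    cross = sum(1 for a, b in zip(dedup, dedup[1:])
                if grid.hemispace(a) != grid.hemispace(b))

    return {
        "MSc_En": float(msc),
        "LRdiff_En": float(left_missed - right_missed),
        "ReSel_pct": resel_pct,
        "ReSelL_pct": resel_left_pct,
        "InitialPos": initial,
        "CrossMid": float(cross),
    }


def exoat_variables(log: ExoATLog) -> dict[str, float]:
    """Compute the six ExoAT variables.

    MSc_Ex     : number of unresponded flashes.
    LRdiff_Ex  : left-hemispace misses minus right-hemispace misses.
    RTmean/std : over responded trials (population SD, NaN on empty).
    LRratio    : mean RT left hemispace / mean RT right hemispace.
    EndlineLR  : mean RT leftmost column / mean RT rightmost column.
    Ratios with an empty numerator or denominator group are NaN.
    """
    responded_rts = [rt for _, r, rt in log.trials if r]
    missed = [t for t, r, _ in log.trials if not r]

    def mean_rt(targets_filter) -> float:
        rts = [rt for t, r, rt in log.trials if r and targets_filter(t)]
        return float(np.mean(rts)) if rts else math.nan

    left_miss = sum(1 for t in missed if grid.hemispace(t) == grid.LEFT)
    right_miss = sum(1 for t in missed if grid.hemispace(t) == grid.RIGHT)

    rt_mean = float(np.mean(responded_rts)) if responded_rts else math.nan
    rt_std = float(np.std(responded_rts)) if responded_rts else math.nan

    left_mean = mean_rt(lambda t: grid.hemispace(t) == grid.LEFT)
    right_mean = mean_rt(lambda t: grid.hemispace(t) == grid.RIGHT)
    lr_ratio = left_mean / right_mean if not (math.isnan(left_mean) or math.isnan(right_mean)) else math.nan

    col1_mean = mean_rt(lambda t: grid.column_of(t) == 0)
    col7_mean = mean_rt(lambda t: grid.column_of(t) == grid.N_COLS - 1)
    endline = col1_mean / col7_mean if not (math.isnan(col1_mean) or math.isnan(col7_mean)) else math.nan

    return {
        "MSc_Ex": float(len(missed)),
        "LRdiff_Ex": float(left_miss - right_miss),
        "RTmean": rt_mean,
        "RTstd": rt_std,
        "LRratio": lr_ratio,
        "EndlineLR": endline,
    }


def patient_features(endo: EndoATLog, exo: ExoATLog, bit: BITScores,
                     resel_left_denominator: str = "left") -> dict[str, float]:
    """All 18 variables for a single patient, in ``FEATURE_COLUMNS`` order."""
    row: dict[str, float] = {}
    row.update(endoat_variables(endo, resel_left_denominator))
    row.update(exoat_variables(exo))
    row.update({k: float(v) for k, v in bit.as_dict().items()})
    return {c: row[c] for c in FEATURE_COLUMNS}


def build_feature_table(cohort) -> pd.DataFrame:
    """N x 18 feature table for a cohort; row order follows the cohort.

    Missing cells (undefined ratios, empty logs) are NaN; the index is the
    patient id.
    """
    rows = {}
    for p in cohort.patients:
        rows[p.patient_id] = patient_features(p.endo, p.exo, p.bit)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    table.index.name = "patient_id"
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with the fixed 18-column header plus a JSON metadata sidecar."""
    path = Path(path)
    table.to_csv(path)
    sidecar = path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(VARIABLE_INFO, indent=2))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="patient_id")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table[FEATURE_COLUMNS]
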