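"""Longitudinal projection of repeated assessments through frozen models.

The cross-sectional PCA and mixture model are fitted once and never refit:
each later timepoint's 18 variables are standardized with the stored
means/SDs, projected onto the retained loadings, and scored against the fixed
mixture components.  This guarantees that adding timepoints can never change
the cross-sectional solution or any other patient's labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmm import MixtureModel
from .metrics import FEATURE_COLUMNS
from .pca import PCModel, project


@dataclass
class TimepointResult:
    day: float
    scores: np.ndarray
    posteriors: np.ndarray
    label: int  # 1-based cluster label
    confident: bool  # max posterior >= the confidence floor


@dataclass
class Trajectory:
    patient_id: str
    timepoints: list[TimepointResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        days = [t.day for t in self.timepoints]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("timepoints must be strictly increasing")

    def labels(self) -> list[int]:
        return [t.label for t in self.timepoints]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.timepoints:
            row = {"patient_id": self.patient_id, "day": t.day,
                   "label": t.label, "confident": t.confident}
            row.update({f"PC{i + 1}": s for i, s in enumerate(t.scores)})
            row.update({f"post_{k + 1}": p for k, p in enumerate(t.posteriors)})
            rows.append(row)
        return pd.DataFrame(rows)


def project_timepoint(pc_model: PCModel, mixture: MixtureModel,
                      features: dict[str, float] | pd.Series,
                      min_posterior: float = 0.5) -> TimepointResult | None:
    """Project one assessment's 18 variables to (scores, posteriors, label).

    Returns None when any variable is missing — no silent imputation; the
    caller decides how to handle flagged timepoints.  The label is 1-based
    (argmax posterior); ``confident`` is False below the posterior floor.
    """
    row = pd.Series(features)
    if row.reindex(FEATURE_COLUMNS).isna().any():
        return None
    table = row.reindex(FEATURE_COLUMNS).to_frame().T
    table.index = ["_tp"]
    scores = project(pc_model, table).to_numpy(float)[0]
    post = mixture.predict_proba(scores[None, :])[0]
    label = int(np.argmax(post)) + 1
    return TimepointResult(day=np.nan, scores=scores, posteriors=post,
                           label=label, confident=bool(post.max() >= min_posterior))


def build_trajectory(patient_id: str, pc_model: PCModel, mixture: MixtureModel,
                     assessments: list[tuple[float, dict[str, float] | pd.Series]],
                     min_posterior: float = 0.5) -> Trajectory:
    """Project a patient's (day, features) assessments; missing-variable
    timepoints are dropped with their day recorded as flagged."""
    tps = []
    for day, feats in assessments:
        res = project_timepoint(pc_model, mixture, feats, min_posterior)
        if res is not None:
            res.day = float(day)
            tps.append(res)
    return Trajectory(patient_id=patient_id, timepoints=tps)


def transition_table(trajectories: list[Trajectory], n_clusters: int) -> pd.DataFrame:
    """Counts of consecutive cluster-to-cluster moves; diagonal = persistence.

    Square matrix over 1..n_clusters; empty input gives the zero matrix.
    """
    counts = np.zeros((n_clusters, n_clusters), int)
    for tr in trajectories:
        labels = tr.labels()
        for a, b in zip(labels, labels[1:]):
            counts[a - 1, b - 1] += 1
    idx = [f"c{k}" for k in range(1, n_clusters + 1)]
    return pd.DataFrame(counts, index=idx, columns=idx)
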