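"""PCA of the 18 behavioral variables on the correlation scale.

Variables mix milliseconds, counts and test scores, so the decomposition is an
eigendecomposition of the correlation matrix (z-scored data).  Component
retention combines the Kaiser rule (eigenvalue > 1) with a cumulative
proportion-of-variance threshold.  The fitted model is frozen — means, SDs and
loadings are stored — so later timepoints can be projected into the same
component space.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PCModel:
    """Frozen standardization + loading model.

    ``loadings`` holds all unit-norm eigenvectors (p x p, columns ordered by
    decreasing eigenvalue, sign convention: largest-magnitude entry of each
    column is positive); ``retained`` is the number of components kept.
    """

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    cumulative: np.ndarray
    retained: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": self.columns,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "cumulative": self.cumulative.tolist(),
            "retained": self.retained,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCModel":
        d = json.loads(Path(path).read_text())
        return cls(columns=d["columns"], means=np.array(d["means"]),
                   sds=np.array(d["sds"]), loadings=np.array(d["loadings"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   cumulative=np.array(d["cumulative"]), retained=d["retained"])


def complete_cases(features: pd.DataFrame) -> pd.DataFrame:
    """Rows without missing cells; logs how many were dropped and why."""
    mask = features.notna().all(axis=1)
    dropped = features.index[~mask]
    if len(dropped):
        reasons = {pid: list(features.columns[features.loc[pid].isna()])
                   for pid in dropped}
        log.info("complete-case analysis dropped %d/%d rows: %s",
                 len(dropped), len(features), reasons)
    return features.loc[mask]


def correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between all variables (complete cases)."""
    data = complete_cases(features)
    corr = np.corrcoef(data.to_numpy(float), rowvar=False)
    return pd.DataFrame(corr, index=features.columns, columns=features.columns)


def fit_pca(features: pd.DataFrame, cum_threshold: float = 0.70) -> PCModel:
    """Fit the correlation-scale PCA and choose the retained component count.

    Raises on constant columns (zero variance makes z-scores undefined) and
    on fewer than two complete rows.
    """
    data = complete_cases(features).to_numpy(float)
    if data.shape[0] < 2:
        raise ValueError("PCA needs at least two complete rows")
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=1)
    constant = [c for c, s in zip(features.columns, sds) if s == 0 or not np.isfinite(s)]
    if constant:
        raise ValueError(f"constant column(s) make correlations undefined: {constant}")

    z = (data - means) / sds
    corr = (z.T @ z) / (data.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    # deterministic sign: largest-|entry| of each loading column is positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    cumulative = np.cumsum(eigval) / eigval.sum()
    model = PCModel(columns=list(features.columns), means=means, sds=sds,
                    loadings=eigvec, eigenvalues=eigval, cumulative=cumulative,
                    retained=0)
    model.retained = select_components(model, cum_threshold=cum_threshold)
    return model


def select_components(model: PCModel, cum_threshold: float = 0.70,
                      kaiser_cutoff: float = 1.0) -> int:
    """Smallest K whose cumulative proportion reaches the threshold while the
    K-th eigenvalue still passes the Kaiser cutoff.

    If the two criteria cannot be met jointly the Kaiser count is used, with a
    warning; the result is floored at one component.
    """
    eig = model.eigenvalues
    kaiser_k = int(np.sum(eig > kaiser_cutoff))
    reach = np.nonzero(model.cumulative >= cum_threshold)[0]
    cum_k = int(reach[0]) + 1 if len(reach) else len(eig)

    if kaiser_k == 0:
        warnings.warn("no eigenvalue exceeds the Kaiser cutoff; retaining 1 component")
        return 1
    if cum_k > kaiser_k:
        warnings.warn(
            f"cumulative threshold {cum_threshold} needs {cum_k} components but only "
            f"{kaiser_k} pass the Kaiser rule; retaining {kaiser_k}")
        return kaiser_k
    return cum_k


def project(model: PCModel, features: pd.DataFrame) -> pd.DataFrame:
    """Scores of (complete) rows on the retained components.

    Projection uses the frozen means/SDs, so the same features always map to
    the same scores regardless of what else is in the table.
    """
    if list(features.columns) != model.columns:
        raise ValueError("feature columns do not match the fitted model")
    data = complete_cases(features)
    z = (data.to_numpy(float) - model.means) / model.sds
    scores = z @ model.loadings[:, : model.retained]
    return pd.DataFrame(scores, index=data.index,
                        columns=[f"PC{i + 1}" for i in range(model.retained)])
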