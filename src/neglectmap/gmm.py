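"""Gaussian-mixture subtype discovery on retained PC scores.

The candidate family crosses G = 1..10 components with six covariance
structures — spherical/diagonal/full, each either shared (tied) across
components or free per component — giving the canonical 60-candidate grid.
Each candidate is fit by EM with k-means++ initialization and multiple
restarts; model selection uses the Bayesian information criterion and the
integrated complete-data likelihood, both on the "higher is better" scale:

    BIC = 2 * loglik - m * log N
    ICL = BIC - 2 * sum of assignment entropies

so ICL <= BIC always, with equality when clusters are perfectly separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

log = logging.getLogger(__name__)

FAMILIES = ("spherical_tied", "spherical", "diag_tied", "diag", "full_tied", "full")

_FAMILY_ORDER = {f: i for i, f in enumerate(FAMILIES)}  # simpler first


def n_cov_params(family: str, g: int, d: int) -> int:
    if family == "spherical_tied":
        return 1
    if family == "spherical":
        return g
    if family == "diag_tied":
        return d
    if family == "diag":
        return g * d
    if family == "full_tied":
        return d * (d + 1) // 2
    if family == "full":
        return g * d * (d + 1) // 2
    raise ValueError(f"unknown covariance family {family!r}")


def n_free_params(family: str, g: int, d: int) -> int:
    """Mixing weights + means + covariance parameters."""
    return (g - 1) + g * d + n_cov_params(family, g, d)


@dataclass
class MixtureCandidate:
    n_components: int
    family: str
    loglik: float
    n_params: int
    bic: float
    icl: float
    converged: bool
    weights: np.ndarray | None = None
    loglik_history: list[float] | None = None
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None  # always expanded to (G, d, d)
    responsibilities: np.ndarray | None = None
    skip_reason: str | None = None


@dataclass
class MixtureModel:
    """Selected mixture with responsibilities and hard assignments."""

    candidate: MixtureCandidate
    labels: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.argmax(self.candidate.responsibilities, axis=1)

    @property
    def n_components(self) -> int:
        return self.candidate.n_components

    def cluster_means(self) -> np.ndarray:
        return self.candidate.means

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior component probabilities for new points."""
        c = self.candidate
        lp = _log_prob(np.asarray(X, float), c.means, c.covariances) + np.log(c.weights)
        lp -= logsumexp(lp, axis=1, keepdims=True)
        return np.exp(lp)


def _log_prob(X: np.ndarray, means: np.ndarray, covs: np.ndarray,
              diagonal: bool = False) -> np.ndarray:
    """Per-component Gaussian log-density, covariances as (G, d, d).

    ``diagonal=True`` takes a vectorized path valid when every covariance is
    diagonal (the spherical and diagonal families).
    """
    n, d = X.shape
    g = means.shape[0]
    if diagonal:
        var = covs[:, np.arange(d), np.arange(d)]  # (g, d)
        diff2 = (X[:, None, :] - means[None]) ** 2
        maha = (diff2 / var[None]).sum(axis=2)
        logdet = np.log(var).sum(axis=1)
        return -0.5 * (d * np.log(2 * np.pi) + logdet[None] + maha)
    out = np.empty((n, g))
    for k in range(g):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        sol = np.linalg.solve(L, diff.T)
        maha = np.sum(sol ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _m_step_cov(X: np.ndarray, resp: np.ndarray, means: np.ndarray,
                family: str, reg: float) -> np.ndarray:
    """Family-constrained covariance update, expanded to (G, d, d)."""
    n, d = X.shape
    g = means.shape[0]
    nk = resp.sum(axis=0)

    if family in ("full", "full_tied"):
        covs = np.empty((g, d, d))
        for k in range(g):
            diff = X - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
        if family == "full_tied":
            pooled = np.einsum("k,kij->ij", nk, covs) / n
            covs = np.repeat(pooled[None], g, axis=0)
        covs[:, np.arange(d), np.arange(d)] += reg
        return covs

    # diagonal / spherical: per-component weighted variances per dimension,
    # via squared deviations from the mean (stable for tight clusters)
    diff2 = (X[:, None, :] - means[None]) ** 2
    var = np.einsum("ng,ngd->gd", resp, diff2) / nk[:, None]
    if family == "diag_tied":
        var = np.repeat((nk @ var / n)[None], g, axis=0)
    elif family == "spherical":
        var = np.repeat(var.mean(axis=1, keepdims=True), d, axis=1)
    elif family == "spherical_tied":
        var = np.full((g, d), (nk @ var.mean(axis=1)) / n)
    var = np.clip(var, reg, None)
    covs = np.zeros((g, d, d))
    covs[:, np.arange(d), np.arange(d)] = var
    return covs


def _em_once(X: np.ndarray, g: int, family: str, rng: np.random.Generator,
             tol: float, max_iter: int, reg: float):
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, g, random_state=int(rng.integers(2 ** 31)))
    # hard one-hot init from nearest center
    dist = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    resp = np.zeros((n, g))
    resp[np.arange(n), np.argmin(dist, axis=1)] = 1.0
    resp = 0.99 * resp + 0.01 / g  # soften so no component starts empty

    ll_prev = -np.inf
    converged = False
    weights = means = covs = None
    history: list[float] = []
    for _ in range(max_iter):
        nk = resp.sum(axis=0)
        # a component holding fewer than two weighted points collapses onto
        # the variance floor and spikes the likelihood; reject the restart
        if np.any(nk < 2.0):
            return None
        weights = nk / n
        means = resp.T @ X / nk[:, None]
        covs = _m_step_cov(X, resp, means, family, reg)

        lp = _log_prob(X, means, covs,
                       diagonal=family not in ("full", "full_tied")) + np.log(weights)
        norm = logsumexp(lp, axis=1, keepdims=True)
        ll = float(norm.sum())
        history.append(ll)
        resp = np.exp(lp - norm)

        # stop when the signed improvement falls below the relative tolerance;
        # the variance floor can make the objective drift slightly downward on
        # degenerate within-component dimensions, which also means "done"
        if ll < ll_prev - tol * (abs(ll_prev) + 1.0):
            log.debug("EM log-likelihood decreased (%g -> %g)", ll_prev, ll)
        if np.isfinite(ll_prev) and ll - ll_prev <= tol * (abs(ll_prev) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return weights, means, covs, resp, ll_prev, converged, history


def _entropy(resp: np.ndarray) -> float:
    r = np.clip(resp, 1e-300, 1.0)
    return float(-(r * np.log(r)).sum())


def fit_candidate(X: np.ndarray, g: int, family: str, seed: int,
                  n_init: int = 10, tol: float = 1e-6, max_iter: int = 300,
                  reg: float = 1e-6) -> MixtureCandidate:
    """Fit one (G, family) candidate with multiple EM restarts."""
    X = np.asarray(X, float)
    n, d = X.shape
    m = n_free_params(family, g, d)
    if n < g:
        return MixtureCandidate(g, family, -np.inf, m, -np.inf, -np.inf, False,
                                skip_reason=f"N={n} < G={g}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        out = _em_once(X, g, family, rng, tol, max_iter, reg)
        if out is None:
            continue
        if best is None or out[4] > best[4]:
            best = out
    if best is None:
        return MixtureCandidate(g, family, -np.inf, m, -np.inf, -np.inf, False,
                                skip_reason="all restarts degenerate")
    weights, means, covs, resp, ll, converged, history = best
    bic = 2.0 * ll - m * np.log(n)
    icl = bic - 2.0 * _entropy(resp)
    return MixtureCandidate(g, family, ll, m, bic, icl, converged,
                            weights=weights, means=means, covariances=covs,
                            responsibilities=resp, loglik_history=history)


def fit_candidates(scores: pd.DataFrame | np.ndarray, seed: int,
                   g_range: Sequence[int] = range(1, 11),
                   families: Sequence[str] = FAMILIES,
                   n_init: int = 10, tol: float = 1e-6,
                   max_iter: int = 300) -> list[MixtureCandidate]:
    """Fit the full candidate grid (default 10 x 6 = 60 models)."""
    X = scores.to_numpy(float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(g_range) * len(families)) % (2 ** 31)
    out = []
    i = 0
    for g in g_range:
        for fam in families:
            out.append(fit_candidate(X, g, fam, int(seeds[i]), n_init=n_init,
                                     tol=tol, max_iter=max_iter))
            i += 1
    return out


def candidate_table(candidates: list[MixtureCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "G": c.n_components, "family": c.family, "loglik": c.loglik,
        "n_params": c.n_params, "BIC": c.bic, "ICL": c.icl,
        "converged": c.converged, "skip_reason": c.skip_reason,
    } for c in candidates])


def select_model(candidates: list[MixtureCandidate],
                 bic_tolerance: float = 10.0) -> MixtureModel:
    """Best-ICL candidate among those within ``bic_tolerance`` of the best BIC.

    Ties break toward fewer components, then the simpler covariance family.
    Non-converged or skipped candidates are excluded.
    """
    ok = [c for c in candidates if c.converged and c.skip_reason is None]
    if not ok:
        raise ValueError("no converged candidate to select from")
    best_bic = max(c.bic for c in ok)
    window = [c for c in ok if c.bic >= best_bic - bic_tolerance]
    chosen = max(window, key=lambda c: (c.icl, -c.n_components, -_FAMILY_ORDER[c.family]))
    bic_best = max(ok, key=lambda c: c.bic)
    if (chosen.n_components, chosen.family) != (bic_best.n_components, bic_best.family):
        log.info("BIC-best (G=%d, %s) and selection (G=%d, %s) differ; "
                 "ICL within BIC window decided", bic_best.n_components,
                 bic_best.family, chosen.n_components, chosen.family)
    return MixtureModel(chosen)


def cluster_summary(model: MixtureModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster size, percentage (two decimals) and mean PC scores."""
    labels = model.labels
    n = len(labels)
    rows = []
    for k in range(model.n_components):
        mask = labels == k
        row = {"cluster": k + 1, "size": int(mask.sum()),
               "pct": round(100.0 * mask.sum() / n, 2)}
        for j, col in enumerate(scores.columns):
            row[f"mean_{col}"] = float(scores.to_numpy(float)[mask, j].mean()) if mask.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def membership_percentages(sizes: Sequence[int]) -> list[float]:
    """Cluster membership percentages (to two decimals) from member counts."""
    total = sum(sizes)
    if total == 0:
        raise ValueError("empty clustering")
    return [round(100.0 * s / total, 2) for s in sizes]
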