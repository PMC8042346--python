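"""Mixture fitting and BIC/ICL selection: closed-form checks, planted-cluster
recovery, selection policy, and an independent cross-check against sklearn on
the covariance families both implementations share."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from neglectmap import gmm


def _blobs(rng, centers, n_per, sd=1.0):
    return np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])


def test_free_parameter_counts_grow_with_family_complexity():
    d, g = 4, 3
    # within each shape, tied <= free; across shapes at fixed sharing,
    # spherical <= diag <= full
    for shape in ("spherical", "diag", "full"):
        assert gmm.n_free_params(f"{shape}_tied", g, d) <= gmm.n_free_params(shape, g, d)
    for tied in ("_tied", ""):
        assert (gmm.n_free_params("spherical" + tied, g, d)
                <= gmm.n_free_params("diag" + tied, g, d)
                <= gmm.n_free_params("full" + tied, g, d))
    assert gmm.n_free_params("full", g, d) == (g - 1) + g * d + g * d * (d + 1) // 2


def test_one_component_bic_matches_closed_form_gaussian():
    x = np.array([[1.0], [2.0], [4.0], [7.0], [11.0]])
    cand = gmm.fit_candidate(x, 1, "spherical_tied", seed=0, n_init=1)
    mu, var = x.mean(), x.var() + 1e-6  # EM reg floor on the variance
    ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (x - mu) ** 2 / var)
    assert cand.loglik == pytest.approx(ll, rel=1e-9)
    assert cand.n_params == 2  # one mean, one variance
    assert cand.bic == pytest.approx(2 * ll - 2 * np.log(5), rel=1e-9)
    assert cand.icl == pytest.approx(cand.bic)  # zero assignment entropy


def test_icl_never_exceeds_bic(rng):
    x = _blobs(rng, [(0, 0), (3, 3)], 60)
    for cand in gmm.fit_candidates(x, seed=4, g_range=range(1, 4)):
        if cand.converged:
            assert cand.icl <= cand.bic + 1e-9


def test_single_cloud_selects_one_component(rng):
    x = rng.normal(0, 1, size=(150, 3))
    model = gmm.select_model(gmm.fit_candidates(x, seed=5, g_range=range(1, 5)))
    assert model.n_components == 1


def test_three_separated_clusters_recovered_exactly(rng):
    x = _blobs(rng, [(0, 0), (10, 0), (0, 10)], 100)
    truth = np.repeat([0, 1, 2], 100)
    model = gmm.select_model(gmm.fit_candidates(x, seed=6, g_range=range(1, 7)))
    assert model.n_components == 3
    assert adjusted_rand_score(truth, model.labels) == 1.0


def test_em_loglik_is_monotone_within_tolerance(rng):
    x = _blobs(rng, [(0, 0), (3, 1), (6, 0)], 60)
    for fam in gmm.FAMILIES:
        cand = gmm.fit_candidate(x, 3, fam, seed=2, n_init=3)
        hist = np.asarray(cand.loglik_history)
        drops = np.diff(hist)
        assert (drops >= -1e-6 * (np.abs(hist[:-1]) + 1)).all(), fam


def test_responsibilities_rows_sum_to_one(rng):
    x = _blobs(rng, [(0, 0), (4, 4)], 50)
    cand = gmm.fit_candidate(x, 3, "full", seed=8)
    assert np.allclose(cand.responsibilities.sum(axis=1), 1.0, atol=1e-9)


def test_candidate_skipped_when_fewer_points_than_components(rng):
    cand = gmm.fit_candidate(rng.normal(size=(3, 2)), 5, "diag", seed=1)
    assert cand.skip_reason is not None and not cand.converged


def test_loglik_matches_sklearn_on_shared_families(rng):
    x = _blobs(rng, [(0, 0, 0), (6, 6, 6)], 80)
    pairs = {"full": "full", "diag": "diag", "spherical": "spherical",
             "full_tied": "tied"}
    for ours, theirs in pairs.items():
        cand = gmm.fit_candidate(x, 2, ours, seed=3, n_init=5)
        sk = GaussianMixture(2, covariance_type=theirs, n_init=5,
                             reg_covar=1e-6, random_state=0).fit(x)
        assert cand.loglik == pytest.approx(sk.score(x) * len(x), rel=1e-4), ours


def _cand(g, fam, bic, icl):
    return gmm.MixtureCandidate(g, fam, 0.0, 1, bic, icl, True,
                                weights=np.ones(g) / g, means=np.zeros((g, 1)),
                                covariances=np.ones((g, 1, 1)),
                                responsibilities=np.ones((5, g)) / g)


def test_selection_policy_prefers_icl_within_bic_window():
    best_both = _cand(3, "diag", bic=-100.0, icl=-120.0)
    assert gmm.select_model([best_both, _cand(2, "diag", -130.0, -135.0)]
                            ).candidate is best_both
    # BIC-best and ICL-best differ: ICL decides inside the tolerance window
    bic_best = _cand(5, "full", bic=-100.0, icl=-160.0)
    icl_best = _cand(3, "diag", bic=-105.0, icl=-140.0)
    chosen = gmm.select_model([bic_best, icl_best], bic_tolerance=10.0)
    assert chosen.candidate is icl_best
    # outside the window the ICL-best is ignored
    chosen = gmm.select_model([bic_best, icl_best], bic_tolerance=2.0)
    assert chosen.candidate is bic_best
    with pytest.raises(ValueError):
        gmm.select_model([gmm.MixtureCandidate(2, "diag", -np.inf, 1, -np.inf,
                                               -np.inf, False)])


def test_cluster_summary_percentages(rng):
    import pandas as pd
    sizes = (6, 20, 8, 50, 22, 16)
    labels = np.repeat(np.arange(6), sizes)
    resp = np.zeros((122, 6))
    resp[np.arange(122), labels] = 1.0
    cand = gmm.MixtureCandidate(6, "diag", 0.0, 1, 0.0, 0.0, True,
                                weights=np.full(6, 1 / 6), means=np.zeros((6, 2)),
                                covariances=np.tile(np.eye(2), (6, 1, 1)),
                                responsibilities=resp)
    scores = pd.DataFrame(rng.normal(size=(122, 2)), columns=["PC1", "PC2"])
    summary = gmm.cluster_summary(gmm.MixtureModel(cand), scores)
    assert summary["size"].sum() == 122
    assert summary["pct"].tolist() == [4.92, 16.39, 6.56, 40.98, 18.03, 13.11]
    assert gmm.membership_percentages([10]) == [100.0]
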