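"""Generator behavior: determinism, degenerate noise-free limits, and
convergence of feature marginals to their parametric expectations."""

import numpy as np
import pytest
from scipy import stats as sps

from neglectmap import grid, metrics, synthetic
from neglectmap.synthetic import (LesionFocus, SimulationConfig, SubtypeSpec,
                                  default_cohort_config, generate_cohort,
                                  generate_endoat_log, generate_exoat_log,
                                  generate_lesion_volume)


def _clean_spec(**kw):
    base = dict(id=1, prevalence=1.0, start_position_dist={1: 1.0})
    base.update(kw)
    return SubtypeSpec(**base)


def test_noise_free_subtype_selects_everything(rng):
    cfg = SimulationConfig(n_patients=5, subtypes=[_clean_spec()], seed=3,
                           generate_lesions=False)
    cohort = generate_cohort(cfg)
    for p in cohort.patients:
        assert sorted(p.endo.selections) == list(range(1, 36))
        assert all(r for _, r, _ in p.exo.trials)


def test_same_seed_is_bit_identical():
    cfg = default_cohort_config(n_patients=30, seed=42)
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    for pa, pb in zip(a.patients, b.patients):
        assert pa.endo.selections == pb.endo.selections
        assert pa.exo.trials == pb.exo.trials or all(
            ta[:2] == tb[:2] and (ta[2] == tb[2] or (np.isnan(ta[2]) and np.isnan(tb[2])))
            for ta, tb in zip(pa.exo.trials, pb.exo.trials))
        assert pa.bit == pb.bit
        assert np.array_equal(pa.lesion, pb.lesion)


def test_two_subtype_counts_within_binomial_bounds():
    spec1 = _clean_spec(id=1, prevalence=0.5)
    spec2 = _clean_spec(id=2, prevalence=0.5)
    cfg = SimulationConfig(n_patients=200, subtypes=[spec1, spec2], seed=9,
                           generate_lesions=False)
    counts = generate_cohort(cfg).truth_labels().value_counts()
    lo, hi = sps.binom.ppf([0.005, 0.995], 200, 0.5)
    assert lo <= counts.loc[1] <= hi


def test_columnwise_left_start_gives_initial_column_one(rng):
    log = generate_endoat_log(_clean_spec(crossing_style="columnwise"), rng)
    assert len(log.selections) == 35 and len(set(log.selections)) == 35
    assert grid.column_of(log.selections[0]) == 0


def test_total_left_miss_gradient_removes_left_targets(rng):
    spec = _clean_spec(endo_miss_gradient=(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0),
                       start_position_dist={4: 1.0})
    log = generate_endoat_log(spec, rng)
    assert sorted(log.selections) == sorted(t for t in range(1, 36)
                                            if grid.hemispace(t) != grid.LEFT)


def test_reselection_rate_converges_to_parameter(rng):
    spec = _clean_spec(reselect_prob=0.5)
    vals = [metrics.endoat_variables(generate_endoat_log(spec, rng))["ReSel_pct"]
            for _ in range(10_000)]
    assert abs(np.mean(vals) - 50.0) < 1.0


def test_exoat_closed_form_endline_ratio(rng):
    spec = _clean_spec(rt_base=400.0, rt_left_gradient=50.0, rt_sd=0.0)
    v = metrics.exoat_variables(generate_exoat_log(spec, rng))
    assert v["EndlineLR"] == pytest.approx((400 + 6 * 50) / 400)
    assert v["LRratio"] > 1


def test_exoat_total_left_miss_gradient(rng):
    spec = _clean_spec(exo_miss_gradient=(1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0))
    v = metrics.exoat_variables(generate_exoat_log(spec, rng))
    assert v["MSc_Ex"] == 15 and v["LRdiff_Ex"] == 15


def test_exoat_miss_count_converges(rng):
    grad = (0.4, 0.3, 0.2, 0.1, 0.0, 0.0, 0.0)
    spec = _clean_spec(exo_miss_gradient=grad)
    expected = 5 * sum(grad)  # five targets per column
    n = 5000
    vals = [metrics.exoat_variables(generate_exoat_log(spec, rng))["MSc_Ex"]
            for _ in range(n)]
    se = np.std(vals, ddof=1) / np.sqrt(n)
    assert abs(np.mean(vals) - expected) < 3 * se


def test_generated_features_respect_ranges(small_features):
    for name, info in metrics.VARIABLE_INFO.items():
        lo, hi = info["range"]
        col = small_features[name].dropna()
        assert (col >= lo).all(), name
        if hi is not None:
            assert (col <= hi).all(), name


def test_lesion_sphere_and_determinism():
    rng = np.random.default_rng(5)
    spec = _clean_spec(lesion_foci=[LesionFocus((4, 5, 6), 0.0, prob=1.0)])
    vol = generate_lesion_volume(spec, (10, 10, 10), rng, background_prob=0.0)
    assert vol.sum() == 1 and vol[4, 5, 6] == 1
    a = generate_lesion_volume(spec, (10, 10, 10), np.random.default_rng(7), 0.1)
    b = generate_lesion_volume(spec, (10, 10, 10), np.random.default_rng(7), 0.1)
    assert np.array_equal(a, b)


def test_default_cohort_matches_described_contrasts():
    cfg = default_cohort_config(n_patients=400, seed=21)
    cfg.generate_lesions = False
    table = metrics.build_feature_table(generate_cohort(cfg))
    truth = generate_cohort(cfg).truth_labels()
    by = table.groupby(truth.values)
    rt = by["RTmean"].mean()
    # subtype 1 globally slow; 2 slowed by the left gradient; 6 fastest
    assert rt.loc[1] > rt.loc[2] > rt.loc[6]
    # subtype 2 has the steepest left-right asymmetry
    assert by["LRratio"].mean().idxmax() == 2
    # subtype 3 reselects the most; subtype 1 reselects on the right only
    assert by["ReSel_pct"].mean().idxmax() == 3
    assert by["ReSelL_pct"].mean().loc[1] < by["ReSel_pct"].mean().loc[1]
    # subtypes 4 vs 5: right vs left initial-selection bias
    assert by["InitialPos"].mean().loc[4] > by["InitialPos"].mean().loc[5]


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=5, subtypes=[], seed=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=5, subtypes=[_clean_spec(prevalence=0.4)], seed=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=5, subtypes=[_clean_spec()], grid_shape=(6, 6), seed=0)
    with pytest.raises(ValueError):
        _clean_spec(reselect_prob=1.5)
    with pytest.raises(ValueError):
        _clean_spec(bit_means=(40, 40, 54, 4, 9, 3))


def test_cohort_roundtrip_through_disk(tmp_path):
    cfg = default_cohort_config(n_patients=8, seed=2)
    cohort = generate_cohort(cfg)
    synthetic.write_cohort(cohort, tmp_path)
    back = synthetic.read_cohort(tmp_path)
    assert [p.patient_id for p in back.patients] == [p.patient_id for p in cohort.patients]
    for pa, pb in zip(cohort.patients, back.patients):
        assert pa.endo.selections == pb.endo.selections
        assert pa.subtype == pb.subtype and pa.bit == pb.bit
        assert np.array_equal(pa.lesion, pb.lesion)
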