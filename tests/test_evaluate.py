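"""ROC/AUC on tied discrete scores, Youden bands, and diagnostic metrics."""

import numpy as np
import pytest

import vurscore as vs
from vurscore.evaluate import (
    RiskBands,
    _counts_at_threshold,
    band_metrics,
    capped_subgroup_analysis,
    pairwise_auc,
    roc_auc,
    threshold_metrics,
    youden_bands,
)
from vurscore.scoring import ScoreDistribution


def _random_dist(rng, max_score=7, max_count=30):
    while True:
        n0 = tuple(int(x) for x in rng.integers(0, max_count, max_score + 1))
        n1 = tuple(int(x) for x in rng.integers(0, max_count, max_score + 1))
        if sum(n0) and sum(n1):
            return ScoreDistribution(n0, n1)


# -- AUC ---------------------------------------------------------------------


def test_auc_perfect_separation():
    dist = ScoreDistribution((50, 0, 0, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0, 0, 5))
    assert roc_auc(dist).auc == pytest.approx(1.0)


def test_auc_identical_distributions():
    dist = ScoreDistribution((10, 20, 10), (10, 20, 10))
    assert roc_auc(dist).auc == pytest.approx(0.5)


def test_auc_empty_class_undefined():
    with pytest.raises(vs.UndefinedStatisticError):
        roc_auc(ScoreDistribution((5, 5), (0, 0)))


def test_auc_matches_allpairs_oracle_on_random_distributions():
    """Threshold-sweep AUC equals the brute-force tie-half pair count."""
    rng = np.random.default_rng(1234)
    for _ in range(100):
        dist = _random_dist(rng)
        assert roc_auc(dist).auc == pytest.approx(pairwise_auc(dist), abs=1e-12)


def test_auc_equals_trapezoid_over_roc_points():
    rng = np.random.default_rng(99)
    for _ in range(20):
        dist = _random_dist(rng)
        res = roc_auc(dist)
        xs, ys = zip(*res.points)
        assert np.trapezoid(ys, xs) == pytest.approx(res.auc, abs=1e-12)


def test_roc_points_monotone(table2_dist):
    res = roc_auc(table2_dist)
    xs, ys = zip(*res.points)
    assert all(x2 >= x1 for x1, x2 in zip(xs, xs[1:]))
    assert all(y2 >= y1 for y1, y2 in zip(ys, ys[1:]))
    assert res.points[0] == (0.0, 0.0)
    assert res.points[-1] == (1.0, 1.0)


def test_reference_auc_and_ci(table2_dist):
    res = roc_auc(table2_dist)
    assert res.auc == pytest.approx(0.8983, abs=5e-4)
    assert res.ci_low < res.auc < res.ci_high
    delong = roc_auc(table2_dist, ci_method="delong")
    assert delong.auc == res.auc
    # both normal approximations should be in the same ballpark
    assert delong.ci_low == pytest.approx(res.ci_low, abs=0.03)


# -- Youden bands ------------------------------------------------------------


def test_reference_bands_are_3_and_5(table2_dist):
    bands = youden_bands(table2_dist)
    assert (bands.lower_cut, bands.upper_cut) == (3, 5)
    assert bands.bands == (("low", 0, 2), ("moderate", 3, 4), ("high", 5, 7))


def test_perfect_separation_cut_has_unit_youden_index():
    dist = ScoreDistribution((40, 40, 0, 0), (0, 0, 10, 10))
    bands = youden_bands(dist, high_specificity_floor=0.97)
    assert bands.lower_cut == 2
    tp, fp, fn, tn = _counts_at_threshold(dist, 2)
    assert tp / (tp + fn) + tn / (tn + fp) - 1 == pytest.approx(1.0)


def test_lower_cut_matches_exhaustive_scan():
    rng = np.random.default_rng(555)
    for _ in range(100):
        dist = _random_dist(rng)
        best_j, best_t = -np.inf, None
        for t in range(1, dist.max_score + 1):
            tp, fp, fn, tn = _counts_at_threshold(dist, t)
            j = tp / (tp + fn) + tn / (tn + fp) - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        try:
            bands = youden_bands(dist, high_specificity_floor=0.5)
            assert bands.lower_cut == best_t
        except vs.BandConstructionError:
            # no threshold above the maximizer reaches the floor; the
            # maximizer itself is still checked through the error path
            pass


def test_youden_ties_take_smallest_threshold():
    # J(t) identical at t=1 and t=2 by construction
    dist = ScoreDistribution((10, 0, 10), (5, 0, 5))
    assert youden_bands(dist, high_specificity_floor=0.4).lower_cut == 1


def test_unreachable_specificity_floor_errors():
    # negatives pile up at the top score: no threshold above the Youden
    # maximizer ever reaches 97% specificity
    dist = ScoreDistribution((10, 10, 10), (1, 5, 20))
    with pytest.raises(vs.BandConstructionError):
        youden_bands(dist, high_specificity_floor=0.97)


def test_invalid_band_boundaries_rejected():
    with pytest.raises(vs.ParameterError):
        RiskBands(lower_cut=5, upper_cut=3, max_score=7)


# -- threshold & band metrics ------------------------------------------------


def test_threshold_five_reference_metrics(table2_dist):
    m = threshold_metrics(table2_dist, 5)
    assert (m.tp, m.fp, m.fn, m.tn) == (38, 25, 48, 933)
    assert 100 * m.sensitivity == pytest.approx(44.2, abs=0.05)
    assert 100 * m.specificity == pytest.approx(97.4, abs=0.05)
    assert 100 * m.ppv == pytest.approx(60.3, abs=0.05)
    assert 100 * m.npv == pytest.approx(95.1, abs=0.05)
    assert m.or_point == pytest.approx(29.5, abs=0.1)
    assert m.or_ci_low == pytest.approx(16.6, abs=0.1)
    assert m.or_ci_high == pytest.approx(52.9, abs=0.1)


def test_threshold_four_counts(table2_dist):
    m = threshold_metrics(table2_dist, 4)
    assert (m.tp, m.fp, m.fn, m.tn) == (63, 108, 23, 850)
    assert m.tp + m.fp == 171  # 63 severe cases found among 171 test-positives


def test_sensitivity_one_when_no_low_score_positives():
    dist = ScoreDistribution((5, 5, 5), (0, 3, 3))
    assert threshold_metrics(dist, 1).sensitivity == pytest.approx(1.0)


def test_metric_monotonicity_and_conservation(table2_dist):
    prev_se, prev_sp = np.inf, -np.inf
    for t in range(1, table2_dist.max_score + 1):
        m = threshold_metrics(table2_dist, t)
        assert m.total == table2_dist.total
        assert m.sensitivity <= prev_se + 1e-12
        assert m.specificity >= prev_sp - 1e-12
        prev_se, prev_sp = m.sensitivity, m.specificity


def test_degenerate_margin_flagged_not_zero():
    dist = ScoreDistribution((0, 5), (0, 5))  # nobody below threshold 1
    m = threshold_metrics(dist, 1)
    assert "npv" in m.undefined
    assert np.isnan(m.npv)


def test_band_metrics_reference_rows(table2_dist):
    bands = youden_bands(table2_dist)
    be = band_metrics(table2_dist, bands)
    low, moderate, high = be.reports
    assert (low.n, low.events) == (706, 9)
    assert 100 * low.event_rate == pytest.approx(1.27, abs=0.01)
    assert 100 * low.metrics.sensitivity == pytest.approx(10.5, abs=0.05)
    assert 100 * low.metrics.specificity == pytest.approx(27.2, abs=0.05)
    assert low.metrics.or_point == pytest.approx(0.04, abs=0.005)
    assert low.metrics.or_ci_low == pytest.approx(0.02, abs=0.005)
    assert low.metrics.or_ci_high == pytest.approx(0.09, abs=0.005)
    assert (moderate.n, moderate.events) == (275, 39)
    assert 100 * moderate.event_rate == pytest.approx(14.2, abs=0.05)
    assert moderate.metrics.or_point == pytest.approx(2.5, abs=0.05)
    assert moderate.metrics.or_ci_low == pytest.approx(1.6, abs=0.05)
    assert moderate.metrics.or_ci_high == pytest.approx(4.0, abs=0.05)
    assert (high.n, high.events) == (63, 38)
    assert 100 * high.event_rate == pytest.approx(60.3, abs=0.05)


def test_band_event_rates_strictly_increase(table2_dist):
    be = band_metrics(table2_dist, youden_bands(table2_dist))
    rates = [b.event_rate for b in be.reports]
    assert rates[0] < rates[1] < rates[2]


def test_band_outcome_chi2_significant(table2_dist):
    be = band_metrics(table2_dist, youden_bands(table2_dist))
    assert be.p_value < 0.001


def test_single_band_covering_everything():
    m = threshold_metrics(ScoreDistribution((0, 90), (0, 10)), 1)
    assert m.sensitivity == pytest.approx(1.0)
    assert m.ppv == pytest.approx(0.1)  # PPV collapses to prevalence


# -- capped-score subgroup ---------------------------------------------------


def test_no_dmsa_subgroup_reference(reference_cohort, reference_weights, fixture_set):
    rep = capped_subgroup_analysis(reference_cohort, reference_weights)
    assert rep.n == 537
    assert rep.n_events == 18
    assert rep.capped_max_score == 5
    assert rep.threshold == 5
    m = rep.metrics
    assert (m.tp, m.fp, m.fn, m.tn) == (9, 15, 9, 504)
    assert 100 * m.sensitivity == pytest.approx(50.0, abs=0.05)
    assert 100 * m.specificity == pytest.approx(97.1, abs=0.05)
    assert 100 * m.ppv == pytest.approx(37.5, abs=0.05)
    assert 100 * m.npv == pytest.approx(98.2, abs=0.05)
    assert m.or_point == pytest.approx(33.6, abs=0.05)
    # matches the packaged subgroup counts
    nd = fixture_set.nodmsa.contingency()
    assert (m.tp, m.fn, m.fp, m.tn) == (nd.a, nd.b, nd.c, nd.d)


def test_subgroup_or_is_exact_cross_product():
    assert (9 * 504) / (9 * 15) == pytest.approx(33.6)


def test_subgroup_requires_some_missing_modality(reference_weights, tiny_cohort):
    complete = vs.Cohort(tuple(r for r in tiny_cohort if r.dmsa_done == 1))
    with pytest.raises(vs.DegenerateTableError):
        capped_subgroup_analysis(complete, reference_weights)


def test_subgroup_requires_weighted_modality(reference_cohort):
    spec = vs.WeightSpec(entries={"male": 1}, ors={"male": 2.0}, min_or_anchor=2.0)
    with pytest.raises(vs.ParameterError):
        capped_subgroup_analysis(reference_cohort, spec)
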