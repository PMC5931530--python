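"""Classification protocol: selection, LOO, severity scaling, significance."""

import numpy as np
import pytest

import eegnld
from eegnld.classify import ClassifierSettings, _loo_accuracy
from eegnld.synthetic import SubjectOutcome


def synthetic_matrix(n_per_class=20, n_features=1026, n_informative=10,
                     shift=1.5, seed=0, groups=("LRC-", "ASD")):
    """Feature-level cohort: Gaussian noise + class shift in a known subset."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.repeat([0, 1], n_per_class)
    X[:, :n_informative] += shift * y[:, None]
    css = np.where(y == 1, rng.uniform(4, 10, n), rng.uniform(1, 2.5, n))
    outs = [SubjectOutcome(f"S{i:03d}", groups[y[i]], float(css[i]), 6.0)
            for i in range(n)]
    return X, outs


# ---------------------------------------------------------------------------
# recursive feature elimination

def test_rfe_recovers_informative_features():
    recalls = []
    for seed in range(20):
        X, outs = synthetic_matrix(seed=seed, shift=1.2)
        y = np.array([o.group == "ASD" for o in outs], dtype=int)
        idx = eegnld.rfe_select(X, y, n_features=10)
        recalls.append(np.isin(idx, np.arange(10)).sum() / 10)
    assert np.median(recalls) >= 0.8
    assert np.isin(eegnld.rfe_select(X, y, n_features=10), np.arange(10)).sum() >= 7


def test_rfe_never_returns_empty_on_noise():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 200))
    y = np.repeat([0, 1], 15)
    idx = eegnld.rfe_select(X, y, n_features=10)
    assert idx.size == 10


def test_rfe_keeps_a_copy_of_duplicated_informative_feature():
    X, outs = synthetic_matrix(n_informative=1, shift=3.0, seed=1)
    X[:, 1] = X[:, 0]   # exact duplicate of the informative column
    y = np.array([o.group == "ASD" for o in outs], dtype=int)
    idx = eegnld.rfe_select(X, y, n_features=10)
    assert 0 in idx or 1 in idx


def test_rfe_cv_mode_and_single_class_error():
    X, outs = synthetic_matrix(n_per_class=10, n_features=60, shift=2.0)
    y = np.array([o.group == "ASD" for o in outs], dtype=int)
    idx = eegnld.rfe_select(X, y, cv=3, min_features=5)
    assert idx.size >= 5
    with pytest.raises(ValueError):
        eegnld.rfe_select(X, np.zeros(len(y)))


# ---------------------------------------------------------------------------
# severity scaling and labeling

def test_css_affine_midpoint():
    est = eegnld.css_from_distance(np.array([-2.0, 2.0]),
                                   np.array([1.0, 10.0]), 0.0)
    assert est == pytest.approx(5.5)


def test_css_clipped_to_scale():
    assert eegnld.css_from_distance(np.array([-2.0, 2.0]),
                                    np.array([1.0, 10.0]), 50.0) == 10.0
    assert eegnld.css_from_distance(np.array([-2.0, 2.0]),
                                    np.array([1.0, 10.0]), -50.0) == 1.0


def test_css_monotone_in_distance():
    d_tr = np.array([-3.0, -1.0, 1.0, 3.0])
    c_tr = np.array([1.0, 2.0, 6.0, 9.0])
    grid = np.linspace(-10, 10, 41)
    est = [eegnld.css_from_distance(d_tr, c_tr, d) for d in grid]
    assert all(b >= a for a, b in zip(est, est[1:]))


def test_css_rejects_degenerate_training():
    with pytest.raises(ValueError):
        eegnld.css_from_distance(np.array([1.0, 1.0]), np.array([2.0, 3.0]), 0.0)


def test_uncertainty_labeling():
    assert eegnld.label_with_uncertainty(4.0) == "uncertain"
    assert eegnld.label_with_uncertainty(5.2) == "ASD"
    assert eegnld.label_with_uncertainty(2.0) == "not-ASD"
    assert eegnld.label_with_uncertainty(4.5) == "ASD"
    assert eegnld.label_with_uncertainty(3.5) == "not-ASD"
    assert eegnld.label_with_uncertainty(4.0, uncertainty=False) == "ASD"
    assert eegnld.label_with_uncertainty(3.9, uncertainty=False) == "not-ASD"


# ---------------------------------------------------------------------------
# metrics

def _results(pred_true_pairs):
    return [
        eegnld.PredictionResult(f"S{i}", 6.0, p, 0.0, 5.0, t, 5.0)
        for i, (p, t) in enumerate(pred_true_pairs)
    ]


def test_metrics_standard_definitions():
    pairs = ([("ASD", "ASD")] * 9 + [("not-ASD", "ASD")]
             + [("not-ASD", "not-ASD")] * 9 + [("ASD", "not-ASD")])
    rep = eegnld.metrics(_results(pairs))
    assert (rep.tp, rep.fn, rep.tn, rep.fp) == (9, 1, 9, 1)
    assert rep.sensitivity == rep.specificity == rep.ppv == 0.9


def test_metrics_all_correct():
    rep = eegnld.metrics(_results([("ASD", "ASD")] * 5
                                  + [("not-ASD", "not-ASD")] * 5))
    assert rep.sensitivity == rep.specificity == rep.ppv == 1.0


def test_metrics_uncertain_excluded_and_counted():
    pairs = ([("ASD", "ASD")] * 20 + [("not-ASD", "not-ASD")] * 19
             + [("uncertain", "not-ASD")] * 7)
    rep = eegnld.metrics(_results(pairs))
    assert rep.n_uncertain == 7
    assert rep.tp + rep.fp + rep.tn + rep.fn == 39
    # without exclusion, uncertain predictions count as non-ASD calls
    rep_keep = eegnld.metrics(_results(pairs), exclude_uncertain=False)
    assert rep_keep.tp + rep_keep.fp + rep_keep.tn + rep_keep.fn == 46
    assert rep_keep.n_uncertain == 7


def test_metrics_zero_denominator_is_nan():
    rep = eegnld.metrics(_results([("not-ASD", "not-ASD")] * 5))
    assert np.isnan(rep.sensitivity) and np.isnan(rep.ppv)
    assert rep.specificity == 1.0


# ---------------------------------------------------------------------------
# leave-one-out protocol

def test_loo_separable_cohort_all_correct():
    X, outs = synthetic_matrix(shift=2.0, seed=2)
    res = eegnld.loo_predict(X, outs)
    assert len(res) == len(outs)
    for r in res:
        assert 1.0 <= r.css_estimate <= 10.0
        assert (r.css_estimate >= 4.5) == (r.true_label == "ASD") or \
            r.predicted_label == "uncertain"
    acc = np.mean([(r.css_estimate >= 4) == (r.true_label == "ASD")
                   for r in res])
    assert acc == 1.0


def test_loo_null_accuracy_near_chance():
    accs = []
    for seed in range(20):
        X, outs = synthetic_matrix(n_per_class=6, n_features=200,
                                   n_informative=0, shift=0.0, seed=seed)
        accs.append(_loo_accuracy(X, outs, ClassifierSettings()))
    assert abs(np.mean(accs) - 0.5) < 0.2


def test_loo_hra_scored_by_full_endpoint_model():
    X, outs = synthetic_matrix(shift=2.0, seed=3)
    rng = np.random.default_rng(0)
    X_h = rng.standard_normal((5, X.shape[1]))
    X_h[:, :10] += 0.75   # halfway between the class means
    outs_h = [SubjectOutcome(f"H{i}", "HRA-", 3.0, 6.0) for i in range(5)]
    res = eegnld.loo_predict(np.vstack([X, X_h]), outs + outs_h)
    hra = [r for r in res if r.subject_id.startswith("H")]
    assert len(hra) == 5
    ends = [r for r in res if not r.subject_id.startswith("H")]
    lo = np.mean([r.css_estimate for r in ends if r.true_label != "ASD"])
    hi = np.mean([r.css_estimate for r in ends if r.true_label == "ASD"])
    mid = np.mean([r.css_estimate for r in hra])
    assert lo < mid < hi


def test_loo_leakage_guard_label_and_css():
    """A subject's own label/severity never affect their own prediction."""
    X, outs = synthetic_matrix(n_per_class=8, n_features=120, shift=1.0, seed=4)
    res = eegnld.loo_predict(X, outs)
    probe = 3
    flipped = list(outs)
    flipped[probe] = SubjectOutcome(outs[probe].subject_id, "ASD", 9.9,
                                    outs[probe].age_months)
    res_flipped = eegnld.loo_predict(X, flipped)
    r0 = next(r for r in res if r.subject_id == outs[probe].subject_id)
    r1 = next(r for r in res_flipped if r.subject_id == outs[probe].subject_id)
    assert r0.decision_distance == r1.decision_distance
    assert r0.css_estimate == r1.css_estimate


def test_loo_requires_three_per_class():
    X, outs = synthetic_matrix(n_per_class=2, n_features=20, shift=1.0)
    with pytest.raises(ValueError):
        eegnld.loo_predict(X, outs)


# ---------------------------------------------------------------------------
# permutation significance

def test_permutation_p_small_for_separable():
    X, outs = synthetic_matrix(n_per_class=10, n_features=120, shift=3.0, seed=6)
    p, count, obs = eegnld.permutation_pvalue(X, outs, n_trials=19, seed=1)
    assert obs == 1.0
    assert count == 0
    assert p == pytest.approx(1 / 20)


def test_permutation_single_trial_values():
    X, outs = synthetic_matrix(n_per_class=5, n_features=30, shift=2.0, seed=7)
    p, _, _ = eegnld.permutation_pvalue(X, outs, n_trials=1, seed=2)
    assert p in (0.5, 1.0)
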