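"""Outcome classification and severity estimation.

The prediction protocol: a support-vector machine with an RBF kernel is
trained on the two endpoint outcome groups (diagnosed ASD vs low-risk
controls without ASD) under leave-one-out cross-validation; high-risk
infants without a diagnosis are scored against the model trained on the
full endpoint set.  Each subject's signed distance from the separating
surface is mapped to a severity estimate on the 1-10 calibrated scale
by an affine fit done within the training fold, and estimates falling
in the open interval (3.5, 4.5) around the diagnostic cutoff of 4 can
be labeled "uncertain" rather than forced to a side.

Everything that learns from data — median imputation of degenerate
cells, z-scoring, recursive feature elimination, the SVM itself, and
the distance-to-severity map — is fit strictly within the training
fold, so a subject's own data never touch the model that scores them.

Feature ranking inside recursive elimination needs per-feature weights,
which an RBF kernel does not expose; elimination therefore ranks with a
linear-kernel SVM and the RBF model is refit on the surviving subset
for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import RFE, RFECV
from sklearn.svm import SVC

from .synthetic import SubjectOutcome

TRAINING_GROUPS = ("ASD", "LRC-")
UNCERTAIN_ZONE = (3.5, 4.5)
CSS_CUTOFF = 4.0


@dataclass
class ClassifierSettings:
    """Protocol knobs; defaults follow the library's stock SVM parameters.

    ``n_features`` and ``rfe_step`` control recursive elimination inside
    each fold (halving steps down to 20 features keeps the per-fold cost
    linear in the feature count); ``uncertainty_zone`` enables the
    three-way labeling.
    """

    n_features: int = 20
    rfe_step: float = 0.5
    uncertainty_zone: bool = True
    css_scaling: str = "affine"  # or "minmax"
    seed: int = 0


@dataclass
class PredictionResult:
    """Leave-one-out prediction for one subject-visit."""

    subject_id: str
    age_months: float
    predicted_label: str          # "ASD" | "not-ASD" | "uncertain"
    decision_distance: float      # signed; positive is the ASD side
    css_estimate: float
    true_label: str
    true_css: float


@dataclass
class ClassificationReport:
    """Confusion counts and standard rates over a result set."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_uncertain: int
    sensitivity: float
    specificity: float
    ppv: float
    cohort_descriptor: str = ""


class _FoldModel:
    """Impute + scale + RFE + RBF SVM + distance-to-severity map, fold-local."""

    def __init__(self, X: np.ndarray, y: np.ndarray, css: np.ndarray,
                 settings: ClassifierSettings):
        self.medians = np.nanmedian(X, axis=0)
        self.medians = np.where(np.isnan(self.medians), 0.0, self.medians)
        Xi = self._impute(X)
        self.mu = Xi.mean(axis=0)
        sd = Xi.std(axis=0)
        self.sd = np.where(sd == 0, 1.0, sd)
        Xs = (Xi - self.mu) / self.sd

        n_keep = min(settings.n_features, Xs.shape[1])
        if Xs.shape[1] > n_keep:
            rfe = RFE(
                estimator=SVC(kernel="linear"),
                n_features_to_select=n_keep,
                step=settings.rfe_step,
            )
            rfe.fit(Xs, y)
            self.support = rfe.support_
        else:
            self.support = np.ones(Xs.shape[1], dtype=bool)

        self.svm = SVC(kernel="rbf")  # stock hyperparameters
        self.svm.fit(Xs[:, self.support], y)

        d_train = self.svm.decision_function(Xs[:, self.support])
        self._fit_css_map(d_train, css, settings.css_scaling)

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, dtype=np.float64, copy=True)
        bad = np.isnan(X)
        if bad.any():
            X[bad] = np.broadcast_to(self.medians, X.shape)[bad]
        return X

    def _fit_css_map(self, d: np.ndarray, css: np.ndarray, mode: str) -> None:
        if np.ptp(d) <= 0:
            raise ValueError("zero-variance training distances; cannot scale to CSS")
        if mode == "affine":
            A = np.column_stack([d, np.ones_like(d)])
            coef, *_ = np.linalg.lstsq(A, css, rcond=None)
            self.css_a, self.css_b = float(coef[0]), float(coef[1])
        elif mode == "minmax":
            self.css_a = 9.0 / np.ptp(d)
            self.css_b = 1.0 - self.css_a * d.min()
        else:
            raise ValueError(f"unknown css scaling {mode!r}")

    def predict(self, x: np.ndarray) -> tuple[float, float]:
        """(signed distance, severity estimate) for one feature vector."""
        xs = (self._impute(x[None, :]) - self.mu) / self.sd
        d = float(self.svm.decision_function(xs[:, self.support])[0])
        return d, css_from_distance_coef(self.css_a, self.css_b, d)


def css_from_distance_coef(a: float, b: float, d: float) -> float:
    return float(np.clip(a * d + b, 1.0, 10.0))


def css_from_distance(
    distances: np.ndarray, css_train: np.ndarray, d_new: float
) -> float:
    """Severity estimate for ``d_new`` via a least-squares affine map.

    Fitted from training (distance, severity) pairs and clipped to the
    calibrated 1-10 range.  The fit must be done with training-fold
    values only; this helper has no access to the scored subject.
    """
    d = np.asarray(distances, dtype=np.float64)
    c = np.asarray(css_train, dtype=np.float64)
    if d.size < 2 or np.ptp(d) <= 0:
        raise ValueError("need >= 2 training points with distinct distances")
    A = np.column_stack([d, np.ones_like(d)])
    coef, *_ = np.linalg.lstsq(A, c, rcond=None)
    return css_from_distance_coef(float(coef[0]), float(coef[1]), d_new)


def label_with_uncertainty(css_estimate: float, uncertainty: bool = True) -> str:
    """Three-way label from a severity estimate.

    A severity of 4 or above indicates ASD; with the uncertainty zone
    enabled, estimates strictly inside (3.5, 4.5) are "too close to
    call".  In binary mode the cutoff at 4 is applied directly.
    """
    lo, hi = UNCERTAIN_ZONE
    if uncertainty:
        if lo < css_estimate < hi:
            return "uncertain"
        return "ASD" if css_estimate >= hi else "not-ASD"
    return "ASD" if css_estimate >= CSS_CUTOFF else "not-ASD"


def rfe_select(
    X: np.ndarray, y: np.ndarray,
    n_features: int | None = 20, step: float = 0.5,
    cv: int | None = None, min_features: int = 10,
) -> np.ndarray:
    """Indices of features kept by recursive elimination (linear-SVM ranking).

    With ``cv`` set, the retained count is chosen by internal
    cross-validation (elimination in halving steps, accuracy scoring);
    otherwise exactly ``n_features`` survive.  Never returns an empty
    set.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need two classes for feature selection")
    X = np.asarray(X, dtype=np.float64)
    if cv is not None:
        sel = RFECV(
            estimator=SVC(kernel="linear"), step=step, cv=cv,
            scoring="accuracy", min_features_to_select=min_features,
        )
    else:
        sel = RFE(
            estimator=SVC(kernel="linear"),
            n_features_to_select=min(n_features or 1, X.shape[1]),
            step=step,
        )
    sel.fit(X, y)
    idx = np.flatnonzero(sel.support_)
    assert idx.size > 0
    return idx


def _as_outcome_arrays(outcomes: list[SubjectOutcome]):
    groups = np.array([o.group for o in outcomes])
    css = np.array([o.css for o in outcomes], dtype=np.float64)
    return groups, css


def loo_predict(
    X: np.ndarray,
    outcomes: list[SubjectOutcome],
    settings: ClassifierSettings | None = None,
) -> list[PredictionResult]:
    """Leave-one-out predictions for every subject at one age.

    Endpoint-group subjects (ASD, low-risk control) are each scored by a
    model trained on all *other* endpoint subjects; intermediate
    high-risk subjects are scored by the model trained on the full
    endpoint set.  Rows of ``X`` and ``outcomes`` are parallel; call
    once per visit age (visits are treated as independent encounters).
    """
    settings = settings or ClassifierSettings()
    X = np.asarray(X, dtype=np.float64)
    groups, css = _as_outcome_arrays(outcomes)
    train_mask = np.isin(groups, TRAINING_GROUPS)
    train_idx = np.flatnonzero(train_mask)
    y_all = (groups == "ASD").astype(int)
    for g in TRAINING_GROUPS:
        if (groups[train_idx] == g).sum() < 3:
            raise ValueError(f"need >= 3 training subjects in group {g}")

    results: list[PredictionResult] = []

    def score(model: _FoldModel, i: int) -> None:
        d, css_est = model.predict(X[i])
        label = label_with_uncertainty(css_est, settings.uncertainty_zone)
        results.append(
            PredictionResult(
                subject_id=outcomes[i].subject_id,
                age_months=outcomes[i].age_months,
                predicted_label=label,
                decision_distance=d,
                css_estimate=css_est,
                true_label="ASD" if y_all[i] else "not-ASD",
                true_css=css[i],
            )
        )

    for i in train_idx:
        fold = train_idx[train_idx != i]
        model = _FoldModel(X[fold], y_all[fold], css[fold], settings)
        score(model, i)
    rest = np.flatnonzero(~train_mask)
    if rest.size:
        full = _FoldModel(X[train_idx], y_all[train_idx], css[train_idx], settings)
        for i in rest:
            score(full, i)
    return results


def metrics(
    results: list[PredictionResult], exclude_uncertain: bool = True,
    cohort_descriptor: str = "",
) -> ClassificationReport:
    """Confusion counts and sensitivity/specificity/PPV (positive = ASD).

    Uncertain predictions are counted and, when ``exclude_uncertain``,
    removed before the rates are computed.  Zero denominators yield NaN
    rates rather than exceptions.
    """
    if not results:
        raise ValueError("empty result list")
    n_unc = sum(r.predicted_label == "uncertain" for r in results)
    used = [r for r in results if r.predicted_label != "uncertain"] \
        if exclude_uncertain else results
    tp = sum(r.predicted_label == "ASD" and r.true_label == "ASD" for r in used)
    fp = sum(r.predicted_label == "ASD" and r.true_label != "ASD" for r in used)
    tn = sum(r.predicted_label != "ASD" and r.true_label != "ASD" for r in used)
    fn = sum(r.predicted_label != "ASD" and r.true_label == "ASD" for r in used)

    def rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, n_uncertain=n_unc,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        cohort_descriptor=cohort_descriptor,
    )


def _loo_accuracy(X, outcomes, settings) -> float:
    res = loo_predict(X, outcomes, settings)
    correct = sum(
        (r.css_estimate >= CSS_CUTOFF) == (r.true_label == "ASD") for r in res
    )
    return correct / len(res)


def permutation_pvalue(
    X: np.ndarray,
    outcomes: list[SubjectOutcome],
    n_trials: int = 100,
    seed: int = 0,
    settings: ClassifierSettings | None = None,
) -> tuple[float, int, float]:
    """Empirical significance of the leave-one-out accuracy.

    The observed accuracy (binary cutoff at severity 4) is compared with
    the accuracies of ``n_trials`` re-runs of the identical pipeline
    under randomly permuted outcome labels (group and severity permuted
    together).  Returns ``(p, n_as_extreme, observed_accuracy)`` with
    the add-one estimator ``p = (1 + #{acc_perm >= acc_obs}) / (1 +
    n_trials)``, which can never report exactly zero.
    """
    if n_trials < 1:
        raise ValueError("need at least one permutation trial")
    settings = settings or ClassifierSettings(uncertainty_zone=False)
    groups, _ = _as_outcome_arrays(outcomes)
    keep = np.flatnonzero(np.isin(groups, TRAINING_GROUPS))
    X_t = np.asarray(X, dtype=np.float64)[keep]
    out_t = [outcomes[i] for i in keep]
    observed = _loo_accuracy(X_t, out_t, settings)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_trials):
        perm = rng.permutation(len(out_t))
        shuffled = [
            SubjectOutcome(
                subject_id=out_t[i].subject_id,
                group=out_t[perm[i]].group,
                css=out_t[perm[i]].css,
                age_months=out_t[i].age_months,
            )
            for i in range(len(out_t))
        ]
        try:
            acc = _loo_accuracy(X_t, shuffled, settings)
        except ValueError:
            continue  # a permutation cannot starve a class here, but be safe
        if acc >= observed - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_trials)
    return p, count, observed
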