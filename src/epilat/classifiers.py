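"""Uncertainty-banded laterality classifiers (scikit-learn estimators).

Each classifier turns per-subject features into a five-level decision in
{L, UL, U, UR, R}.  All are linear decision rules with symmetric
uncertainty bands around the decision boundary, calibrated in different
units:

* :class:`EigenlineClassifier` — a control cohort's 2-D scatter (e.g. left
  vs right normalized hippocampal volume) defines a decision line through
  its centroid along its first principal axis; decisions are banded at 1
  and 2 control standard deviations of perpendicular distance off the line.
* :class:`TristructuralLogisticClassifier` — logistic regression on the
  hippocampal/amygdalar/thalamic volume asymmetries; decisions banded on
  the probability of left-sided epileptogenicity (p = 0.5 → U,
  0.5 < p < 0.7 → UL, p ≥ 0.7 → L, mirrored on the right).
* :class:`MarginBandClassifier` — a linear max-margin separator; decisions
  banded at 0.5 and 1 times the maximum margin M of the support vectors.
* :class:`HVUClassifier` — per-measure hemispheric-variation-uncertainty
  thresholds from control diffusion asymmetries; a subject votes L or R on
  a measure only when its asymmetry exceeds the control threshold in the
  direction expected ipsilateral to seizure onset, and the votes are
  aggregated (unanimous → L/R, partial with abstentions → UL/UR).

Estimators follow scikit-learn conventions (``fit``/``predict``/
``decision_function``, trailing-underscore fitted attributes,
``get_params``/``set_params``) and compose with sklearn model selection.
``predict`` returns decision tokens as strings.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted

from . import decisions as dec

CONTROL, LEFT, RIGHT = "control", "left", "right"


def _check_2d(X, n_features=None) -> np.ndarray:
    X = check_array(X, ensure_2d=True, dtype=float)
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} features, got {X.shape[1]}")
    return X


class EigenlineClassifier(ClassifierMixin, BaseEstimator):
    """Principal-axis decision line with 1 sd / 2 sd uncertainty bands.

    Fit on a 2-D feature scatter with labels ``"control"``, ``"left"``,
    ``"right"``.  Controls define the line (centroid + first principal
    axis of their covariance) and the band width (standard deviation of
    their signed perpendicular distances); at least one lateralized
    calibration case fixes which side of the line maps to L.

    Attributes
    ----------
    centroid_ : (2,) ndarray — control centroid (origin of distances).
    direction_ : (2,) unit ndarray — first principal axis of the controls.
    normal_ : (2,) unit ndarray — normal to the decision line.
    sd_ : float — control perpendicular-residual standard deviation.
    orientation_sign_ : ±1 — maps positive signed distance to L (+1) or
        R (−1).
    """

    def __init__(self, min_controls: int = 3):
        self.min_controls = min_controls

    def fit(self, X, y):
        X = _check_2d(X, n_features=2)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        bad = set(y) - {CONTROL, LEFT, RIGHT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        controls = X[y == CONTROL]
        if controls.shape[0] < self.min_controls:
            raise ValueError(
                f"need at least {self.min_controls} controls to fit the "
                "decision line")
        self.centroid_ = controls.mean(axis=0)
        cov = np.cov(controls.T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        self.direction_ = eigvecs[:, np.argmax(eigvals)]
        self.normal_ = np.array([-self.direction_[1], self.direction_[0]])
        resid = (controls - self.centroid_) @ self.normal_
        sd = float(resid.std(ddof=1))
        along_sd = float(((controls - self.centroid_)
                          @ self.direction_).std(ddof=1))
        if sd <= 1e-10 * max(along_sd, 1.0):
            raise ValueError(
                "control scatter is collinear (zero perpendicular sd); "
                "bands undefined")
        self.sd_ = sd
        d_left = (X[y == LEFT] - self.centroid_) @ self.normal_
        d_right = (X[y == RIGHT] - self.centroid_) @ self.normal_
        if d_left.size == 0 and d_right.size == 0:
            raise ValueError(
                "orientation undefined: need at least one left or right "
                "calibration case")
        score = 0.0
        if d_left.size:
            score += d_left.mean()
        if d_right.size:
            score -= d_right.mean()
        if score == 0:
            raise ValueError("calibration cases do not separate the sides")
        self.orientation_sign_ = 1 if score > 0 else -1
        self.classes_ = np.array(dec.DECISIONS, dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Oriented signed distance off the line (positive toward L)."""
        check_is_fitted(self, "sd_")
        X = _check_2d(X, n_features=2)
        return self.orientation_sign_ * ((X - self.centroid_) @ self.normal_)

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.array([
            dec.banded_decision(v, self.sd_, 2 * self.sd_, positive=dec.L)
            for v in d], dtype=object)


class TristructuralLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Logistic decision on volume asymmetries with probability bands.

    Fit on (n, 3) normalized volume asymmetries (hippocampus, amygdala,
    thalamus) with labels ``"left"``/``"right"``; ``predict_proba_left``
    gives the modeled probability of left-sided epileptogenicity and
    ``predict`` bands it (p ≥ 0.7 → L, 0.5 < p < 0.7 → UL, p = 0.5 → U,
    0.3 < p < 0.5 → UR, p ≤ 0.3 → R).
    """

    def __init__(self, C: float = 1.0, band_halfwidth: float = 0.2):
        self.C = C
        self.band_halfwidth = band_halfwidth

    def fit(self, X, y):
        X = _check_2d(X)
        y = np.asarray(y, dtype=object)
        present = set(y)
        if present != {LEFT, RIGHT}:
            raise ValueError(
                f"need both 'left' and 'right' training labels, got "
                f"{sorted(present)}")
        self.model_ = LogisticRegression(C=self.C).fit(X, y)
        self.weights_ = self.model_.coef_[0].copy()
        self.intercept_ = float(self.model_.intercept_[0])
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array(dec.DECISIONS, dtype=object)
        return self

    def predict_proba_left(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _check_2d(X, n_features=self.n_features_in_)
        idx = list(self.model_.classes_).index(LEFT)
        return self.model_.predict_proba(X)[:, idx]

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba_left(X)
        return np.array([
            dec.banded_decision(v - 0.5, 0.0, self.band_halfwidth,
                                positive=dec.L)
            for v in p], dtype=object)


class MarginBandClassifier(ClassifierMixin, BaseEstimator):
    """Linear max-margin separator banded at 0.5 M and M.

    M is the maximum (geometric) margin of the support vectors.  With the
    default near-hard-margin regularization (``C=1e6``) the separator
    approximates the maximum-margin hyperplane of a separable sample.

    ``kind="laterality"`` expects labels ``"left"``/``"right"`` and emits
    five-level tokens.  ``kind="categorization"`` expects two arbitrary
    class labels and emits the class name when the sample sits at least
    0.5 M off the plane, else ``"uncertain"``.
    """

    def __init__(self, C: float = 1e6, kind: str = "laterality"):
        self.C = C
        self.kind = kind

    def fit(self, X, y):
        if self.kind not in ("laterality", "categorization"):
            raise ValueError(f"unknown kind {self.kind!r}")
        X = _check_2d(X)
        y = np.asarray(y, dtype=object)
        labels = sorted(set(y))
        if len(labels) != 2:
            raise ValueError(f"need exactly two classes, got {labels}")
        if self.kind == "laterality" and set(labels) != {LEFT, RIGHT}:
            raise ValueError(
                "laterality classifier needs 'left'/'right' labels")
        self.model_ = SVC(kernel="linear", C=self.C).fit(X, y)
        self.weights_ = self.model_.coef_[0].copy()
        self.intercept_ = float(self.model_.intercept_[0])
        norm = float(np.linalg.norm(self.weights_))
        if norm == 0:
            raise ValueError("degenerate separator (zero weight vector)")
        self.margin_ = 1.0 / norm     # geometric distance to the margin
        self.positive_class_ = self.model_.classes_[1]
        self.negative_class_ = self.model_.classes_[0]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Geometric signed distance from the separating plane."""
        check_is_fitted(self, "margin_")
        X = _check_2d(X, n_features=self.n_features_in_)
        return self.model_.decision_function(X) * self.margin_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        if self.kind == "laterality":
            positive = dec.L if self.positive_class_ == LEFT else dec.R
            return np.array([
                dec.banded_decision(v, 0.5 * self.margin_, self.margin_,
                                    positive=positive)
                for v in d], dtype=object)
        out = []
        for v in d:
            if abs(v) < 0.5 * self.margin_:
                out.append("uncertain")
            else:
                out.append(self.positive_class_ if v > 0
                           else self.negative_class_)
        return np.array(out, dtype=object)


def diffusion_asymmetry(left, right):
    """Hemispheric asymmetry (L − R) / ((L + R)/2) of a diffusion scalar."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("diffusion values must be positive")
    return (left - right) / ((left + right) / 2.0)


class HVUClassifier(ClassifierMixin, BaseEstimator):
    """Hemispheric-variation-uncertainty voting on diffusion asymmetries.

    Fit on control asymmetries, shape (n_controls, n_measures); the HVU
    threshold per measure is mean + 2 sd of the control absolute
    asymmetries.  ``left_direction`` gives, per measure, the asymmetry
    sign expected when the left side is epileptogenic: +1 for measures
    elevated ipsilaterally (hippocampal mean diffusivity), −1 for measures
    reduced ipsilaterally (posteroinferior cingulum FA, forniceal crus FA).

    A subject's measure votes L or R only when |asymmetry| exceeds the
    HVU; unanimous votes give L/R, one-sided votes with abstentions give
    UL/UR, anything else (including conflicting votes) gives U.
    """

    MEASURES = ("hippocampal_md", "cingulum_fa", "fornix_fa")

    def __init__(self, left_direction: tuple[int, ...] = (1, -1, -1),
                 n_sd: float = 2.0, min_controls: int = 5):
        self.left_direction = left_direction
        self.n_sd = n_sd
        self.min_controls = min_controls

    def fit(self, X, y=None):
        X = _check_2d(X, n_features=len(self.left_direction))
        if X.shape[0] < self.min_controls:
            raise ValueError(
                f"need at least {self.min_controls} controls per measure")
        if any(s not in (-1, 1) for s in self.left_direction):
            raise ValueError("left_direction entries must be ±1")
        a = np.abs(X)
        self.hvu_ = a.mean(axis=0) + self.n_sd * a.std(axis=0, ddof=1)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array(dec.DECISIONS, dtype=object)
        return self

    def votes(self, X) -> np.ndarray:
        """Per-measure votes, array of "L"/"R"/"U" of shape (n, m)."""
        check_is_fitted(self, "hvu_")
        X = _check_2d(X, n_features=self.n_features_in_)
        out = np.full(X.shape, dec.U, dtype=object)
        for j, direction in enumerate(self.left_direction):
            exceed = np.abs(X[:, j]) > self.hvu_[j]
            toward_left = np.sign(X[:, j]) == direction
            out[exceed & toward_left, j] = dec.L
            out[exceed & ~toward_left, j] = dec.R
        return out

    def predict(self, X) -> np.ndarray:
        votes = self.votes(X)
        decisions = []
        for row in votes:
            n_l = int(np.sum(row == dec.L))
            n_r = int(np.sum(row == dec.R))
            if n_l and n_r:
                decisions.append(dec.U)
            elif n_l == len(row):
                decisions.append(dec.L)
            elif n_r == len(row):
                decisions.append(dec.R)
            elif n_l:
                decisions.append(dec.UL)
            elif n_r:
                decisions.append(dec.UR)
            else:
                decisions.append(dec.U)
        return np.array(decisions, dtype=object)


# ---------------------------------------------------------------------------
# thin functional wrappers

def fit_eigenline(control_points, calibration_points, calibration_labels,
                  ) -> EigenlineClassifier:
    """Fit an eigenline from control scatter plus labeled calibration cases."""
    controls = np.asarray(control_points, dtype=float)
    calib = np.asarray(calibration_points, dtype=float)
    X = np.vstack([controls, calib])
    y = np.array([CONTROL] * len(controls) + list(calibration_labels),
                 dtype=object)
    return EigenlineClassifier().fit(X, y)


def classify_eigenline(model: EigenlineClassifier, point) -> tuple[str, float]:
    """(decision, oriented signed distance) for a single 2-vector."""
    point = np.asarray(point, dtype=float).reshape(1, -1)
    return model.predict(point)[0], float(model.decision_function(point)[0])


def fit_msa_logistic(asymmetries, labels) -> TristructuralLogisticClassifier:
    return TristructuralLogisticClassifier().fit(asymmetries, labels)


def classify_msa(model: TristructuralLogisticClassifier, x,
                 ) -> tuple[str, float]:
    """(decision, probability of left-sided epileptogenicity)."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    return model.predict(x)[0], float(model.predict_proba_left(x)[0])


def fit_margin_classifier(features, labels, kind: str = "laterality",
                          C: float = 1e6) -> MarginBandClassifier:
    return MarginBandClassifier(C=C, kind=kind).fit(features, labels)


def classify_margin(model: MarginBandClassifier, x) -> str:
    return model.predict(np.asarray(x, dtype=float).reshape(1, -1))[0]


def hvu_from_controls(control_asymmetries, **kwargs) -> HVUClassifier:
    return HVUClassifier(**kwargs).fit(control_asymmetries)


def classify_hvu(model: HVUClassifier, subject_asymmetries) -> str:
    x = np.asarray(subject_asymmetries, dtype=float).reshape(1, -1)
    return model.predict(x)[0]


# ---------------------------------------------------------------------------
# plain-text model serialization

def model_to_dict(model) -> dict:
    """Serialize a fitted banded classifier to plain python types."""
    if isinstance(model, EigenlineClassifier):
        check_is_fitted(model, "sd_")
        return {"model": "eigenline",
                "centroid": model.centroid_.tolist(),
                "direction": model.direction_.tolist(),
                "sd": model.sd_,
                "orientation_sign": model.orientation_sign_}
    if isinstance(model, TristructuralLogisticClassifier):
        check_is_fitted(model, "model_")
        return {"model": "tristructural_logistic",
                "weights": model.weights_.tolist(),
                "intercept": model.intercept_,
                "classes": list(model.model_.classes_),
                "band_halfwidth": model.band_halfwidth}
    if isinstance(model, HVUClassifier):
        check_is_fitted(model, "hvu_")
        return {"model": "hvu", "hvu": model.hvu_.tolist(),
                "left_direction": list(model.left_direction)}
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(payload: dict):
    """Rebuild a fitted classifier from :func:`model_to_dict` output."""
    kind = payload.get("model")
    if kind == "eigenline":
        m = EigenlineClassifier()
        m.centroid_ = np.asarray(payload["centroid"], dtype=float)
        m.direction_ = np.asarray(payload["direction"], dtype=float)
        m.normal_ = np.array([-m.direction_[1], m.direction_[0]])
        m.sd_ = float(payload["sd"])
        m.orientation_sign_ = int(payload["orientation_sign"])
        m.classes_ = np.array(dec.DECISIONS, dtype=object)
        return m
    if kind == "hvu":
        m = HVUClassifier(
            left_direction=tuple(payload["left_direction"]))
        m.hvu_ = np.asarray(payload["hvu"], dtype=float)
        m.n_features_in_ = m.hvu_.size
        m.classes_ = np.array(dec.DECISIONS, dtype=object)
        return m
    raise ValueError(f"unknown serialized model kind {kind!r}")


def save_model(model, path) -> None:
    """Write a fitted classifier to a plain-text YAML file."""
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh)


def load_model(path):
    import yaml
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
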