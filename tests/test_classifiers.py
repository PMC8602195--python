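import numpy as np
import pytest

from epilat import decisions as dec
from epilat.classifiers import (CONTROL, LEFT, RIGHT, EigenlineClassifier,
                                HVUClassifier, MarginBandClassifier,
                                TristructuralLogisticClassifier,
                                classify_eigenline, classify_hvu,
                                classify_margin, classify_msa,
                                diffusion_asymmetry, fit_eigenline,
                                fit_margin_classifier, fit_msa_logistic,
                                hvu_from_controls, model_from_dict,
                                model_to_dict)


def eigenline_fixture(n=40, noise=0.05, seed=0):
    """Controls along the identity line; cases displaced off it."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(1, 3, n)
    controls = np.c_[base, base + rng.normal(0, noise, n)]
    left = np.c_[base - 1.0, base + 1.0][: n // 2]
    right = np.c_[base + 1.0, base - 1.0][: n // 2]
    X = np.vstack([controls, left, right])
    y = np.array([CONTROL] * n + [LEFT] * (n // 2) + [RIGHT] * (n // 2),
                 dtype=object)
    return X, y


class TestEigenline:
    def test_direction_matches_eigendecomposition_oracle(self):
        controls = np.array([[1, 1.1], [2, 1.9], [3, 3.0]])
        model = fit_eigenline(controls, [[0.0, 3.0]], [LEFT])
        # oracle: leading eigenvector of the 2x2 covariance
        w, v = np.linalg.eigh(np.cov(controls.T))
        lead = v[:, np.argmax(w)]
        assert abs(float(model.direction_ @ lead)) == pytest.approx(1.0)
        assert abs(model.direction_[0]) == pytest.approx(0.707, abs=0.02)

    def test_collinear_controls_rejected(self):
        controls = [[1, 1], [2, 2], [3, 3], [4, 4]]
        with pytest.raises(ValueError, match="collinear"):
            fit_eigenline(controls, [[0, 1]], [LEFT])

    def test_orientation_calibrated_from_labels(self):
        controls = np.array([[1.0, 1.0], [2.0, 2.1], [3.0, 2.9],
                             [1.5, 1.6], [2.5, 2.4]])
        above, below = [0.5, 3.0], [3.0, 0.5]
        m_left_above = fit_eigenline(controls, [above], [LEFT])
        m_left_below = fit_eigenline(controls, [below], [LEFT])
        assert classify_eigenline(m_left_above, above)[0] == dec.L
        assert classify_eigenline(m_left_below, below)[0] == dec.L
        assert classify_eigenline(m_left_above, below)[0] == dec.R

    def test_missing_calibration_rejected(self):
        X, _ = eigenline_fixture()
        with pytest.raises(ValueError, match="orientation"):
            EigenlineClassifier().fit(X[:10], np.array([CONTROL] * 10))

    def test_band_rules_at_known_distances(self):
        X, y = eigenline_fixture()
        model = EigenlineClassifier().fit(X, y)
        # construct points at controlled perpendicular distances
        point = model.centroid_ + 1.5 * model.sd_ * \
            model.orientation_sign_ * model.normal_
        decision, d = classify_eigenline(model, point)
        assert d == pytest.approx(1.5 * model.sd_)
        assert decision == dec.UL
        on_line = model.centroid_ + 0.7 * model.direction_
        assert classify_eigenline(model, on_line)[0] == dec.U
        far = model.centroid_ - 3 * model.sd_ * model.orientation_sign_ * \
            model.normal_
        assert classify_eigenline(model, far)[0] == dec.R

    def test_mirror_property(self):
        """Swapping the two scatter coordinates (with recalibration)
        mirrors every decision."""
        X, y = eigenline_fixture()
        model = EigenlineClassifier().fit(X, y)
        swapped = X[:, ::-1]
        y_swapped = np.array([{LEFT: RIGHT, RIGHT: LEFT}.get(t, t)
                              for t in y], dtype=object)
        model_swapped = EigenlineClassifier().fit(swapped, y_swapped)
        pred = model.predict(X)
        pred_swapped = model_swapped.predict(swapped)
        assert all(b == dec.mirror(a) for a, b in zip(pred, pred_swapped))

    def test_serialization_round_trip(self):
        X, y = eigenline_fixture()
        model = EigenlineClassifier().fit(X, y)
        clone = model_from_dict(model_to_dict(model))
        assert np.array_equal(model.predict(X), clone.predict(X))


@pytest.fixture(scope="module")
def logistic_model():
    rng = np.random.default_rng(1)
    left = rng.normal([-15, -8, -4], 3, (60, 3))
    right = rng.normal([15, 8, 4], 3, (60, 3))
    X = np.vstack([left, right])
    y = np.array([LEFT] * 60 + [RIGHT] * 60, dtype=object)
    return fit_msa_logistic(X, y)


@pytest.fixture(scope="module")
def hvu_model():
    rng = np.random.default_rng(4)
    controls = rng.normal(0, 0.02, (30, 3))
    return hvu_from_controls(controls)


class TestLogistic:
    def test_probability_bands(self, logistic_model):
        # scan feature space for probabilities in each band
        d, p = classify_msa(logistic_model, [-15, -8, -4])
        assert p > 0.7 and d == dec.L
        d, p = classify_msa(logistic_model, [15, 8, 4])
        assert p < 0.3 and d == dec.R
        d, p = classify_msa(logistic_model, [0, 0, 0])
        assert d in (dec.U, dec.UL, dec.UR)

    def test_band_edges_on_probability_offset(self):
        """Band mapping on the centered probability p − 1/2: only exactly
        1/2 is U, the weak band is open at 0.2 and |offset| ≥ 0.2 is
        definitive."""
        for v, expected in [(0.0, dec.U), (0.125, dec.UL), (0.2, dec.L),
                            (0.35, dec.L), (-0.125, dec.UR),
                            (-0.2, dec.R), (-0.3, dec.R)]:
            assert dec.banded_decision(v, 0.0, 0.2,
                                       positive=dec.L) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="left"):
            fit_msa_logistic(np.zeros((4, 3)), [LEFT] * 4)

    def test_mirror_property(self, logistic_model):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 10, (30, 3))
        flipped_model = TristructuralLogisticClassifier().fit(
            *_mirrored_training())
        for x in X:
            d, _ = classify_msa(logistic_model, x)
            d2, _ = classify_msa(flipped_model, -x)
            assert d2 == dec.mirror(d)


def _mirrored_training():
    rng = np.random.default_rng(1)
    left = rng.normal([-15, -8, -4], 3, (60, 3))
    right = rng.normal([15, 8, 4], 3, (60, 3))
    X = -np.vstack([left, right])
    y = np.array([RIGHT] * 60 + [LEFT] * 60, dtype=object)
    return X, y


class TestMarginBand:
    def test_two_point_closed_form(self):
        """For the two-point set the max-margin plane is the perpendicular
        bisector and M is half the separation."""
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array([RIGHT, LEFT], dtype=object)
        model = fit_margin_classifier(X, y)
        assert model.margin_ == pytest.approx(np.sqrt(2), rel=1e-3)
        assert classify_margin(model, [1.0, 1.0]) == dec.U
        assert classify_margin(model, [2.0, 2.0]) == dec.L
        assert classify_margin(model, [0.0, 0.0]) == dec.R
        # distance 0.75 M on the left side -> weakly left
        mid = np.array([1.0, 1.0])
        w = model.weights_ / np.linalg.norm(model.weights_)
        sign = 1 if model.positive_class_ == LEFT else -1
        probe = mid + sign * 0.75 * model.margin_ * w
        assert classify_margin(model, probe) == dec.UL

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_margin_classifier(np.zeros((3, 2)), [LEFT] * 3)

    def test_categorization_variant(self):
        rng = np.random.default_rng(3)
        tle = rng.normal([2, 2], 0.3, (30, 2))
        other = rng.normal([-2, -2], 0.3, (30, 2))
        model = fit_margin_classifier(
            np.vstack([tle, other]),
            np.array(["tle"] * 30 + ["non_tle"] * 30, dtype=object),
            kind="categorization")
        assert classify_margin(model, [2, 2]) == "tle"
        assert classify_margin(model, [-2, -2]) == "non_tle"
        assert classify_margin(model, [0, 0]) == "uncertain"


class TestHVU:
    def test_threshold_is_mean_plus_2sd_of_abs(self, hvu_model):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(0, 0.02, (30, 3)))
        assert hvu_model.hvu_ == pytest.approx(a.mean(0) + 2 * a.std(0, ddof=1))

    def test_control_like_subject_is_indeterminate(self, hvu_model):
        assert classify_hvu(hvu_model, [0.0, 0.0, 0.0]) == dec.U

    def test_unanimous_votes_definitive(self, hvu_model):
        # left epileptogenic: MD up, both FA measures down on the left
        assert classify_hvu(hvu_model, [0.5, -0.5, -0.5]) == dec.L
        assert classify_hvu(hvu_model, [-0.5, 0.5, 0.5]) == dec.R

    def test_partial_votes_weak(self, hvu_model):
        assert classify_hvu(hvu_model, [0.5, 0.0, 0.0]) == dec.UL
        assert classify_hvu(hvu_model, [-0.5, 0.5, 0.0]) == dec.UR

    def test_conflicting_votes_indeterminate(self, hvu_model):
        assert classify_hvu(hvu_model, [0.5, 0.5, -0.5]) == dec.U

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError, match="controls"):
            hvu_from_controls(np.zeros((3, 3)) + 0.01)

    def test_diffusion_asymmetry(self):
        assert diffusion_asymmetry(1.2, 0.8) == pytest.approx(0.4)
        with pytest.raises(ValueError, match="positive"):
            diffusion_asymmetry(-1.0, 1.0)

    def test_serialization_round_trip(self, hvu_model):
        clone = model_from_dict(model_to_dict(hvu_model))
        X = np.array([[0.5, -0.5, -0.5], [0, 0, 0]])
        assert np.array_equal(hvu_model.predict(X), clone.predict(X))


def test_parameter_recovery_on_separated_cohorts():
    """With case displacement far beyond the control band width, both
    control-calibrated classifiers lateralize essentially all cases."""
    rng = np.random.default_rng(5)
    n = 50
    base = rng.uniform(1, 3, 3 * n)
    noise = rng.normal(0, 0.05, (3 * n, 2))
    X = np.c_[base, base] + noise
    X[n:2 * n] += [-0.5, 0.5]
    X[2 * n:] += [0.5, -0.5]
    y = np.array([CONTROL] * n + [LEFT] * n + [RIGHT] * n, dtype=object)
    model = EigenlineClassifier().fit(X, y)
    pred = model.predict(X[n:])
    sides = [dec.side_of(p) for p in pred]
    truth = ["left"] * n + ["right"] * n
    acc = np.mean([s == t for s, t in zip(sides, truth)])
    assert acc >= 0.9
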