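"""Polynomial calibration: recovery, degree monotonicity, epoch assignment."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gazephen.calibration import (
    CalibrationModel,
    assign_epochs,
    dot_residuals,
    fit_calibration,
    monomial_basis,
    n_coefficients,
    predict_world,
)
from gazephen.synth.schedule import DotEvent


def affine_pairs(n=25, seed=0):
    rng = np.random.default_rng(seed)
    pupil = rng.random((n, 2))
    world = pupil @ np.array([[1.1, 0.1], [-0.05, 0.9]]).T + np.array([0.02, -0.03])
    return pupil, world


def quadratic_pairs(n=40, seed=1):
    rng = np.random.default_rng(seed)
    pupil = rng.random((n, 2))
    x, y = pupil[:, 0], pupil[:, 1]
    world = np.column_stack([
        0.1 + 0.9 * x + 0.05 * y + 0.2 * x**2 - 0.1 * x * y,
        -0.02 + 0.08 * x + 1.05 * y + 0.15 * y**2,
    ])
    return pupil, world


def identity_model(degree=1):
    pupil = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    return fit_calibration(pupil, pupil, degree=degree)


class TestFit:
    def test_affine_recovered_exactly(self):
        pupil, world = affine_pairs()
        model = fit_calibration(pupil, world, degree=1)
        assert model.fit_residual < 1e-10
        held_out = np.array([[0.21, 0.77]])
        expected = held_out @ np.array([[1.1, 0.1], [-0.05, 0.9]]).T + [0.02, -0.03]
        np.testing.assert_allclose(predict_world(model, held_out), expected, atol=1e-9)

    def test_quadratic_recovered(self):
        pupil, world = quadratic_pairs()
        model = fit_calibration(pupil, world, degree=2)
        assert model.fit_residual < 1e-8

    def test_insufficient_points_rejected(self):
        pupil, world = affine_pairs(n=3)
        with pytest.raises(ValueError, match="at least 6"):
            fit_calibration(pupil, world, degree=2)

    def test_collinear_points_rank_deficient(self):
        t = np.linspace(0, 1, 10)
        pupil = np.column_stack([t, 2 * t])
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_calibration(pupil, pupil, degree=2)

    def test_residual_nonincreasing_in_degree(self):
        rng = np.random.default_rng(5)
        pupil = rng.random((30, 2))
        world = rng.random((30, 2))
        residuals = [
            fit_calibration(pupil, world, degree=d).fit_residual for d in (1, 2, 3)
        ]
        assert residuals[0] >= residuals[1] >= residuals[2] - 1e-12

    def test_basis_size(self):
        assert monomial_basis(np.zeros((1, 2)), 2).shape[1] == n_coefficients(2) == 6


class TestPredict:
    def test_identity_model(self):
        model = identity_model()
        pts = np.array([[0.3, 0.4], [0.9, 0.1]])
        np.testing.assert_allclose(predict_world(model, pts), pts, atol=1e-10)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            predict_world(identity_model(), np.array([[np.nan, 0.5]]))


def pupil_frame(coords):
    return pd.DataFrame(
        {"frame": np.arange(len(coords)), "x": coords[:, 0], "y": coords[:, 1],
         "missing": False}
    )


class TestDots:
    dots = [DotEvent(0, 10), DotEvent(50, 10)]

    def test_correct_model_zero_residual(self):
        coords = np.full((60, 2), 0.5)
        res = dot_residuals(identity_model(), pupil_frame(coords), self.dots)
        assert res["median"] < 1e-9

    def test_constant_offset_median(self):
        coords = np.full((60, 2), 0.5)
        coords[:, 0] += 0.07  # pupil shifted: prediction off by exactly 0.07
        res = dot_residuals(identity_model(), pupil_frame(coords), self.dots)
        assert res["median"] == pytest.approx(0.07, abs=1e-9)

    def test_noisy_residual_scales_with_sigma(self):
        """Median dot error ~ sigma * sqrt(2 ln 2) for an identity map."""
        sigma = 0.02
        medians = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            coords = np.full((60, 2), 0.5) + rng.normal(0, sigma, (60, 2))
            res = dot_residuals(identity_model(), pupil_frame(coords), self.dots)
            medians.append(res["median"])
        expected = sigma * np.sqrt(2 * np.log(2))
        assert np.mean(medians) == pytest.approx(expected, rel=0.5)


class TestAssign:
    def test_single_epoch_correct_model(self):
        coords = np.full((100, 2), 0.5)
        dots = [DotEvent(20, 10), DotEvent(70, 10)]
        out = assign_epochs(pupil_frame(coords), [identity_model()], dots,
                            n_frames=100)
        assert all(eid == 0 for _, _, eid in out.intervals)
        assert out.intervals[0][0] == 0 and out.intervals[-1][1] == 100

    def test_mapping_switch_found_at_dot_boundary(self):
        """A planted mapping switch is localized at the switching dot event."""
        n = 200
        dots = [DotEvent(40, 10), DotEvent(100, 10), DotEvent(160, 10)]
        switch = 105  # midpoint of the second dot
        # epoch A: pupil == world; epoch B: pupil shifted by +0.2 in x
        coords = np.full((n, 2), 0.5)
        coords[switch:, 0] -= 0.2
        model_a = identity_model()
        shifted = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        model_b = CalibrationModel(
            epoch_id=1, degree=1,
            coef_x=model_a.coef_x + np.array([0.2, 0.0, 0.0]),
            coef_y=model_a.coef_y, fit_residual=0.0, n_points=4,
        )
        out = assign_epochs(pupil_frame(coords), [model_a, model_b], dots,
                            n_frames=n)
        eids = [eid for _, _, eid in out.intervals]
        assert eids == [0, 0, 1, 1]
        # boundary between assignments falls inside the switching dot event
        boundary = out.intervals[1][1]
        assert 100 <= boundary < 110

    def test_grossly_wrong_models_assigned_none(self):
        coords = np.full((100, 2), 0.5)
        dots = [DotEvent(20, 10), DotEvent(70, 10)]
        bad = CalibrationModel(
            epoch_id=7, degree=1,
            coef_x=np.array([0.5, 1.0, 0.0]), coef_y=np.array([0.0, 0.0, 1.0]),
            fit_residual=0.0, n_points=4,
        )
        out = assign_epochs(pupil_frame(coords), [bad], dots, n_frames=100)
        assert all(eid is None for _, _, eid in out.intervals)

    def test_no_dots_falls_back_with_warning(self):
        coords = np.full((50, 2), 0.5)
        with pytest.warns(UserWarning, match="no dot events"):
            out = assign_epochs(pupil_frame(coords), [identity_model()], [],
                                n_frames=50)
        assert out.intervals == ((0, 50, 0),)
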