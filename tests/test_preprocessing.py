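"""Surface Laplacian and Butterworth high-pass behaviour."""

import numpy as np
import pytest

from neurogait import (
    ElectrodeLayout,
    FilterSpec,
    Trial,
    ValidationError,
    butterworth_highpass,
    laplacian_filter,
    laplacian_weights,
    select_channels,
)
from neurogait.core import DegenerateGeometryError

FS = 500.0


def triangle_layout(d12=1.0, d13=1.0):
    """Three unit-sphere electrodes with controllable chord distances from e1."""

    def at_angle(theta):
        return [np.sin(theta), 0.0, np.cos(theta)]

    # chord distance d corresponds to polar angle 2*arcsin(d/2)
    a12 = 2 * np.arcsin(d12 / 2)
    a13 = 2 * np.arcsin(d13 / 2)
    coords = np.array([[0, 0, 1.0], at_angle(a12), [-np.sin(a13), 0, np.cos(a13)]])
    return ElectrodeLayout(["e1", "e2", "e3"], coords, ["e1"])


class TestLaplacianWeights:
    def test_equidistant_neighbors_share_weight(self):
        w = laplacian_weights(triangle_layout(1.0, 1.0))
        assert w.g[0, 1] == pytest.approx(0.5)
        assert w.g[0, 2] == pytest.approx(0.5)

    def test_inverse_distance_weighting(self):
        # neighbors at distances 1 and 2: weights (1/1)/(3/2)=2/3 and (1/2)/(3/2)=1/3
        w = laplacian_weights(triangle_layout(1.0, 2.0))
        assert w.g[0, 1] == pytest.approx(2 / 3)
        assert w.g[0, 2] == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self, layout):
        w = laplacian_weights(layout)
        np.testing.assert_allclose(w.g.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diag(w.g) == 0)
        assert np.all(w.g >= 0)

    def test_coincident_electrodes_rejected(self):
        coords = np.array([[0, 0, 1.0], [0, 0, 1.0], [1, 0, 0.0]])
        with pytest.raises((DegenerateGeometryError, ValidationError)):
            ElectrodeLayout(["a", "b", "c"], coords, [])


class TestLaplacianFilter:
    def trial(self, data):
        return Trial(np.asarray(data, float), FS, ["e1", "e2", "e3"])

    def test_uniform_field_maps_to_zero(self):
        w = laplacian_weights(triangle_layout())
        out = laplacian_filter(self.trial(np.full((3, 10), 7.3)), w)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_hand_evaluated_equidistant_case(self):
        w = laplacian_weights(triangle_layout(1.0, 1.0))
        out = laplacian_filter(self.trial([[10.0], [3.0], [6.0]]), w)
        assert out.data[0, 0] == pytest.approx(10 - 4.5)

    def test_hand_evaluated_weighted_case(self):
        w = laplacian_weights(triangle_layout(1.0, 2.0))
        out = laplacian_filter(self.trial([[10.0], [3.0], [6.0]]), w)
        assert out.data[0, 0] == pytest.approx(10 - (2 / 3 * 3 + 1 / 3 * 6))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        w = laplacian_weights(triangle_layout(1.0, 1.7))
        X, Y = rng.standard_normal((2, 3, 100))
        a, b = 2.5, -1.25
        lhs = laplacian_filter(self.trial(a * X + b * Y), w).data
        rhs = a * laplacian_filter(self.trial(X), w).data + b * laplacian_filter(self.trial(Y), w).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        w = laplacian_weights(triangle_layout())
        with pytest.raises(ValidationError):
            laplacian_filter(Trial(np.zeros((2, 5)), FS, ["e1", "e2"]), w)


class TestButterworthHighpass:
    def trial(self, x):
        return Trial(np.atleast_2d(x), FS, ["Cz"])

    def test_dc_rejected(self):
        out = butterworth_highpass(self.trial(np.full(2000, 123.0)))
        assert np.max(np.abs(out.data)) < 1e-6 * 123.0

    def test_passband_tone_preserved(self):
        t = np.arange(10000) / FS  # 20 s: trials are filtered whole
        x = np.sin(2 * np.pi * 10 * t)
        out = butterworth_highpass(self.trial(x))
        core = slice(2000, 8000)  # the 0.2 Hz filter rings for seconds at the edges
        assert np.max(np.abs(out.data[0, core] - x[core])) < 0.01

    def test_linearity_splits_dc_from_tone(self):
        t = np.arange(10000) / FS
        x = 100.0 + np.sin(2 * np.pi * 10 * t)
        out = butterworth_highpass(self.trial(x))
        core = slice(2000, 8000)  # the 0.2 Hz filter rings for seconds at the edges
        assert np.max(np.abs(out.data[0, core] - np.sin(2 * np.pi * 10 * t)[core])) < 0.01

    def test_idempotent_above_1hz(self):
        rng = np.random.default_rng(1)
        t = np.arange(10000) / FS
        x = sum(np.sin(2 * np.pi * f * t + p) for f, p in zip([2, 10, 40], rng.uniform(0, 6, 3)))
        once = butterworth_highpass(self.trial(x))
        twice = butterworth_highpass(once)
        core = slice(2000, 8000)  # the 0.2 Hz filter rings for seconds at the edges
        rel = np.max(np.abs(twice.data[0, core] - once.data[0, core])) / np.max(np.abs(once.data))
        assert rel < 0.02

    def test_too_short_trial_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            butterworth_highpass(self.trial(np.zeros(10)))


class TestSelectChannels:
    def test_subset_and_reorder(self):
        t = Trial(np.arange(6.0).reshape(3, 2), FS, ["a", "b", "c"])
        out = select_channels(t, ["c", "a"])
        assert out.channel_names == ["c", "a"]
        np.testing.assert_array_equal(out.data, t.data[[2, 0]])

    def test_identity_and_idempotence(self):
        t = Trial(np.arange(6.0).reshape(3, 2), FS, ["a", "b", "c"])
        same = select_channels(t, ["a", "b", "c"])
        np.testing.assert_array_equal(same.data, t.data)
        twice = select_channels(select_channels(t, ["b", "c"]), ["b", "c"])
        np.testing.assert_array_equal(twice.data, t.data[[1, 2]])

    def test_unknown_channel_rejected(self):
        t = Trial(np.zeros((2, 2)), FS, ["a", "b"])
        with pytest.raises(ValidationError, match="unknown"):
            select_channels(t, ["z"])
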