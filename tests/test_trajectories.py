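"""Synthetic trajectory generator: curve equations, encoding, protocol."""

import math

import numpy as np
import pytest

from rnnpb.trajectories import (
    DatasetProtocol,
    circle_curve,
    cosine_curve,
    curve_function,
    make_dataset,
    make_sequence,
    phase_values,
    read_sequences_csv,
    speed_variant,
    square_curve,
    write_sequences_csv,
)


class TestCurves:
    @pytest.mark.parametrize("f", [cosine_curve, square_curve, circle_curve])
    def test_x_constant_12(self, f):
        for t in np.linspace(-math.pi + 1e-9, math.pi, 17):
            assert f(float(t))[0] == 12.0

    @pytest.mark.parametrize("f", [cosine_curve, square_curve, circle_curve])
    @pytest.mark.parametrize("t", [-4.0, math.pi + 1e-6, -math.pi])
    def test_phase_domain_enforced(self, f, t):
        with pytest.raises(ValueError):
            f(t)

    def test_cosine_values(self):
        assert cosine_curve(0.0)[2] == pytest.approx(4.10)
        assert cosine_curve(0.0)[1] == pytest.approx(0.04)
        assert cosine_curve(math.pi / 2)[2] == pytest.approx(-3.90)

    def test_square_values(self):
        assert square_curve(0.0)[1] == pytest.approx(8.0)
        assert square_curve(math.pi)[1] == pytest.approx(0.0)

    def test_square_continuity_at_branch_boundaries(self):
        eps = 1e-9
        for b in (-3 * math.pi / 4, -math.pi / 4, math.pi / 4, 3 * math.pi / 4):
            left = square_curve(b)
            right = square_curve(b + eps)
            assert left[1] == pytest.approx(right[1], abs=1e-6)
            assert left[2] == pytest.approx(right[2], abs=1e-6)

    def test_square_loop_closure(self):
        # last sampled point adjoins the first within one segment step
        ts = phase_values(20)
        pts = np.array([square_curve(float(t))[1:] for t in sorted(ts)])
        seg = np.max(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        wrap = np.linalg.norm(pts[-1] - pts[0])
        assert wrap <= seg + 1e-9

    def test_circle_radius_invariant(self):
        for t in np.linspace(-math.pi + 1e-9, math.pi, 33):
            _, y, z = circle_curve(float(t))
            assert (y - 0.04) ** 2 + (z - 0.10) ** 2 == pytest.approx(16.0, rel=1e-12)

    def test_circle_values(self):
        assert circle_curve(0.0)[1:] == pytest.approx((0.04, 4.10))
        assert circle_curve(math.pi / 4)[1] == pytest.approx(4.04)

    def test_unknown_curve_rejected_with_listing(self):
        with pytest.raises(ValueError, match="cosine"):
            curve_function("spiral")


def test_normalization_bounds_cover_all_curves():
    """The fixed closed-form bounds contain every point of all three
    curves (checked by dense sampling)."""
    from rnnpb.trajectories import NORM_BOUNDS, _curve_extent

    lo = np.minimum.reduce([_curve_extent(c)[0] for c in ("cosine", "square", "circle")])
    hi = np.maximum.reduce([_curve_extent(c)[1] for c in ("cosine", "square", "circle")])
    assert np.all(NORM_BOUNDS[:2, 0] <= lo + 1e-9)
    assert np.all(NORM_BOUNDS[:2, 1] >= hi - 1e-9)
    # and the bounds are tight to within the sampling resolution
    assert np.allclose(NORM_BOUNDS[:2, 0], lo, atol=0.05)
    assert np.allclose(NORM_BOUNDS[:2, 1], hi, atol=0.05)


class TestPhases:
    def test_even_sampling_in_half_open_interval(self):
        ts = phase_values(20)
        assert len(ts) == 20
        assert np.all(ts > -math.pi) and np.all(ts <= math.pi)
        assert math.pi in ts  # the endpoint is included

    def test_speed_factor_two_wraps_into_two_loops(self):
        ts = phase_values(20, speed_factor=2.0)
        assert len(ts) == 20
        # 10 distinct phases, each visited twice
        assert len(np.unique(np.round(ts, 12))) == 10


class TestMakeSequence:
    def test_yellow_occupies_layer_one_only(self):
        s = make_sequence("cosine", "yellow", DatasetProtocol(), seed=3)
        assert np.all(s.values[:, 2:] == 0.0)
        assert np.any(s.values[:, :2] != 0.0)

    def test_green_occupies_layer_two_only(self):
        s = make_sequence("circle", "green", DatasetProtocol(), seed=3)
        assert np.all(s.values[:, :2] == 0.0)

    def test_default_length_20(self):
        assert len(make_sequence("square", "green", DatasetProtocol(), seed=0)) == 20

    def test_noiseless_is_seed_independent_and_in_unit_interval(self):
        proto = DatasetProtocol(noise_sigma=0.0)
        a = make_sequence("cosine", "yellow", proto, seed=1)
        b = make_sequence("cosine", "yellow", proto, seed=999)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.all(a.values >= 0.0) and np.all(a.values <= 1.0)

    def test_same_seed_reproducible(self):
        a = make_sequence("cosine", "green", DatasetProtocol(), seed=42)
        b = make_sequence("cosine", "green", DatasetProtocol(), seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_color_rejected(self):
        with pytest.raises(ValueError, match="yellow"):
            make_sequence("cosine", "blue", DatasetProtocol(), seed=0)

    def test_speed_factor_doubles_dominant_frequency(self):
        base = make_sequence("cosine", "yellow", DatasetProtocol(noise_sigma=0.0), seed=0)
        fast = make_sequence(
            "cosine", "yellow",
            speed_variant(DatasetProtocol(noise_sigma=0.0), 2.0), seed=0,
        )

        def dominant(z):
            spec = np.abs(np.fft.rfft(z - z.mean()))
            return int(np.argmax(spec[1:]) + 1)

        # column 1 carries the z = cos(2t) oscillation
        assert dominant(fast.values[:, 1]) == 2 * dominant(base.values[:, 1])


class TestDataset:
    def test_default_protocol_yields_20_unique_sequences(self):
        seqs = make_dataset(DatasetProtocol(base_seed=7))
        assert len(seqs) == 20
        assert len({s.sequence_id for s in seqs}) == 20
        assert all(len(s) == 20 for s in seqs)

    def test_single_cell_protocol(self):
        seqs = make_dataset(
            DatasetProtocol(reps_per_class=1, colors=("yellow",), curves=("cosine",))
        )
        assert len(seqs) == 1

    def test_reproducible_from_base_seed(self):
        a = make_dataset(DatasetProtocol(base_seed=5))
        b = make_dataset(DatasetProtocol(base_seed=5))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)
            assert sa.sequence_id == sb.sequence_id

    def test_channel_exclusivity(self):
        for s in make_dataset(DatasetProtocol(base_seed=2)):
            active = slice(0, 2) if s.color_label == "yellow" else slice(2, 4)
            inactive = slice(2, 4) if s.color_label == "yellow" else slice(0, 2)
            assert np.all(s.values[:, inactive] == 0.0)
            assert np.any(s.values[:, active] != 0.0)

    def test_speed_variant_identity_and_validation(self):
        proto = DatasetProtocol()
        assert speed_variant(proto, 1.0) == proto
        with pytest.raises(ValueError):
            speed_variant(proto, 0.0)


class TestCsvRoundTrip:
    def test_lossless_at_12_digits(self, tmp_path):
        seqs = make_dataset(DatasetProtocol(base_seed=3, reps_per_class=2))
        path = tmp_path / "seqs.csv"
        write_sequences_csv(seqs, path)
        back = read_sequences_csv(path)
        assert [s.sequence_id for s in back] == [s.sequence_id for s in seqs]
        for sa, sb in zip(seqs, back):
            np.testing.assert_allclose(sb.values, sa.values, rtol=1e-11, atol=1e-13)
            assert sb.color_label == sa.color_label
            assert sb.curve_label == sa.curve_label

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sequence_id,t_index,in1\ns,0,0.5\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_sequences_csv(path)
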