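"""Echo-train timing: schedules, echo counts, bandwidth-noise scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from megre import protocol as P


class TestAcquisitionTime:
    @pytest.mark.parametrize(
        "n_x, bw_total, expected",
        [
            (240, 801 * 240, 1.25),   # 1.24844 ms ceiled to the 0.01 ms grid
            (192, 192000, 1.00),      # exact raster multiple, no rounding
            (240, 342 * 240, 2.93),   # 2.9240 ms ceiled
        ],
    )
    def test_ceil_to_raster(self, n_x, bw_total, expected):
        assert P.acquisition_time(n_x, bw_total, raster=0.01) == pytest.approx(
            expected, abs=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            P.acquisition_time(0, 1000.0)
        with pytest.raises(ValueError):
            P.acquisition_time(10, -1.0)
        with pytest.raises(ValueError):
            P.acquisition_time(10, 1000.0, raster=0.0)


class TestTeSchedule:
    timing = P.GradientTiming(t_prep=3.105, t_ramp=0.11, t_fb=1.45)

    def test_bipolar_matches_printed_protocol(self):
        train = P.te_schedule(self.timing, 1.25, P.BIPOLAR, 3)
        assert train.te == pytest.approx([3.84, 5.31, 6.78])
        assert list(train.parity) == [0, 1, 0]

    def test_monopolar_matches_printed_protocol(self):
        train = P.te_schedule(self.timing, 1.25, P.MONOPOLAR, 2)
        assert train.te == pytest.approx([3.84, 6.76])
        assert train.delta_te == pytest.approx(2.92)
        assert list(train.parity) == [0, 0]

    def test_zero_flyback_degenerates_to_bipolar_spacing(self):
        timing = P.GradientTiming(t_prep=3.105, t_ramp=0.11, t_fb=0.0)
        mono = P.te_schedule(timing, 1.25, P.MONOPOLAR, 8)
        bip = P.te_schedule(timing, 1.25, P.BIPOLAR, 8)
        np.testing.assert_allclose(mono.te, bip.te)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            P.te_schedule(self.timing, 1.25, P.MONOPOLAR, 0)

    @given(
        t_prep=st.floats(0, 10),
        t_ramp=st.floats(0, 1),
        t_fb=st.floats(0.01, 3),
        t_acq=st.floats(0.1, 5),
        n=st.integers(2, 40),
    )
    def test_flyback_accumulates_linearly(self, t_prep, t_ramp, t_fb, t_acq, n):
        """TE_n(mono) - TE_n(bip) = (n-1) * t_fb exactly."""
        timing = P.GradientTiming(t_prep=t_prep, t_ramp=t_ramp, t_fb=t_fb)
        mono = P.te_schedule(timing, t_acq, P.MONOPOLAR, n)
        bip = P.te_schedule(timing, t_acq, P.BIPOLAR, n)
        np.testing.assert_allclose(
            mono.te - bip.te, (np.arange(1, n + 1) - 1) * t_fb, rtol=1e-12, atol=1e-12
        )


class TestCountEchoes:
    @pytest.mark.parametrize(
        "te_1, delta_te, te_max, expected",
        [
            # 801 Hz/px protocol at both TE ranges
            (3.84, 2.92, 97.0, 32),
            (3.84, 1.47, 97.0, 64),
            (3.84, 2.92, 43.0, 14),
            (3.84, 1.47, 43.0, 27),
            # lower-bandwidth protocols, full TE range
            (4.62, 4.48, 97.0, 21),
            (4.62, 3.03, 97.0, 31),
            (4.00, 3.27, 97.0, 29),
            (4.00, 1.82, 97.0, 52),
            (3.90, 3.05, 97.0, 31),
            (3.90, 1.60, 97.0, 59),
        ],
    )
    def test_printed_echo_counts(self, te_1, delta_te, te_max, expected):
        assert P.count_echoes(te_1, delta_te, te_max) == expected

    def test_te_max_below_first_echo(self):
        assert P.count_echoes(3.84, 2.92, 2.0) == 0

    def test_inclusive_boundary(self):
        assert P.count_echoes(2.0, 2.0, 10.0) == 5  # last echo exactly at te_max

    @given(
        te_1=st.floats(1, 10),
        delta_te=st.floats(0.5, 5),
        te_max=st.floats(0, 200),
        bump=st.floats(0, 50),
    )
    def test_monotone_in_te_max(self, te_1, delta_te, te_max, bump):
        assert P.count_echoes(te_1, delta_te, te_max + bump) >= P.count_echoes(
            te_1, delta_te, te_max
        )

    @given(
        te_1=st.floats(1, 10),
        delta_te=st.floats(0.5, 5),
        factor=st.floats(1, 4),
        te_max=st.floats(0, 200),
    )
    def test_non_increasing_in_delta_te(self, te_1, delta_te, factor, te_max):
        assert P.count_echoes(te_1, delta_te * factor, te_max) <= P.count_echoes(
            te_1, delta_te, te_max
        )

    def test_schedule_consistency_with_count(self):
        """The counted train ends at or below te_max; one more echo exceeds it."""
        n = P.count_echoes(3.84, 2.92, 43.0)
        train = P.train_from_params(3.84, 2.92, P.MONOPOLAR, n_e=n + 1)
        assert train.te[n - 1] <= 43.0 < train.te[n]


class TestTimingFromProtocol:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((3.84, 2.92, 1.47, 1.25), (3.105, 0.11, 1.45)),
            ((4.62, 4.48, 3.03, 2.93), (3.105, 0.05, 1.45)),
        ],
    )
    def test_printed_protocol_inversion(self, args, expected):
        timing = P.timing_from_protocol(*args)
        assert (timing.t_prep, timing.t_ramp, timing.t_fb) == pytest.approx(expected)

    def test_zero_ramp_boundary(self):
        timing = P.timing_from_protocol(5.0, 4.0, 2.0, 2.0)
        assert timing.t_ramp == 0.0

    def test_inconsistent_protocol_rejected(self):
        with pytest.raises(P.ProtocolError):
            P.timing_from_protocol(3.84, 1.0, 1.47, 1.25)  # mono spacing < bipolar
        with pytest.raises(P.ProtocolError):
            P.timing_from_protocol(0.1, 2.92, 1.47, 1.25)  # t_prep would be < 0

    @given(
        te_1=st.floats(2, 10),
        delta_bip=st.floats(1, 4),
        extra=st.floats(0, 3),
        t_acq_frac=st.floats(0.2, 1),
        n=st.integers(2, 20),
    )
    def test_round_trip_through_te_schedule(self, te_1, delta_bip, extra, t_acq_frac, n):
        t_acq = delta_bip * t_acq_frac
        delta_mono = delta_bip + extra
        timing = P.timing_from_protocol(te_1, delta_mono, delta_bip, t_acq)
        mono = P.te_schedule(timing, t_acq, P.MONOPOLAR, n)
        bip = P.te_schedule(timing, t_acq, P.BIPOLAR, n)
        assert mono.te[0] == pytest.approx(te_1, abs=1e-9)
        assert bip.te[0] == pytest.approx(te_1, abs=1e-9)
        assert mono.delta_te == pytest.approx(delta_mono, abs=1e-9)
        assert bip.delta_te == pytest.approx(delta_bip, abs=1e-9)


class TestNoiseSigma:
    def test_square_root_law(self):
        assert P.noise_sigma(1.0, 100.0, 100.0) == 1.0
        assert P.noise_sigma(1.0, 400.0, 100.0) == 2.0
        assert P.noise_sigma(1.0, 342 * 240, 801 * 240) == pytest.approx(
            0.6534, abs=5e-5
        )

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            P.noise_sigma(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            P.noise_sigma(1.0, -1.0, 1.0)


class TestPresets:
    def test_all_presets_load_and_count(self):
        counts = {}
        for name in P.preset_names():
            cfg = P.load_protocol(name)
            train = P.protocol_train(cfg)
            counts[name] = train.n_e
        assert counts["bw801_monopolar"] == 32
        assert counts["bw801_bipolar"] == 64
        assert counts["bw342_monopolar"] == 21
        assert counts["bw342_bipolar"] == 31
        assert counts["bw613_monopolar"] == 29
        assert counts["bw613_bipolar"] == 52
        assert counts["bw718_monopolar"] == 31
        assert counts["bw718_bipolar"] == 59

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            P.load_protocol("bw999_monopolar")


class TestEchoTrain:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            P.EchoTrain(np.array([3.0, 2.0]), np.array([0, 1]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            P.EchoTrain(np.array([1.0, 2.0]), np.array([0]))

    def test_delta_te_none_for_non_uniform(self):
        train = P.EchoTrain(np.array([1.0, 2.0, 4.0]), np.zeros(3))
        assert train.delta_te is None

    def test_alternating_detection(self):
        bip = P.train_from_params(3.84, 1.47, P.BIPOLAR, n_e=6)
        mono = P.train_from_params(3.84, 2.92, P.MONOPOLAR, n_e=6)
        assert bip.is_alternating and not mono.is_alternating
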