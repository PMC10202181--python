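"""Oddball paradigm, preprocessing chain, FLDA, and trial decoding."""

import numpy as np
import pytest

from cvta import erp, simulate
from cvta.signals import SignalRecording


def _recording(data, channels=("a", "b"), fs=250.0):
    return SignalRecording(np.asarray(data, dtype=float), list(channels), fs)


class TestSchedule:
    def test_single_repetition_arithmetic(self):
        sched = erp.build_schedule(1, seed=0)
        assert len(sched.events) == 7
        assert sched.duration == pytest.approx(0.98)

    def test_five_repetitions(self):
        assert len(erp.build_schedule(5, seed=0).events) == 35

    @pytest.mark.parametrize("n", [1, 3, 5])
    def test_each_group_once_per_repetition(self, n):
        sched = erp.build_schedule(n, seed=4)
        for rep in range(n):
            groups = sorted(g for _, g in sched.events[rep * 7 : (rep + 1) * 7])
            assert groups == list(range(7))

    @pytest.mark.parametrize("item", [1, 6, 12])
    def test_every_item_flashes_twice_per_repetition(self, item):
        n = 4
        sched = erp.build_schedule(n, seed=9)
        assert sched.target_flags(item).sum() == 2 * n

    def test_onsets_spaced_by_soa(self):
        sched = erp.build_schedule(2, seed=1)
        onsets = np.array([t for t, _ in sched.events])
        np.testing.assert_allclose(np.diff(onsets), 0.14)


class TestCarFilter:
    def test_identical_channels_cancel(self):
        x = np.random.default_rng(0).normal(size=(100, 1))
        rec = _recording(np.hstack([x, x]))
        out = erp.car_filter(rec, ["a", "b"])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_across_referenced_set(self):
        rng = np.random.default_rng(1)
        rec = _recording(rng.normal(size=(200, 3)), ["a", "b", "c"])
        out = erp.car_filter(rec, ["a", "b", "c"])
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(150, 2))
        out1 = erp.car_filter(_recording(base), ["a", "b"])
        out2 = erp.car_filter(_recording(base + 42.0), ["a", "b"])
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)

    def test_single_channel_rejected(self):
        rec = _recording(np.zeros((10, 1)), ["a"])
        with pytest.raises(ValueError):
            erp.car_filter(rec, ["a"])


class TestBandpass:
    @staticmethod
    def _sine(freq, fs=250.0, seconds=6.0):
        t = np.arange(int(fs * seconds)) / fs
        return _recording(np.sin(2 * np.pi * freq * t)[:, None], ["a"], fs)

    def _rms_ratio(self, freq):
        rec = self._sine(freq)
        out = erp.bandpass(rec)
        mid = slice(250, -250)  # avoid filter edge transients
        return np.std(out.data[mid]) / np.std(rec.data[mid])

    def test_50hz_strongly_attenuated(self):
        assert self._rms_ratio(50.0) < 0.10

    def test_10hz_passes(self):
        assert self._rms_ratio(10.0) > 0.90

    def test_zero_in_zero_out(self):
        out = erp.bandpass(_recording(np.zeros((1000, 1)), ["a"]))
        np.testing.assert_allclose(out.data, 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            erp.bandpass(_recording(np.zeros((1000, 1)), ["a"]), band=(30.0, 200.0))


class TestEpochAndFeatures:
    def test_epoch_indices_at_250hz(self):
        # onset 0: samples round(0.05*250)=13 .. 13+175
        data = np.arange(500.0)[:, None]
        rec = _recording(data, ["a"])
        epoch = erp.extract_epoch(rec, onset=0.0)
        np.testing.assert_array_equal(epoch[0], np.arange(13.0, 188.0))

    def test_epoch_length_always_175(self):
        rec = _recording(np.zeros((1000, 2)))
        for onset in (0.0, 0.5, 1.7):
            assert erp.extract_epoch(rec, onset).shape == (2, 175)

    def test_epoch_beyond_recording_rejected(self):
        rec = _recording(np.zeros((100, 2)))
        with pytest.raises(ValueError):
            erp.extract_epoch(rec, onset=0.0)

    def test_feature_vector_is_100_dimensional(self):
        labels = ["Cz", "PO4", "PO7", "PO8", "Oz"]
        epoch = np.zeros((5, 175))
        assert erp.featurize(epoch, labels).shape == (100,)

    def test_zero_epoch_zero_features(self):
        labels = ["PO4", "PO7", "PO8", "Oz"]
        np.testing.assert_array_equal(
            erp.featurize(np.zeros((4, 175)), labels), np.zeros(100)
        )

    def test_decimation_keeps_every_seventh_sample(self):
        labels = ["PO4", "PO7", "PO8", "Oz"]
        epoch = np.zeros((4, 175))
        epoch[0] = np.arange(175.0)  # ramp on PO4
        feats = erp.featurize(epoch, labels)
        np.testing.assert_array_equal(feats[:25], np.arange(0.0, 175.0, 7.0))
        np.testing.assert_array_equal(feats[25:], 0.0)

    def test_missing_feature_channel_rejected(self):
        with pytest.raises(ValueError):
            erp.featurize(np.zeros((2, 175)), ["a", "b"])


class TestFlda:
    @staticmethod
    def _clouds(seed=0, n=40, sep=8.0, dim=10):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(size=(n, dim))
        X1 = rng.normal(size=(n, dim)) + sep / np.sqrt(dim)
        X = np.vstack([X0, X1])
        y = np.array([0] * n + [1] * n)
        return X, y

    def test_separable_clouds_perfectly_reclassified(self):
        X, y = self._clouds()
        model = erp.flda_train(X, y)
        pred = np.array([erp.flda_score(model, x) > 0 for x in X]).astype(int)
        np.testing.assert_array_equal(pred, y)

    def test_label_swap_flips_sign(self):
        X, y = self._clouds(seed=1)
        m1 = erp.flda_train(X, y)
        m2 = erp.flda_train(X, 1 - y)
        np.testing.assert_allclose(m2.w, -m1.w, atol=1e-9)
        assert m2.w0 == pytest.approx(-m1.w0)

    def test_deterministic(self):
        X, y = self._clouds(seed=2)
        m1, m2 = erp.flda_train(X, y), erp.flda_train(X, y)
        np.testing.assert_array_equal(m1.w, m2.w)

    def test_agrees_with_sklearn_lda_on_separable_data(self):
        """Independent cross-check: sklearn's LDA and this FLDA must assign
        the same class to every point of a separable problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = self._clouds(seed=3, sep=6.0)
        model = erp.flda_train(X, y)
        ours = np.array([erp.flda_score(model, x) > 0 for x in X]).astype(int)
        theirs = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        np.testing.assert_array_equal(ours, theirs)

    def test_score_hand_computed(self):
        model = erp.FldaModel(np.array([1.0, 2.0, 3.0]), -1.0)
        assert erp.flda_score(model, np.ones(3)) == pytest.approx(5.0)

    def test_score_affine(self):
        model = erp.FldaModel(np.array([2.0, -1.0]), 0.0)
        a, b = np.array([1.0, 3.0]), np.array([-2.0, 0.5])
        assert erp.flda_score(model, 2 * a + 3 * b) == pytest.approx(
            2 * erp.flda_score(model, a) + 3 * erp.flda_score(model, b)
        )

    def test_trivial_positive_model(self):
        model = erp.FldaModel(np.zeros(4), 1.0)
        assert erp.flda_score(model, np.ones(4)) == 1.0

    def test_dimension_mismatch_rejected(self):
        model = erp.FldaModel(np.zeros(4), 0.0)
        with pytest.raises(ValueError):
            erp.flda_score(model, np.zeros(5))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            erp.flda_train(np.zeros((5, 3)), np.zeros(5))


class TestClassifyTarget:
    def test_noise_free_trial_decoded_exactly(self, trained_model):
        cfg = simulate.ErpSimConfig(noise_sd=0.0)
        sched = erp.build_schedule(5, seed=21)
        rec = simulate.generate_erp_recording(cfg, sched, target_item=6)
        assert erp.classify_target(rec, sched, trained_model) == 6

    def test_all_zero_recording_breaks_ties_to_item_1(self, trained_model):
        sched = erp.build_schedule(5, seed=22)
        rec = SignalRecording(
            np.zeros((2000, 6)), list(simulate.DEFAULT_CHANNELS), 250.0
        )
        assert erp.classify_target(rec, sched, trained_model) == 1

    def test_no_events_rejected(self, trained_model):
        rec = SignalRecording(
            np.zeros((500, 6)), list(simulate.DEFAULT_CHANNELS), 250.0
        )
        with pytest.raises(ValueError):
            erp.classify_target(rec, erp.FlashSchedule([]), trained_model)

    def test_accuracy_non_decreasing_in_repetitions(self):
        """More repetitions aggregate more evidence: at moderate SNR the
        selection accuracy rises with the repetition count."""
        trials = []
        for item in range(1, 13):
            sched = erp.build_schedule(10, seed=200 + item)
            rec = simulate.generate_erp_recording(
                simulate.ErpSimConfig(erp_amplitude=1.0, seed=item), sched, item
            )
            trials.append((rec, sched, item))
        model = erp.train_decoder(trials)

        def accuracy(n_reps, seed0):
            rng = np.random.default_rng(seed0)
            hits = 0
            for _ in range(40):
                item = int(rng.integers(1, 13))
                sched = erp.build_schedule(n_reps, seed=int(rng.integers(2**31)))
                rec = simulate.generate_erp_recording(
                    simulate.ErpSimConfig(
                        erp_amplitude=1.0, seed=int(rng.integers(2**31))
                    ),
                    sched,
                    item,
                )
                hits += erp.classify_target(rec, sched, model) == item
            return hits / 40

        a1, a3, a5 = accuracy(1, 5), accuracy(3, 6), accuracy(5, 7)
        assert a3 >= a1 - 0.05  # allow Monte-Carlo wiggle
        assert a5 >= a3 - 0.05
        assert a5 > a1  # clear overall rise


class TestCommandMap:
    @pytest.mark.parametrize(
        "item,mode,expected",
        [
            (1, "SS", "turn_left_30"),
            (5, "SS", "forward_40"),
            (9, "SS", "forward_20"),
            (12, "SS", "exit"),
            (5, "CVT", 5),
            (11, "CVT", 11),
            (12, "CVT", "exit"),
        ],
    )
    def test_table_assignment(self, item, mode, expected):
        assert erp.item_to_command(item, mode) == expected

    def test_invalid_item_rejected(self):
        with pytest.raises(ValueError):
            erp.item_to_command(13, "SS")

    def test_item_group_geometry(self):
        # item = (row-1)*4 + col; row/col groups intersect at the item
        assert erp.item_groups(6) == (1, 4)  # row 2, column 2
        assert 6 in erp.group_items(1) and 6 in erp.group_items(4)
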