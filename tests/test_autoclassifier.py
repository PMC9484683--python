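import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from epsckit.autoclassifier import (
    DegenerateModelError,
    StateSignal,
    AutoclassifierModel,
    detect_events_from_states,
    fit_clusters,
    make_windows,
    nadaraya_watson_prototype,
    order_clusters,
    preprocess_trace,
    state_signal,
    train_autoencoder,
    train_classifier,
)
from epsckit.synth import SyntheticSpec, generate_trace
from epsckit.trace import Trace

FS = 25_000.0


class TestMakeWindows:
    def test_zero_windows_empty(self, default_trace):
        trace, _ = default_trace
        assert make_windows([preprocess_trace(trace)], 0).shape == (0, 128)

    def test_seed_reproducibility(self, default_trace):
        trace, _ = default_trace
        pre = [preprocess_trace(trace)]
        a = make_windows(pre, 100, rng=5)
        b = make_windows(pre, 100, rng=5)
        np.testing.assert_array_equal(a, b)

    def test_values_in_unit_interval(self, default_trace):
        trace, _ = default_trace
        w = make_windows([preprocess_trace(trace)], 500, rng=0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_short_traces_skipped(self):
        short = Trace(np.zeros(50), FS)
        assert make_windows([short], 10, rng=0).shape == (0, 128)


class TestAutoencoder:
    def test_single_epoch_plumbing(self, rng):
        w = rng.random((100, 128))
        enc, dec, hist = train_autoencoder(w, epochs=1, hidden=(32, 16), rng=rng)
        assert len(hist["loss"]) == 1
        assert np.isfinite(hist["loss"][0])

    def test_latent_softmax_contract(self, rng):
        w = rng.random((64, 128))
        enc, _, _ = train_autoencoder(w, epochs=1, hidden=(32, 16), rng=rng)
        z = enc.predict(w)
        assert z.shape == (64, 8)
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-6)
        assert (z >= 0).all()

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            train_autoencoder(np.empty((0, 128)))

    def test_reconstruction_correlation_on_event_windows(self, trained_autoclassifier):
        """The trained bottleneck must retain the event shape."""
        est = trained_autoclassifier
        trace, truth = generate_trace(
            SyntheticSpec(duration_s=4.0, noise_sigma=0.0, noise_lowpass_sigma=0.0,
                          drift_amplitude=0.0, seed=77)
        )
        pre = preprocess_trace(trace)
        m = est.model_
        rs = []
        for onset in truth.onset_s[:5]:
            i = int(onset * FS) - 20
            window = pre.samples[i : i + 128][None, :].astype(np.float32)
            recon = m.decoder.predict(m.encoder.predict(window))
            rs.append(np.corrcoef(window[0], recon[0])[0, 1])
        assert np.median(rs) >= 0.8


class TestNadarayaWatson:
    def test_constant_members_give_constant(self):
        members = np.full((10, 128), 0.3)
        np.testing.assert_allclose(nadaraya_watson_prototype(members), 0.3, atol=1e-12)

    def test_single_member_smoothed_copy(self, rng):
        # smooth waveform plus mild noise: the prototype follows the member
        member = np.sin(np.linspace(0, 2 * np.pi, 128)) + 0.05 * rng.standard_normal(128)
        proto = nadaraya_watson_prototype(member[None, :])
        assert proto.shape == (128,)
        assert np.std(np.diff(proto)) < np.std(np.diff(member))
        assert np.corrcoef(proto, member)[0, 1] > 0.95

    def test_noisy_copies_average_to_truth(self, rng):
        t = np.linspace(0, 1, 128)
        truth = -np.exp(-t / 0.2) * (1 - np.exp(-t / 0.02))
        sigma = 0.1
        members = truth + sigma * rng.standard_normal((500, 128))
        proto = nadaraya_watson_prototype(members)
        # kernel smoothing slightly biases sharp flanks; compare on the bulk
        rmse = np.sqrt(np.mean((proto[5:] - truth[5:]) ** 2))
        assert rmse < sigma / 10


class TestOrderClusters:
    def _shifted_prototypes(self):
        protos = np.zeros((7, 128))
        positions = [110, 90, 70, 50, 30, 10]
        for i, p in enumerate(positions):
            protos[i, p - 5 : p + 5] = -1.0
        # cluster 6 is flat noise
        counts = np.array([10, 10, 10, 10, 10, 10, 100])
        return protos, counts, positions

    def test_recovers_known_shift_order(self):
        protos, counts, _ = self._shifted_prototypes()
        order, noise = order_clusters(protos, counts)
        assert noise == 6
        assert order == [0, 1, 2, 3, 4, 5]  # descending minimum position

    def test_noise_excluded_from_order(self):
        protos, counts, _ = self._shifted_prototypes()
        order, noise = order_clusters(protos, counts)
        assert noise not in order
        assert sorted(order + [noise]) == list(range(7))

    def test_all_flat_prototypes_degenerate(self):
        protos = np.zeros((7, 128))
        with pytest.raises(DegenerateModelError):
            order_clusters(protos, np.ones(7))


class _StubEncoder:
    """Deterministic stand-in encoder mapping windows to fixed latents."""

    def __init__(self, latents):
        self.latents = np.asarray(latents, dtype=float)

    def predict(self, windows):
        return self.latents


class TestFitClusters:
    def test_separated_blobs_recovered(self, rng):
        centers = np.eye(7, 8)
        labels_true = np.repeat(np.arange(7), 50)
        latents = centers[labels_true] + 0.01 * rng.standard_normal((350, 8))
        windows = rng.random((350, 128))
        model, labels = fit_clusters(_StubEncoder(latents), windows, k=7, seed=0)
        assert adjusted_rand_score(labels_true, labels) >= 0.95

    def test_zero_iqr_dimension_passes_through(self, rng):
        latents = rng.random((100, 8))
        latents[:, 3] = 0.42  # constant dimension: zero IQR
        windows = rng.random((100, 128))
        model, _ = fit_clusters(_StubEncoder(latents), windows, k=7, seed=0)
        assert model.scaler_scale[3] == 1.0  # unscaled passthrough
        scaled = model.scale(latents)
        np.testing.assert_allclose(scaled[:, 3], 0.0, atol=1e-12)

    def test_seed_reproducibility(self, rng):
        latents = rng.random((200, 8))
        windows = rng.random((200, 128))
        m1, l1 = fit_clusters(_StubEncoder(latents), windows, k=7, seed=3)
        m2, l2 = fit_clusters(_StubEncoder(latents), windows, k=7, seed=3)
        np.testing.assert_array_equal(m1.centers, m2.centers)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_distinct_latents_rejected(self):
        latents = np.tile(np.arange(8.0), (50, 1))
        with pytest.raises(ValueError):
            fit_clusters(_StubEncoder(latents), np.random.rand(50, 128), k=7)


class TestClassifier:
    def test_separable_one_hot_perfect_accuracy(self, rng):
        labels = np.repeat(np.arange(7), 40)
        latents = np.eye(7, 8)[labels] * 10
        net, stats = train_classifier(latents, labels, epochs=30, rng=rng)
        assert stats["val_accuracy"] == 1.0

    def test_seed_reproducibility(self):
        labels = np.repeat(np.arange(7), 30)
        latents = np.eye(7, 8)[labels] + 0.1 * np.random.default_rng(0).standard_normal(
            (210, 8)
        )
        _, s1 = train_classifier(latents, labels, epochs=10, rng=11)
        _, s2 = train_classifier(latents, labels, epochs=10, rng=11)
        assert s1["val_accuracy"] == s2["val_accuracy"]
        assert s1["history"]["loss"] == s2["history"]["loss"]


class TestStateSignal:
    def test_length_contract(self, trained_autoclassifier):
        trace, _ = generate_trace(SyntheticSpec(duration_s=0.2, seed=5))
        pre = preprocess_trace(trace)
        st = state_signal(pre, trained_autoclassifier.model_)
        assert len(st) == len(pre) - 127

    def test_short_trace_rejected(self, trained_autoclassifier):
        with pytest.raises(ValueError):
            state_signal(Trace(np.zeros(100), FS), trained_autoclassifier.model_)

    def test_batch_equals_single_window_classification(self, trained_autoclassifier):
        m = trained_autoclassifier.model_
        trace, _ = generate_trace(SyntheticSpec(duration_s=0.1, seed=6))
        pre = preprocess_trace(trace)
        from numpy.lib.stride_tricks import sliding_window_view

        windows = sliding_window_view(pre.samples, 128)[:40].astype(np.float32)
        batch = m.classify(windows)
        single = np.array([m.classify(w[None, :])[0] for w in windows])
        np.testing.assert_array_equal(batch, single)

    def test_event_free_stretches_labelled_noise(self, trained_autoclassifier):
        """Windows far from any event must map to the noise state."""
        m = trained_autoclassifier.model_
        trace, truth = generate_trace(SyntheticSpec(duration_s=4.0, event_rate=2.0, seed=8))
        pre = preprocess_trace(trace)
        st = state_signal(pre, m)
        mask = np.ones(len(st), dtype=bool)
        fs = pre.sampling_rate
        for onset in truth.onset_s:
            lo = max(0, int(onset * fs) - 200 - 128)
            hi = min(len(st), int(onset * fs) + 400)
            mask[lo:hi] = False
        noise_frac = np.mean(st.labels[mask] == m.clusters.noise_label)
        assert noise_frac >= 0.95


def _stair_state(spans, gaps=400, n_ranks=6, noise_dips=()):
    """Construct forward/reverse ordinal tracks with one event per span.

    Each event: forward jumps 0->6 then walks down 6..1; reverse walks up
    1..6 and drops to 0.  ``spans`` are trace-coordinate durations in state
    steps (end index minus start index minus window + 1 compensated by the
    caller).  ``noise_dips`` inserts ordinal-0 samples while at rank 1.
    """
    total = sum(spans) + gaps * (len(spans) + 1) + 127 * len(spans)
    fwd = np.zeros(total)
    rev = np.zeros(total)
    labels = np.zeros(total, dtype=int)
    pos = gaps
    events = []
    for k, span in enumerate(spans):
        length = span + 127  # from start step to end step in state coords
        seg = np.linspace(n_ranks, 1, length)
        stair_f = np.round(seg)
        stair_r = np.round(np.linspace(1, n_ranks, length))
        if k in noise_dips:
            frac = noise_dips[k] if isinstance(noise_dips, dict) else 0.3
            n_dip = int(round(frac * (length + 1)))
            # dips only where the ordinal is <= 2: a 2-ordinal step stays
            # below the 0.51/step trigger after filtering
            low = np.flatnonzero(stair_f <= 2)
            stair_f[low[:n_dip]] = 0.0
        fwd[pos : pos + length] = stair_f
        rev[pos : pos + length] = stair_r
        labels[pos : pos + length] = 1
        events.append((pos, pos + length))
        pos += length + gaps
    return StateSignal(labels=labels, forward=fwd, reverse=rev), events


class TestDetectFromStates:
    def test_constant_noise_empty(self):
        st = StateSignal(labels=np.zeros(2000, int), forward=np.zeros(2000),
                         reverse=np.zeros(2000))
        assert len(detect_events_from_states(st, FS)) == 0

    def test_ideal_stair_yields_one_event(self):
        st, _ = _stair_state([100])
        es = detect_events_from_states(st, FS)
        assert len(es) == 1
        e = es[0]
        assert e.start_index < e.peak_index < e.end_index

    def test_short_event_removed_by_minimum_duration(self):
        # 10 state steps = 0.4 ms at 25 kHz: below the 0.8 ms floor
        st, _ = _stair_state([10])
        assert len(detect_events_from_states(st, FS)) == 0

    def test_long_event_removed_by_maximum_duration(self):
        st, _ = _stair_state([300])  # 12 ms > 10 ms cap
        assert len(detect_events_from_states(st, FS)) == 0

    def test_tightening_duration_gate_never_adds_events(self):
        st, _ = _stair_state([60, 100, 150])
        base = len(detect_events_from_states(st, FS, min_duration_ms=0.8))
        tighter = len(detect_events_from_states(st, FS, min_duration_ms=3.0))
        assert tighter <= base

    def test_noise_proportion_gate(self):
        st, _ = _stair_state([200, 200], noise_dips={1: 0.30})
        es = detect_events_from_states(st, FS)
        assert len(es) == 1  # the 30%-noise event is removed
        st2, _ = _stair_state([200, 200], noise_dips={1: 0.10})
        assert len(detect_events_from_states(st2, FS)) == 2

    def test_tightening_noise_cap_never_adds_events(self):
        st, _ = _stair_state([200, 200], noise_dips={1: 0.15})
        loose = len(detect_events_from_states(st, FS, noise_cap=0.25))
        tight = len(detect_events_from_states(st, FS, noise_cap=0.05))
        assert tight <= loose


class TestModelPersistence:
    def test_roundtrip_state_signal_identical(self, trained_autoclassifier, tmp_path):
        m = trained_autoclassifier.model_
        m.save(tmp_path / "model")
        m2 = AutoclassifierModel.load(tmp_path / "model")
        trace, _ = generate_trace(SyntheticSpec(duration_s=0.5, seed=21))
        pre = preprocess_trace(trace)
        s1 = state_signal(pre, m)
        s2 = state_signal(pre, m2)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        np.testing.assert_array_equal(s1.forward, s2.forward)
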