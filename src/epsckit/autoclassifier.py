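"""Machine-learning event detector ("autoclassifier").

The detector is trained unsupervised in four stages:

1. an autoencoder (dense 128→1024→256→8-softmax encoder, mirrored decoder)
   learns a compact latent description of 128-sample windows of the
   preprocessed signal (25 kHz, baseline-corrected, unit-scaled);
2. the latent vectors of a clustering sample are robust-scaled (median/IQR)
   and grouped by k-means into 7 clusters, interpreted as the states an
   event passes through while it transits the analysis window;
3. each cluster gets a Nadaraya-Watson "common signal" prototype, from
   which the noise cluster (flattest prototype) and the chronological order
   of the event clusters (prototype-minimum position, event entering →
   leaving the window) are identified;
4. a small feed-forward classifier is trained on the cluster labels so that
   encoder + classifier map any window to a state.

At detection time every window position of a trace is classified, the state
labels are re-encoded on two ordinal tracks (forward and reverse
chronological order, noise = 0) and events are read off as stairs: a steep
step in the filtered forward track marks the start, a steep step in the
reverse track the end.  Events shorter than 0.8 ms or longer than 10 ms,
and events whose internal noise-state proportion reaches 25%, are removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.preprocessing import RobustScaler

from . import nn
from .events import Event, EventSet
from .trace import Trace, blackman_harris_kernel, correct_baseline, resample, \
    scale_unit, smooth_array

__all__ = [
    "DegenerateModelError",
    "ClusterModel",
    "AutoclassifierModel",
    "StateSignal",
    "Autoclassifier",
    "preprocess_trace",
    "make_windows",
    "train_autoencoder",
    "fit_clusters",
    "nadaraya_watson_prototype",
    "order_clusters",
    "train_classifier",
    "state_signal",
    "detect_events_from_states",
]

logger = logging.getLogger(__name__)

WINDOW_LEN = 128
TARGET_RATE = 25_000.0


class DegenerateModelError(ValueError):
    """Raised when a trained model cannot express any event structure."""


def preprocess_trace(trace: Trace, window_len: int = WINDOW_LEN,
                     target_rate: float = TARGET_RATE) -> Trace:
    """Resample to the canonical rate, correct the baseline, unit-scale."""
    t = resample(trace, target_rate)
    t = correct_baseline(t, window_len)
    return scale_unit(t)


def make_windows(traces: Sequence[Trace], n_windows: int,
                 window_len: int = WINDOW_LEN,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Randomly cut ``n_windows`` windows of ``window_len`` samples from traces.

    Offsets are uniform over all valid positions of all usable traces;
    traces shorter than the window are skipped with a warning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    usable = []
    for t in traces:
        if len(t) < window_len:
            logger.warning("skipping trace of %d samples (< window %d)", len(t), window_len)
            continue
        usable.append(t.samples)
    if n_windows == 0 or not usable:
        return np.empty((0, window_len))
    counts = np.array([s.size - window_len + 1 for s in usable], dtype=float)
    probs = counts / counts.sum()
    which = rng.choice(len(usable), size=n_windows, p=probs)
    out = np.empty((n_windows, window_len))
    for i, w in enumerate(which):
        off = rng.integers(0, usable[w].size - window_len + 1)
        out[i] = usable[w][off : off + window_len]
    return out


# ---------------------------------------------------------------------------
# autoencoder

def _build_autoencoder(window_len: int, hidden: tuple[int, int], latent_dim: int,
                       l1: float, rng: np.random.Generator) -> tuple[nn.Network, nn.Network]:
    h1, h2 = hidden
    encoder = nn.Network([
        nn.Dense(window_len, h1, "relu", l1=l1, rng=rng),
        nn.Dense(h1, h2, "relu", l1=l1, rng=rng),
        nn.Dense(h2, latent_dim, "softmax", l1=0.0, rng=rng),
    ])
    decoder = nn.Network([
        nn.Dense(latent_dim, h1, "relu", l1=l1, rng=rng),
        nn.Dense(h1, h2, "relu", l1=l1, rng=rng),
        nn.Dense(h2, window_len, "linear", l1=0.0, rng=rng),
    ])
    return encoder, decoder


def train_autoencoder(
    windows: np.ndarray,
    *,
    val_windows: np.ndarray | None = None,
    hidden: tuple[int, int] = (1024, 256),
    latent_dim: int = 8,
    l1: float = 5e-6,
    epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    rng: np.random.Generator | int | None = None,
) -> tuple[nn.Network, nn.Network, dict]:
    """Train the window autoencoder; returns (encoder, decoder, history).

    Training uses Adam with the Huber loss, a reduce-on-plateau learning
    rate schedule (factor 0.2 down to 1e-6) and an L1 penalty on the hidden
    layer weights to provoke sparse connectivity.
    """
    if windows.size == 0:
        raise ValueError("empty window batch")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    window_len = windows.shape[1]
    encoder, decoder = _build_autoencoder(window_len, hidden, latent_dim, l1, rng)
    auto = nn.Network(encoder.layers + decoder.layers)
    history = nn.fit_network(
        auto, windows, windows, loss="huber", epochs=epochs, batch_size=batch_size,
        lr=lr, X_val=val_windows, Y_val=val_windows, rng=rng,
    )
    # sanity floor: must beat predicting each window's own mean by a wide margin
    ref = windows - windows.mean(axis=1, keepdims=True)
    mean_loss = float(np.mean(0.5 * np.minimum(np.abs(ref), 1.0) ** 2
                              + (np.abs(ref) - np.minimum(np.abs(ref), 1.0))))
    final = history["val_loss"][-1] if history["val_loss"] else history["loss"][-1]
    if not np.isfinite(final) or final > 2 * mean_loss:
        logger.warning("autoencoder loss %.3g above sanity floor %.3g", final, 2 * mean_loss)
    history["mean_predictor_loss"] = mean_loss
    return encoder, decoder, history


# ---------------------------------------------------------------------------
# clustering

def nadaraya_watson_prototype(member_windows: np.ndarray,
                              kernel_width: float = 2.0) -> np.ndarray:
    """Gaussian-kernel common signal of a cluster over the window axis.

    A Nadaraya-Watson regression of all member samples on the 0..L-1 time
    axis; because every member shares the same axis this reduces to a
    kernel-weighted average of the per-position means.
    """
    members = np.atleast_2d(np.asarray(member_windows, dtype=float))
    if members.shape[0] < 1:
        raise ValueError("need at least one member window")
    length = members.shape[1]
    pos = np.arange(length)
    G = np.exp(-0.5 * ((pos[:, None] - pos[None, :]) / kernel_width) ** 2)
    col_mean = members.mean(axis=0)
    return (G @ col_mean) / G.sum(axis=1)


@dataclass
class ClusterModel:
    """k-means state model in robust-scaled latent space."""

    scaler_center: np.ndarray
    scaler_scale: np.ndarray
    centers: np.ndarray                   # (k, latent_dim), scaled space
    prototypes: np.ndarray                # (k, window_len) common signals
    rms: np.ndarray                       # per-cluster member-vs-prototype RMS
    counts: np.ndarray                    # per-cluster member counts
    chronological_order: list[int] = field(default_factory=list)
    noise_label: int = -1

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def scale(self, latents: np.ndarray) -> np.ndarray:
        return (latents - self.scaler_center) / self.scaler_scale


def order_clusters(prototypes: np.ndarray, counts: np.ndarray,
                   centers: np.ndarray | None = None,
                   flat_tol: float = 1e-9) -> tuple[list[int], int]:
    """Identify the noise cluster and the chronological order of the rest.

    Noise = smallest prototype peak-to-peak span (ties: largest count).
    Event clusters are ordered by the position of the prototype minimum,
    descending — an event first appears at the trailing edge of the window
    and ages toward the leading edge.  Positional ties are broken by latent
    center distance to the previous cluster (logged).
    """
    prototypes = np.asarray(prototypes, dtype=float)
    counts = np.asarray(counts)
    k = prototypes.shape[0]
    spans = np.ptp(prototypes, axis=1)
    noise_candidates = np.flatnonzero(spans == spans.min())
    noise = int(noise_candidates[np.argmax(counts[noise_candidates])])
    rest = [c for c in range(k) if c != noise]
    if all(spans[c] <= flat_tol for c in rest):
        raise DegenerateModelError("all event-cluster prototypes are flat")
    min_pos = prototypes.argmin(axis=1)
    if len(set(int(min_pos[c]) for c in rest)) < len(rest):
        logger.info("prototype-minimum position tie; breaking by latent center distance")
        if centers is not None:
            order = sorted(
                rest,
                key=lambda c: (-int(min_pos[c]), float(np.linalg.norm(centers[c]))),
            )
            return order, noise
    order = sorted(rest, key=lambda c: -int(min_pos[c]))
    return order, noise


def fit_clusters(
    encoder: nn.Network,
    windows: np.ndarray,
    k: int = 7,
    *,
    kernel_width: float = 2.0,
    seed: int | None = 0,
    max_retries: int = 3,
) -> tuple[ClusterModel, np.ndarray]:
    """Robust-scale the latents of ``windows``, k-means them, build prototypes.

    Returns the cluster model and the per-window labels.  An empty cluster
    after convergence triggers a re-seeded restart (up to ``max_retries``).
    """
    latents = encoder.predict(windows)
    if np.unique(latents.round(decimals=9), axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct latent vectors")
    scaler = RobustScaler().fit(latents)
    scaled = scaler.transform(latents)
    labels = None
    for retry in range(max_retries):
        km = KMeans(n_clusters=k, random_state=(seed or 0) + retry, n_init=10)
        labels = km.fit_predict(scaled)
        if np.unique(labels).size == k:
            break
        logger.warning("empty cluster, re-seeding k-means (retry %d)", retry + 1)
    prototypes = np.empty((k, windows.shape[1]))
    rms = np.empty(k)
    counts = np.empty(k, dtype=int)
    for c in range(k):
        members = windows[labels == c]
        counts[c] = members.shape[0]
        prototypes[c] = nadaraya_watson_prototype(members, kernel_width)
        rms[c] = float(np.mean(np.sqrt(np.mean((members - prototypes[c]) ** 2, axis=1))))
    model = ClusterModel(
        scaler_center=scaler.center_,
        scaler_scale=scaler.scale_,
        centers=km.cluster_centers_,
        prototypes=prototypes,
        rms=rms,
        counts=counts,
    )
    order, noise = order_clusters(prototypes, counts, centers=km.cluster_centers_)
    model.chronological_order = order
    model.noise_label = noise
    return model, labels


# ---------------------------------------------------------------------------
# classifier

def train_classifier(
    latents_scaled: np.ndarray,
    labels: np.ndarray,
    *,
    n_classes: int = 7,
    hidden: tuple[int, ...] = (64, 64, 64),
    l1: float = 1e-3,
    dropout: float = 0.3,
    epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> tuple[nn.Network, dict]:
    """Train the state classifier on cluster labels (80/20 stratified split).

    Returns the network and a dict with training/validation accuracy and
    the loss history.  The final layer is trained with the softmax
    cross-entropy; :func:`classify_proba` applies the softmax at inference.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    latents_scaled = np.asarray(latents_scaled, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    onehot = np.eye(n_classes, dtype=np.float32)[labels]
    # stratified split so every class is present in training
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        cut = max(1, int(round(len(idx) * (1 - val_fraction))))
        train_idx.extend(idx[:cut])
        val_idx.extend(idx[cut:])
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx))

    layers: list = []
    n_in = latents_scaled.shape[1]
    for h in hidden:
        layers.append(nn.Dense(n_in, h, "relu", l1=l1, rng=rng))
        layers.append(nn.Dropout(dropout, rng))
        n_in = h
    layers.append(nn.Dense(n_in, n_classes, "linear", l1=0.0, rng=rng))
    net = nn.Network(layers)
    history = nn.fit_network(
        net, latents_scaled[train_idx], onehot[train_idx],
        loss="softmax_cross_entropy", epochs=epochs, batch_size=batch_size, lr=lr,
        X_val=latents_scaled[val_idx] if val_idx.size else None,
        Y_val=onehot[val_idx] if val_idx.size else None,
        rng=rng,
    )
    pred_train = net.predict(latents_scaled[train_idx]).argmax(axis=1)
    acc_train = float(np.mean(pred_train == labels[train_idx]))
    acc_val = float(
        np.mean(net.predict(latents_scaled[val_idx]).argmax(axis=1) == labels[val_idx])
    ) if val_idx.size else float("nan")
    return net, {"train_accuracy": acc_train, "val_accuracy": acc_val,
                 "history": history}


def classify_proba(net: nn.Network, latents_scaled: np.ndarray) -> np.ndarray:
    """Class probabilities (softmax over the classifier logits)."""
    logits = net.predict(latents_scaled)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# full model and state-based detection

@dataclass
class AutoclassifierModel:
    """Trained encoder + cluster model + classifier, plus training metadata."""

    encoder: nn.Network
    decoder: nn.Network
    classifier: nn.Network
    clusters: ClusterModel
    config: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def encode(self, windows: np.ndarray) -> np.ndarray:
        return self.encoder.predict(windows)

    def classify(self, windows: np.ndarray) -> np.ndarray:
        """Most probable state label for each window."""
        return self.classify_proba(windows).argmax(axis=1)

    def classify_proba(self, windows: np.ndarray) -> np.ndarray:
        scaled = self.clusters.scale(self.encode(windows))
        return classify_proba(self.classifier, scaled.astype(np.float32))

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, net in (("encoder", self.encoder), ("decoder", self.decoder),
                          ("classifier", self.classifier)):
            for i, w in enumerate(net.get_weights()):
                arrays[f"{name}_{i}"] = w
        for name in ("scaler_center", "scaler_scale", "centers", "prototypes",
                     "rms", "counts"):
            arrays[f"clusters_{name}"] = getattr(self.clusters, name)
        np.savez(d / "weights.npz", **arrays)
        meta = {
            "config": self.config,
            "metadata": self.metadata,
            "chronological_order": list(map(int, self.clusters.chronological_order)),
            "noise_label": int(self.clusters.noise_label),
            "layout": {
                "encoder": [(l.W.shape, l.activation, l.l1) for l in self.encoder.dense_layers()],
                "decoder": [(l.W.shape, l.activation, l.l1) for l in self.decoder.dense_layers()],
                "classifier": [
                    (l.W.shape, l.activation, l.l1) for l in self.classifier.dense_layers()
                ],
            },
        }
        (d / "model.json").write_text(json.dumps(meta, default=list, indent=1))

    @staticmethod
    def load(directory) -> "AutoclassifierModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        data = np.load(d / "weights.npz")

        def build(name: str) -> nn.Network:
            layers = []
            for (shape, act, l1) in meta["layout"][name]:
                layers.append(nn.Dense(int(shape[0]), int(shape[1]), act, l1=l1))
            net = nn.Network(layers)
            net.set_weights([data[f"{name}_{i}"]
                             for i in range(2 * len(meta["layout"][name]))])
            return net

        clusters = ClusterModel(
            scaler_center=data["clusters_scaler_center"],
            scaler_scale=data["clusters_scaler_scale"],
            centers=data["clusters_centers"],
            prototypes=data["clusters_prototypes"],
            rms=data["clusters_rms"],
            counts=data["clusters_counts"],
            chronological_order=list(meta["chronological_order"]),
            noise_label=meta["noise_label"],
        )
        return AutoclassifierModel(
            encoder=build("encoder"), decoder=build("decoder"),
            classifier=build("classifier"), clusters=clusters,
            config=meta.get("config", {}), metadata=meta.get("metadata", {}),
        )


@dataclass
class StateSignal:
    """Per-window-position state labels and their ordinal re-encodings.

    ``labels[i]`` is the state of the window starting at sample
    ``i * stride``; the forward track maps event clusters to descending
    chronological rank (entering cluster highest), the reverse track to
    ascending rank; noise maps to 0 on both.
    """

    labels: np.ndarray
    forward: np.ndarray
    reverse: np.ndarray
    stride: int = 1
    window_len: int = WINDOW_LEN

    def __len__(self) -> int:
        return self.labels.size


def _ordinal_tracks(labels: np.ndarray, order: Sequence[int],
                    noise_label: int) -> tuple[np.ndarray, np.ndarray]:
    n_states = max(int(labels.max(initial=0)), noise_label, max(order, default=0)) + 1
    fwd_map = np.zeros(n_states)
    rev_map = np.zeros(n_states)
    n_evt = len(order)
    for rank, c in enumerate(order):     # order: entering -> leaving
        fwd_map[c] = n_evt - rank        # entering cluster -> highest
        rev_map[c] = rank + 1            # leaving cluster -> highest
    fwd_map[noise_label] = 0.0
    rev_map[noise_label] = 0.0
    return fwd_map[labels], rev_map[labels]


def state_signal(trace: Trace, model: AutoclassifierModel, stride: int = 1,
                 chunk: int = 16384) -> StateSignal:
    """Classify every (strided) window position of a preprocessed trace."""
    window_len = int(model.config.get("window_len", WINDOW_LEN))
    if len(trace) < window_len:
        raise ValueError(f"trace shorter than the {window_len}-sample window")
    windows = sliding_window_view(trace.samples, window_len)[::stride]
    labels = np.empty(windows.shape[0], dtype=int)
    for i in range(0, windows.shape[0], chunk):
        block = np.ascontiguousarray(windows[i : i + chunk], dtype=np.float32)
        labels[i : i + chunk] = model.classify(block)
    fwd, rev = _ordinal_tracks(labels, model.clusters.chronological_order,
                               model.clusters.noise_label)
    return StateSignal(labels=labels, forward=fwd, reverse=rev, stride=stride,
                       window_len=window_len)


def _steps(track: np.ndarray, kernel: np.ndarray, threshold: float,
           sign: int) -> np.ndarray:
    """Indices of steep steps (of the given sign) in the filtered track."""
    half = kernel.size // 2
    filt = np.convolve(np.pad(track, half, mode="edge"), kernel, mode="valid")
    slope = np.diff(filt) * sign
    above = slope >= threshold
    if not above.any():
        return np.empty(0, dtype=int)
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return np.array(
        [s + int(np.argmax(slope[s : e + 1])) for s, e in zip(starts, ends)], dtype=int
    )


def detect_events_from_states(
    state: StateSignal,
    sampling_rate: float,
    trace: Trace | None = None,
    *,
    slope_threshold: float = 0.51,
    filter_width: int = 17,
    min_duration_ms: float = 0.8,
    max_duration_ms: float = 10.0,
    noise_cap: float = 0.25,
) -> EventSet:
    """Read events off the ordinal state tracks.

    Starts are steep rising steps of the filtered forward track, ends steep
    falling steps of the filtered reverse track; each start is paired with
    the nearest subsequent end.  Events outside the duration gates or with
    a noise-state proportion of ``noise_cap`` or more are removed; unpaired
    starts are dropped.  When the preprocessed ``trace`` is given, peak
    positions are refined to the trace minimum inside each event.
    """
    kernel = blackman_harris_kernel(filter_width).coefficients
    stride = state.stride
    window = state.window_len
    fs_track = sampling_rate / stride
    starts = _steps(state.forward, kernel, slope_threshold, +1)
    ends = _steps(state.reverse, kernel, slope_threshold, -1)
    min_span = min_duration_ms * 1e-3 * sampling_rate
    max_span = max_duration_ms * 1e-3 * sampling_rate
    events = []
    used_end = -1
    for s in starts:
        # trace coordinates: the event enters at the trailing edge of the
        # window, so the start step at track index s maps to sample
        # s*stride + window - 1; the end step maps to the sample where the
        # event has left the window, i.e. track index * stride.
        s_tr = s * stride + window - 1
        cand = ends[(ends * stride > s_tr) & (ends > used_end)]
        if cand.size == 0:
            continue  # start with no end: dropped
        e = int(cand[0])
        e_tr = e * stride
        span = e_tr - s_tr
        if span > max_span or span < min_span:
            continue
        # ordinal 0 marks the noise state on both tracks
        noise_frac = float(np.mean(state.forward[s : e + 1] == 0))
        if noise_frac >= noise_cap:
            continue
        used_end = e
        if trace is not None:
            lo = max(0, s_tr - int(0.001 * sampling_rate))
            hi = min(len(trace), e_tr + 1)
            peak = lo + int(np.argmin(trace.samples[lo:hi]))
        else:
            peak = (s_tr + e_tr) // 2
        events.append(
            Event(
                peak_index=int(peak),
                start_index=int(min(s_tr, peak)),
                end_index=int(max(e_tr, peak)),
                amplitude=None if trace is None else float(
                    max(0.0, np.median(trace.samples[max(0, s_tr - 50) : s_tr + 1])
                        - trace.samples[peak])
                ),
                method_tag="autoclassifier",
            )
        )
    # de-duplicate peaks that can arise from refinement into a shared minimum
    seen: set[int] = set()
    uniq = [e for e in events if not (e.peak_index in seen or seen.add(e.peak_index))]
    return EventSet(uniq, sampling_rate, "autoclassifier")


# ---------------------------------------------------------------------------
# estimator facade

class Autoclassifier(BaseEstimator):
    """End-to-end machine-learning event detector.

    ``fit`` takes a list of raw traces, trains autoencoder, clustering and
    classifier; ``predict`` takes one raw trace and returns an
    :class:`~epsckit.events.EventSet`.  All randomness flows from ``seed``.

    The defaults reproduce the full-scale training recipe (50k training and
    10k validation windows, 100 epochs); pass smaller values for a
    scaled-down run.
    """

    def __init__(
        self,
        window_len: int = WINDOW_LEN,
        target_rate: float = TARGET_RATE,
        latent_dim: int = 8,
        encoder_hidden: tuple[int, int] = (1024, 256),
        k: int = 7,
        n_train_windows: int = 50_000,
        n_val_windows: int = 10_000,
        n_cluster_windows: int = 60_000,
        ae_epochs: int = 100,
        ae_l1: float = 5e-6,
        clf_hidden: tuple[int, ...] = (64, 64, 64),
        clf_epochs: int = 100,
        clf_l1: float = 1e-3,
        clf_dropout: float = 0.3,
        batch_size: int = 32,
        lr: float = 1e-3,
        stride: int = 1,
        slope_threshold: float = 0.51,
        state_filter_width: int = 17,
        min_duration_ms: float = 0.8,
        max_duration_ms: float = 10.0,
        noise_cap: float = 0.25,
        seed: int = 0,
    ):
        self.window_len = window_len
        self.target_rate = target_rate
        self.latent_dim = latent_dim
        self.encoder_hidden = encoder_hidden
        self.k = k
        self.n_train_windows = n_train_windows
        self.n_val_windows = n_val_windows
        self.n_cluster_windows = n_cluster_windows
        self.ae_epochs = ae_epochs
        self.ae_l1 = ae_l1
        self.clf_hidden = clf_hidden
        self.clf_epochs = clf_epochs
        self.clf_l1 = clf_l1
        self.clf_dropout = clf_dropout
        self.batch_size = batch_size
        self.lr = lr
        self.stride = stride
        self.slope_threshold = slope_threshold
        self.state_filter_width = state_filter_width
        self.min_duration_ms = min_duration_ms
        self.max_duration_ms = max_duration_ms
        self.noise_cap = noise_cap
        self.seed = seed

    def fit(self, X: Sequence[Trace], y=None) -> "Autoclassifier":
        """Train on a list of raw traces."""
        rng = np.random.default_rng(self.seed)
        pre = [preprocess_trace(t, self.window_len, self.target_rate) for t in X]
        train_w = make_windows(pre, self.n_train_windows, self.window_len, rng)
        val_w = make_windows(pre, self.n_val_windows, self.window_len, rng)
        encoder, decoder, ae_hist = train_autoencoder(
            train_w, val_windows=val_w, hidden=self.encoder_hidden,
            latent_dim=self.latent_dim, l1=self.ae_l1, epochs=self.ae_epochs,
            batch_size=self.batch_size, lr=self.lr, rng=rng,
        )
        n_cl = min(self.n_cluster_windows, train_w.shape[0])
        cluster_w = train_w[rng.choice(train_w.shape[0], size=n_cl, replace=False)]
        clusters, labels = fit_clusters(
            encoder, cluster_w, self.k, seed=int(rng.integers(2**31 - 1)),
        )
        scaled = clusters.scale(encoder.predict(cluster_w))
        classifier, clf_stats = train_classifier(
            scaled, labels, n_classes=self.k, hidden=self.clf_hidden,
            l1=self.clf_l1, dropout=self.clf_dropout, epochs=self.clf_epochs,
            batch_size=self.batch_size, lr=self.lr, rng=rng,
        )
        self.model_ = AutoclassifierModel(
            encoder=encoder, decoder=decoder, classifier=classifier,
            clusters=clusters,
            config={"window_len": self.window_len, "target_rate": self.target_rate,
                    "seed": self.seed},
            metadata={
                "ae_loss": ae_hist["loss"][-1],
                "ae_val_loss": ae_hist["val_loss"][-1] if ae_hist["val_loss"] else None,
                "clf_train_accuracy": clf_stats["train_accuracy"],
                "clf_val_accuracy": clf_stats["val_accuracy"],
            },
        )
        self.classifier_val_accuracy_ = clf_stats["val_accuracy"]
        return self

    def predict(self, trace: Trace) -> EventSet:
        """Detect events on one raw trace."""
        if not hasattr(self, "model_"):
            raise RuntimeError("Autoclassifier is not fitted")
        pre = preprocess_trace(trace, self.window_len, self.target_rate)
        state = state_signal(pre, self.model_, stride=self.stride)
        events = detect_events_from_states(
            state, pre.sampling_rate, trace=pre,
            slope_threshold=self.slope_threshold,
            filter_width=self.state_filter_width,
            min_duration_ms=self.min_duration_ms,
            max_duration_ms=self.max_duration_ms,
            noise_cap=self.noise_cap,
        )
        events.method_tag = "autoclassifier"
        return events

    detect = predict
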