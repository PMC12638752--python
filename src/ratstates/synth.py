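"""Synthetic recordings and source scenes with known ground truth.

The generator emulates the structure that microstate analysis assumes: a
semi-Markov sequence of quasi-stable topographies with gamma-distributed
dwell times (tens to hundreds of milliseconds), a rectified oscillatory
amplitude envelope that yields dense GFP peaks, and additive sensor noise.
Everything is reproducible from (parameters, seed).

A toy source scene — positions, neighbourhood graph, band-limited source
time series with a planted coupling to a microstate regressor, and an
optional distance-decay leadfield — provides inputs for the
source-association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording
from .montage import Montage, generate_montage

__all__ = [
    "GroundTruth",
    "SourceScene",
    "BAND_EDGES",
    "random_maps",
    "make_ground_truth",
    "simulate_state_sequence",
    "simulate_recording",
    "simulate_source_scene",
    "stationary_distribution",
]

#: Band edges in Hz used across the package (broadband = no filtering).
BAND_EDGES: dict[str, tuple[float, float] | None] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
    "broadband": None,
}


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic microstate process.

    maps : (K, C) zero-channel-mean, unit-norm topographies.
    dwell_mean_s / dwell_shape : gamma dwell-time distribution (seconds).
    transition_matrix : (K, K) row-stochastic, zero diagonal.
    amp_freq_hz / amp_mod_freq_hz / amp_mod_depth / amplitude : rectified
        oscillatory GFP envelope ``amplitude * |sin(2*pi*f t)| *
        (1 + depth*sin(2*pi*f_mod t))``.
    noise_sd : additive sensor-noise standard deviation (same units as
        ``amplitude``, microvolts).
    """

    maps: np.ndarray
    dwell_mean_s: float = 0.1
    dwell_shape: float = 2.0
    transition_matrix: np.ndarray | None = None
    amplitude: float = 10.0
    amp_freq_hz: float = 10.0
    amp_mod_freq_hz: float = 0.17
    amp_mod_depth: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be (K, C)")
        k = self.maps.shape[0]
        if self.dwell_mean_s <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell parameters must be positive")
        if self.transition_matrix is None:
            tm = np.ones((k, k)) - np.eye(k)
            self.transition_matrix = tm / max(k - 1, 1)
        else:
            self.transition_matrix = np.asarray(self.transition_matrix, float)
        tm = self.transition_matrix
        if tm.shape != (k, k):
            raise ValueError("transition matrix must be (K, K)")
        if k > 1:
            if np.any(np.diag(tm) != 0):
                raise ValueError("transition matrix must have zero diagonal")
            if not np.allclose(tm.sum(axis=1), 1.0):
                raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def random_maps(k: int, n_channels: int, rng: np.random.Generator,
                orthogonalize: bool = True,
                correlation: float = 0.0) -> np.ndarray:
    """Draw K zero-channel-mean unit-norm topographies.

    With ``orthogonalize`` the maps are pairwise orthogonal; a nonzero
    ``correlation`` then mixes each map with a common component so that
    recovery difficulty is controllable (empirical microstate maps are
    inter-correlated).
    """
    if k > n_channels - 1:
        raise ValueError("cannot draw more orthogonal maps than C - 1")
    x = rng.standard_normal((k + 1, n_channels))
    x -= x.mean(axis=1, keepdims=True)
    if orthogonalize:
        # Gram-Schmidt inside the zero-mean subspace
        q = []
        for row in x:
            v = row.copy()
            for u in q:
                v -= (v @ u) * u
            n = np.linalg.norm(v)
            if n < 1e-12:
                raise RuntimeError("degenerate draw; retry with another seed")
            q.append(v / n)
        common, maps = q[0], np.array(q[1:])
        if correlation:
            maps = np.sqrt(1 - correlation**2) * maps + correlation * common
    else:
        maps = x[1:]
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def make_ground_truth(k: int = 5, n_channels: int = 19, snr: float = 5.0,
                      seed: int = 0, dwell_mean_s: float = 0.1,
                      orthogonalize: bool = True,
                      correlation: float = 0.0) -> GroundTruth:
    """Convenience factory: random maps plus noise scaled to a target SNR.

    SNR is defined as per-channel signal RMS over sensor-noise SD.  With a
    unit-norm map scaled by amplitude ``a(t)``, per-channel signal power is
    ``E[a^2]/C``; for the default envelope ``E[a^2] = A^2/2 (1 + depth^2/2)``.
    """
    rng = np.random.default_rng(seed)
    maps = random_maps(k, n_channels, rng, orthogonalize, correlation)
    truth = GroundTruth(maps=maps, dwell_mean_s=dwell_mean_s, seed=seed)
    if snr and np.isfinite(snr):
        amp_ms = truth.amplitude**2 / 2 * (1 + truth.amp_mod_depth**2 / 2)
        truth.noise_sd = float(np.sqrt(amp_ms / n_channels) / snr)
    return truth


def simulate_state_sequence(truth: GroundTruth, duration_s: float,
                            fs: float) -> np.ndarray:
    """Draw a per-sample label sequence from the planted semi-Markov process.

    States follow ``truth.transition_matrix``; dwell times are gamma
    (shape ``dwell_shape``, mean ``dwell_mean_s``) discretised at ``fs``
    with a minimum of one sample.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    k = truth.n_states
    tm = truth.transition_matrix
    if k > 1 and np.any(tm.sum(axis=1) == 0):
        raise ValueError("transition matrix has an all-zero row")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration_s * fs))
    labels = np.empty(n, dtype=np.int64)
    scale = truth.dwell_mean_s / truth.dwell_shape
    state = int(rng.integers(k))
    t = 0
    while t < n:
        dwell = max(1, int(round(rng.gamma(truth.dwell_shape, scale) * fs)))
        labels[t: t + dwell] = state
        t += dwell
        if k > 1:
            state = int(rng.choice(k, p=tm[state]))
    return labels


def _amplitude(truth: GroundTruth, n: int, fs: float) -> np.ndarray:
    t = np.arange(n) / fs
    slow = 1 + truth.amp_mod_depth * np.sin(2 * np.pi * truth.amp_mod_freq_hz * t)
    return truth.amplitude * np.abs(np.sin(2 * np.pi * truth.amp_freq_hz * t)) * slow


def simulate_recording(truth: GroundTruth, labels: np.ndarray, fs: float,
                       montage: Montage | None = None) -> Recording:
    """Render a label sequence into a multichannel recording.

    Sample ``t`` is ``amplitude(t) * maps[labels[t]]`` plus white sensor
    noise projected onto the average-reference subspace, so the channel
    mean of every sample is zero by construction.
    """
    if montage is None:
        montage = generate_montage(truth.n_channels)
    if truth.n_channels != montage.n_channels:
        raise ValueError(
            f"maps have {truth.n_channels} channels, montage has "
            f"{montage.n_channels}"
        )
    labels = np.asarray(labels)
    n = labels.size
    amp = _amplitude(truth, n, fs)
    data = (truth.maps[labels] * amp[:, None]).T.copy()
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed + 1)
        noise = rng.normal(0.0, truth.noise_sd, size=data.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        data += noise
    return Recording(data, fs, montage)


def stationary_distribution(truth: GroundTruth) -> np.ndarray:
    """Long-run fraction of time spent in each state.

    For a semi-Markov process with identical dwell distributions across
    states this is the stationary distribution of the embedded jump chain.
    """
    tm = truth.transition_matrix
    k = tm.shape[0]
    if k == 1:
        return np.ones(1)
    w, v = np.linalg.eig(tm.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1))])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Source scenes


@dataclass
class SourceScene:
    """Toy source space for the band-limited-power association stage."""

    source_positions: np.ndarray
    neighbor_graph: "object"  # networkx.Graph
    source_series: np.ndarray  # (S, T)
    band_assignment: list[str]
    fs: float
    coupling: np.ndarray = field(default=None)  # planted per-source strength
    regressor: np.ndarray = field(default=None)  # the coupled series
    leadfield: np.ndarray | None = None

    @property
    def n_sources(self) -> int:
        return self.source_series.shape[0]


def _bandlimited_noise(rng: np.random.Generator, band: str, n: int,
                       fs: float) -> np.ndarray:
    from scipy.signal import butter, filtfilt

    x = rng.standard_normal(n)
    edges = BAND_EDGES[band]
    if edges is None:
        b, a = butter(3, [1.0, 40.0], btype="bandpass", fs=fs)
    else:
        b, a = butter(3, list(edges), btype="bandpass", fs=fs)
    y = filtfilt(b, a, x)
    return y / max(y.std(), 1e-12)


def simulate_source_scene(n_sources: int, bands: list[str] | str,
                          coupling: np.ndarray | float, fs: float,
                          duration_s: float, seed: int,
                          regressor: np.ndarray | None = None,
                          n_neighbors: int = 5,
                          montage: Montage | None = None) -> SourceScene:
    """Build a toy source scene with a planted regressor coupling.

    Each source emits band-limited noise whose instantaneous amplitude is
    mixed with a slow positive ``regressor`` series in proportion to that
    source's ``coupling``; band-limited power therefore carries a linear
    trace of the regressor that the association GLM should recover.  If no
    regressor is supplied, a smoothed rectified noise series is generated
    and returned in the scene.

    A symmetric k-nearest-neighbour graph over random 3-D positions (mm)
    serves as the neighbourhood structure for cluster enhancement, and an
    optional distance-decay leadfield maps sources to the montage.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    if isinstance(bands, str):
        bands = [bands] * n_sources
    if len(bands) != n_sources:
        bands = [bands[i % len(bands)] for i in range(n_sources)]
    for b in bands:
        if b not in BAND_EDGES:
            raise ValueError(f"unknown band {b!r}; expected one of "
                             f"{sorted(BAND_EDGES)}")
    coupling = np.broadcast_to(np.asarray(coupling, float), (n_sources,)).copy()

    if regressor is None:
        from scipy.ndimage import uniform_filter1d

        raw = np.abs(rng.standard_normal(n))
        regressor = uniform_filter1d(raw, size=max(int(0.2 * fs), 1))
    regressor = np.asarray(regressor, float)
    if regressor.size != n:
        raise ValueError("regressor length must match duration_s * fs")
    reg_norm = (regressor - regressor.min())
    reg_norm /= max(reg_norm.max(), 1e-12)

    positions = rng.uniform(-6, 6, size=(n_sources, 3))
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    graph = nx.Graph()
    graph.add_nodes_from(range(n_sources))
    kq = min(n_neighbors, n_sources - 1)
    for i in range(n_sources):
        for j in np.argsort(d[i])[:kq]:
            graph.add_edge(i, int(j))

    series = np.empty((n_sources, n))
    for s in range(n_sources):
        carrier = _bandlimited_noise(rng, bands[s], n, fs)
        envelope = 1.0 + coupling[s] * reg_norm
        series[s] = envelope * carrier

    leadfield = None
    if montage is not None:
        epos = np.column_stack([montage.positions,
                                np.zeros(montage.n_channels)])[:, :3]
        dist = np.linalg.norm(epos[:, None] - positions[None, :], axis=2)
        leadfield = 1.0 / (1.0 + dist**2)

    return SourceScene(positions, graph, series, list(bands), fs,
                       coupling=coupling, regressor=regressor,
                       leadfield=leadfield)
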