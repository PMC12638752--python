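"""Microstate extraction and description.

The analysis follows the standard topographic-segmentation recipe:

1. compute the global field power (GFP) — the per-sample population
   standard deviation across channels — and locate its peaks, the moments
   of highest signal-to-noise topography;
2. cluster the topographies at GFP peaks with atomize-and-agglomerate
   hierarchical clustering (AAHC), which starts from singleton clusters and
   repeatedly dissolves the cluster contributing least global explained
   variance (GEV), reassigning its members by absolute spatial correlation;
3. backfit the resulting template maps to every sample of the continuous
   recording;
4. derive the classical parameters (mean GFP, duration, occurrence,
   coverage, GEV) and the observed-vs-expected transition structure.

Polarity is ignored throughout: a topography and its negation belong to
the same microstate class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Recording

__all__ = [
    "GfpSeries",
    "MicrostateModel",
    "LabelSequence",
    "MicrostateStats",
    "TransitionAnalysis",
    "compute_gfp",
    "find_gfp_peaks",
    "spatial_correlation",
    "aahc_cluster",
    "backfit",
    "compute_gev",
    "microstate_parameters",
    "expected_transitions",
    "transition_analysis",
]

UNASSIGNED = -1


# ---------------------------------------------------------------------------
# GFP

@dataclass
class GfpSeries:
    """Per-sample global field power and the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray

    def __len__(self) -> int:
        return self.values.size


def compute_gfp(rec: Recording, find_peaks: bool = True) -> GfpSeries:
    """Global field power: population SD across channels at each sample.

    Expects average-referenced data (for zero-mean samples the GFP equals
    the RMS amplitude across channels).
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    values = rec.data.std(axis=0, ddof=0)
    peaks = find_gfp_peaks(values) if find_peaks else np.array([], dtype=int)
    return GfpSeries(values, peaks)


def find_gfp_peaks(values: np.ndarray | GfpSeries) -> np.ndarray:
    """Strict interior local maxima of a series.

    A maximal plateau counts as one peak located at its first sample; a
    plateau touching either edge of the series is not a peak.
    """
    v = values.values if isinstance(values, GfpSeries) else np.asarray(values)
    n = v.size
    if n < 3:
        return np.array([], dtype=int)
    d = np.diff(v)
    sl = np.sign(d)
    nzidx = np.nonzero(sl)[0]
    if nzidx.size == 0:
        return np.array([], dtype=int)
    # sign of the next non-flat step at or after each position
    pos = np.searchsorted(nzidx, np.arange(sl.size))
    next_sign = np.where(pos < nzidx.size,
                         sl[nzidx[np.minimum(pos, nzidx.size - 1)]], 0)
    i = np.arange(1, n - 1)
    mask = (d[i - 1] > 0) & (next_sign[i] < 0)
    return i[mask]


# ---------------------------------------------------------------------------
# Spatial similarity

def spatial_correlation(u: np.ndarray, v: np.ndarray,
                        ignore_polarity: bool = True) -> float:
    """Pearson correlation of two topographies across channels.

    With ``ignore_polarity`` (the default) the absolute value is returned,
    since a microstate map and its negation describe the same field
    configuration.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape or u.size < 3:
        raise ValueError("topographies must match and have >= 3 channels")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu < 1e-300 or nv < 1e-300:
        raise ValueError("correlation undefined for a constant topography")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if ignore_polarity else r


# ---------------------------------------------------------------------------
# AAHC

@dataclass
class MicrostateModel:
    """K template topographies plus clustering provenance.

    ``maps`` rows are zero-channel-mean and unit-norm; their global sign is
    arbitrary (fixed here so the largest-magnitude channel is positive).
    ``training_gev`` is the GEV of the model on its own training peaks.
    ``training_assignments`` holds the per-peak cluster index.
    """

    maps: np.ndarray
    training_gev: float
    provenance: dict = field(default_factory=dict)
    training_assignments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must be (K, C) with K >= 1")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def _top_component(scatter: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenpair of a symmetric scatter matrix, sign-fixed."""
    w, v = np.linalg.eigh(scatter)
    t = v[:, -1]
    if t[np.argmax(np.abs(t))] < 0:
        t = -t
    return t, float(w[-1])


def aahc_cluster(peak_maps: np.ndarray, gfp_at_peaks: np.ndarray | None = None,
                 k_min: int = 1, k_max: int = 10) -> dict[int, MicrostateModel]:
    """Atomize-and-agglomerate hierarchical clustering of peak topographies.

    Every peak map starts as its own cluster.  At each step the cluster
    whose removal costs the least GEV is dissolved and its members are
    reassigned to the remaining cluster of highest absolute spatial
    correlation.  A cluster's template is the dominant spatial component
    (first principal component) of its members, which is also the
    GEV-optimal polarity-invariant representative: the GEV contribution of
    a cluster with GFP-weighted scatter ``S`` equals the top eigenvalue of
    ``S`` divided by the total squared GFP.

    Returns one model per K in ``k_min..k_max``; the hierarchy is nested
    and deterministic given the input order.
    """
    x = np.asarray(peak_maps, float)
    if x.ndim != 2:
        raise ValueError("peak_maps must be (P, C)")
    p, c = x.shape
    if p <= k_max:
        raise ValueError(f"need more peaks ({p}) than k_max ({k_max})")
    if not 1 <= k_min <= k_max:
        raise ValueError("require 1 <= k_min <= k_max")
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms < 1e-300):
        raise ValueError("peak maps must be non-constant")
    if gfp_at_peaks is None:
        gfp_at_peaks = norms / np.sqrt(c)
    gfp = np.asarray(gfp_at_peaks, float)
    w = (gfp / norms) ** 2          # per-peak scatter weight: gfp^2 r^2 = t'St
    denom = float(np.sum(gfp**2))
    xn = x / norms[:, None]

    members: list[list[int] | None] = [[i] for i in range(p)]
    scatter = [w[i] * np.outer(x[i], x[i]) for i in range(p)]
    templates = xn.copy()
    lam = w * norms**2
    alive = list(range(p))

    snapshots: dict[int, MicrostateModel] = {}

    def snapshot(k: int) -> None:
        order = sorted(alive, key=lambda ci: -lam[ci])
        maps = np.array([templates[ci] for ci in order])
        assign = np.empty(p, dtype=int)
        for new_idx, ci in enumerate(order):
            assign[members[ci]] = new_idx
        gev = float(sum(lam[ci] for ci in order) / denom)
        snapshots[k] = MicrostateModel(
            maps, training_gev=gev,
            provenance={"algorithm": "aahc", "n_peaks": p},
            training_assignments=assign,
        )

    while True:
        k = len(alive)
        if k_min <= k <= k_max:
            snapshot(k)
        if k <= k_min:
            break
        # dissolve the cluster contributing least GEV
        worst_pos = int(np.argmin([lam[ci] for ci in alive]))
        worst = alive.pop(worst_pos)
        orphan_idx = np.array(members[worst], dtype=int)
        members[worst] = None
        t_alive = np.array([templates[ci] for ci in alive])
        corr = np.abs(xn[orphan_idx] @ t_alive.T)
        target_pos = np.argmax(corr, axis=1)
        touched = set()
        for m, tp in zip(orphan_idx, target_pos):
            ci = alive[tp]
            members[ci].append(int(m))
            scatter[ci] += w[m] * np.outer(x[m], x[m])
            touched.add(ci)
        for ci in touched:
            templates[ci], lam[ci] = _top_component(scatter[ci])

    return snapshots


# ---------------------------------------------------------------------------
# Backfitting and GEV

@dataclass
class LabelSequence:
    """Per-sample microstate assignment.

    ``labels[t]`` is the winning class index, or ``UNASSIGNED`` (-1) where
    GFP is zero; ``correlations[t]`` is the absolute spatial correlation to
    the winning map.
    """

    labels: np.ndarray
    correlations: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.correlations = np.asarray(self.correlations, float)
        if self.labels.shape != self.correlations.shape:
            raise ValueError("labels and correlations must align")


def _sample_map_correlations(data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """|Pearson r| between every sample (column) and every map; (T, K)."""
    xc = data - data.mean(axis=0, keepdims=True)
    xnorm = np.linalg.norm(xc, axis=0)
    mc = maps - maps.mean(axis=1, keepdims=True)
    mnorm = np.linalg.norm(mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(xc.T @ mc.T) / (xnorm[:, None] * mnorm[None, :])
    corr[xnorm == 0] = 0.0
    return corr


def backfit(rec: Recording, model: MicrostateModel) -> LabelSequence:
    """Label every sample with the template of highest |spatial correlation|.

    Ties break toward the lowest class index; zero-GFP samples remain
    unassigned.
    """
    if rec.n_channels != model.n_channels:
        raise ValueError("channel count mismatch between recording and model")
    corr = _sample_map_correlations(rec.data, model.maps)
    labels = np.argmax(corr, axis=1)
    best = corr[np.arange(corr.shape[0]), labels]
    gfp = rec.data.std(axis=0, ddof=0)
    labels = np.where(gfp > 0, labels, UNASSIGNED)
    best = np.where(gfp > 0, best, 0.0)
    return LabelSequence(labels, best, model.k)


def compute_gev(rec: Recording, model: MicrostateModel, labels: LabelSequence,
                scope: str = "peaks") -> tuple[np.ndarray, float]:
    """Global explained variance per class and in total.

    GEV_k = sum_i GFP_i^2 C_ik^2 [L_i = k] / sum_i GFP_i^2, where C_ik is
    the spatial correlation between sample i and map k and L_i the
    backfitted label.  ``scope`` selects the samples entering both sums:
    GFP peaks (default) or all samples.
    """
    if scope not in ("peaks", "all"):
        raise ValueError("scope must be 'peaks' or 'all'")
    gfp = compute_gfp(rec, find_peaks=(scope == "peaks"))
    idx = gfp.peak_indices if scope == "peaks" else np.arange(len(gfp))
    if idx.size == 0 or not np.any(gfp.values[idx] > 0):
        raise ValueError("GEV undefined: no non-zero-GFP samples in scope")
    g2 = gfp.values[idx] ** 2
    lab = labels.labels[idx]
    corr = _sample_map_correlations(rec.data[:, idx], model.maps)
    denom = g2.sum()
    gev_k = np.zeros(model.k)
    for k in range(model.k):
        sel = lab == k
        gev_k[k] = np.sum(g2[sel] * corr[sel, k] ** 2) / denom
    return gev_k, float(gev_k.sum())


# ---------------------------------------------------------------------------
# Parameters

@dataclass
class MicrostateStats:
    """Classical per-class microstate parameters.

    duration is reported both in seconds (``duration_s``) and milliseconds
    (``duration_ms``); occurrence is events per second; coverage is the
    fraction of assigned samples.  Unassigned (zero-GFP) samples are
    excluded from the coverage denominator so that coverages sum to one.
    """

    gfp_mean: np.ndarray
    duration_s: np.ndarray
    occurrence: np.ndarray
    coverage: np.ndarray
    n_runs: np.ndarray
    total_time_s: float
    gev: np.ndarray | None = None
    tot_gev: float | None = None

    @property
    def duration_ms(self) -> np.ndarray:
        return self.duration_s * 1e3

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "gfp_mean": self.gfp_mean,
            "duration_s": self.duration_s,
            "duration_ms": self.duration_ms,
            "occurrence_per_s": self.occurrence,
            "coverage": self.coverage,
            "n_runs": self.n_runs,
        })


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal assigned labels as (label, length) pairs."""
    out: list[tuple[int, int]] = []
    prev = None
    length = 0
    for lab in labels:
        if lab == prev:
            length += 1
        else:
            if prev is not None and prev != UNASSIGNED:
                out.append((int(prev), length))
            prev = lab
            length = 1
    if prev is not None and prev != UNASSIGNED:
        out.append((int(prev), length))
    return out


def microstate_parameters(labels: LabelSequence, gfp: GfpSeries,
                          fs: float) -> MicrostateStats:
    """Duration, occurrence, coverage and mean GFP per microstate class.

    A microstate event is a maximal run of identically-labelled samples;
    with the halfway-boundary convention (events begin and end midway
    between the last sample of one run and the first of the next, and at
    the half-sample edges of the recording) an L-sample run lasts L/fs
    seconds exactly.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    lab = labels.labels
    assigned = lab != UNASSIGNED
    if not np.any(assigned):
        raise ValueError("no assigned samples")
    k = labels.n_classes
    runs = _runs(lab)
    n_runs = np.zeros(k)
    run_samples = np.zeros(k)
    for cls, length in runs:
        n_runs[cls] += 1
        run_samples[cls] += length
    total_time = assigned.sum() / fs
    with np.errstate(invalid="ignore", divide="ignore"):
        duration = np.where(n_runs > 0, run_samples / np.maximum(n_runs, 1) / fs,
                            0.0)
    occurrence = n_runs / total_time
    coverage = run_samples / assigned.sum()
    gfp_mean = np.array([
        gfp.values[lab == cls].mean() if np.any(lab == cls) else 0.0
        for cls in range(k)
    ])
    return MicrostateStats(gfp_mean, duration, occurrence, coverage,
                           n_runs, total_time)


# ---------------------------------------------------------------------------
# Transitions

@dataclass
class TransitionAnalysis:
    """Observed vs occurrence-expected transition structure.

    ``observed`` is the row-stochastic run-to-run transition matrix (zero
    diagonal by construction).  ``expected`` follows the occurrence null
    ExpTM(k1,k2) = (Occ(k1)/MeanOcc * Occ(k2)/MeanOcc) / (1 - Occ(k1)/MeanOcc);
    it is +inf where Occ(k1) equals MeanOcc (degenerate denominator) and
    negative where Occ(k1) exceeds the mean.  ``expected_normalized`` is
    the row-stochastic form of that null — off-diagonal entries of a row
    are proportional to Occ(k2), i.e. Occ(k2) / (sum Occ - Occ(k1)) —
    which is what row-normalising ExpTM yields wherever ExpTM is regular,
    and which stays well-defined at its singular points.  ``difference``
    is observed minus the normalised null.
    """

    observed: np.ndarray
    expected: np.ndarray
    expected_normalized: np.ndarray
    difference: np.ndarray
    occurrence: np.ndarray


def expected_transitions(occurrence: np.ndarray) -> np.ndarray:
    """Occurrence-based expected transition matrix.

    ExpTM(k1, k2) = (Occ(k1)/MeanOcc * Occ(k2)/MeanOcc) / (1 - Occ(k1)/MeanOcc).
    A class with zero occurrence yields an all-zero row; a class whose
    occurrence equals the mean makes the denominator vanish, in which case
    the row is +inf (sentinel) and a warning is emitted.
    """
    occ = np.asarray(occurrence, float)
    k = occ.size
    rel = occ / occ.mean()
    expected = np.empty((k, k))
    for k1 in range(k):
        if occ[k1] == 0:
            expected[k1] = 0.0
            continue
        denom = 1.0 - rel[k1]
        if abs(denom) < 1e-12:
            warnings.warn(
                f"ExpTM degenerate for class {k1}: Occ equals MeanOcc",
                RuntimeWarning, stacklevel=2,
            )
            expected[k1] = np.inf
            continue
        expected[k1] = rel[k1] * rel / denom
    return expected


def transition_analysis(labels: LabelSequence, fs: float) -> TransitionAnalysis:
    """Observed and occurrence-expected microstate transition matrices."""
    runs = _runs(labels.labels)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a transition analysis")
    k = labels.n_classes
    counts = np.zeros((k, k))
    seq = [cls for cls, _ in runs]
    for a, b in zip(seq[:-1], seq[1:]):
        counts[a, b] += 1
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(rowsum > 0, counts / np.maximum(rowsum, 1), 0.0)

    assigned = labels.labels != UNASSIGNED
    total_time = assigned.sum() / fs
    occ = np.bincount([c for c, _ in runs], minlength=k) / total_time
    expected = expected_transitions(occ)
    exp_norm = np.zeros((k, k))
    for k1 in range(k):
        rest = occ.sum() - occ[k1]
        if occ[k1] == 0 or rest <= 0:
            continue
        exp_norm[k1] = occ / rest
        exp_norm[k1, k1] = 0.0
    difference = observed - exp_norm
    return TransitionAnalysis(observed, expected, exp_norm, difference, occ)
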