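"""Choosing the number of microstate classes.

Candidate cluster counts (typically 2-10) are scored with several
criteria on the polarity-invariant distance d(u, v) = 1 - |r(u, v)|,
where r is the spatial Pearson correlation:

* within-cluster dispersion W(K) and the Krzanowski-Lai (KL) elbow
  criterion built from it (the preferred criterion here, being largely
  insensitive to electrode count);
* a predictive cross-validation (CV) criterion penalised by channel count;
* Davies-Bouldin, Dunn and Frey-Van Groenewoud indices;
* a metacriterion that takes the median vote of the individual optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Recording
from .microstates import MicrostateModel, compute_gfp

__all__ = [
    "CriterionTable",
    "cluster_dispersion",
    "kl_criterion",
    "cv_criterion",
    "auxiliary_criteria",
    "metacriterion_select",
    "score_models",
]


@dataclass
class CriterionTable:
    """Per-criterion scores over candidate K and each criterion's optimum."""

    k_values: np.ndarray
    scores: dict[str, np.ndarray]
    chosen_k: dict[str, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=pd.Index(self.k_values, name="K"))


def _normalized(peak_maps: np.ndarray) -> np.ndarray:
    x = np.asarray(peak_maps, float)
    x = x - x.mean(axis=1, keepdims=True)
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def _distance_matrix(peak_maps: np.ndarray) -> np.ndarray:
    """Pairwise polarity-invariant distances 1 - |r| between peak maps."""
    xn = _normalized(peak_maps)
    return np.clip(1.0 - np.abs(xn @ xn.T), 0.0, 1.0)


def cluster_dispersion(peak_maps: np.ndarray, assignments: np.ndarray,
                       dist: np.ndarray | None = None,
                       n_clusters: int | None = None) -> float:
    """Within-cluster dispersion W.

    Sum over clusters of (cluster size) x (mean pairwise squared
    polarity-invariant distance among members).  Singletons contribute
    zero; W therefore vanishes when every point is its own cluster and is
    non-increasing in K on nested agglomerative solutions.  When
    ``n_clusters`` is given, all labels 0..n_clusters-1 must occur.
    """
    assignments = np.asarray(assignments)
    if dist is None:
        dist = _distance_matrix(peak_maps)
    present = np.unique(assignments)
    if n_clusters is not None and present.size != n_clusters:
        missing = sorted(set(range(n_clusters)) - set(present.tolist()))
        raise ValueError(f"empty cluster(s): {missing}")
    w = 0.0
    for cls in present:
        idx = np.nonzero(assignments == cls)[0]
        n = idx.size
        if n < 2:
            continue
        sub = dist[np.ix_(idx, idx)]
        mean_sq = (sub**2).sum() / (n * (n - 1))  # off-diagonal mean
        w += n * mean_sq
    return float(w)


def kl_criterion(w: dict[int, float] | np.ndarray, n_channels: int,
                 k_values: np.ndarray | None = None
                 ) -> tuple[dict[int, float], int]:
    """Krzanowski-Lai scores and their argmax.

    DIFF(K) = (K-1)^(2/m) W(K-1) - K^(2/m) W(K) with m the channel count;
    KL(K) = |DIFF(K)| / |DIFF(K+1)|.  Defined only for interior K (both
    neighbours needed), so the endpoints of the candidate range can never
    be selected.
    """
    if isinstance(w, dict):
        k_values = np.array(sorted(w))
        w_arr = np.array([w[k] for k in k_values], float)
    else:
        w_arr = np.asarray(w, float)
        if k_values is None:
            raise ValueError("k_values required when w is an array")
        k_values = np.asarray(k_values)
    if not np.all(np.diff(k_values) == 1):
        raise ValueError("K range must be contiguous")
    if k_values.size < 3:
        raise ValueError("KL needs at least three consecutive K values")
    e = 2.0 / n_channels
    diff = (k_values[:-1]**e) * w_arr[:-1] - (k_values[1:]**e) * w_arr[1:]
    # diff[j] corresponds to K = k_values[j + 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        kl = np.abs(diff[:-1]) / np.abs(diff[1:])
    scores = {int(k_values[j + 1]): float(kl[j]) for j in range(kl.size)}
    finite = {k: v for k, v in scores.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("KL undefined everywhere (flat dispersion curve)")
    best = max(sorted(finite), key=lambda k: finite[k])
    return scores, int(best)


def cv_criterion(rec: Recording, models: dict[int, MicrostateModel],
                 scope: str = "peaks") -> tuple[dict[int, float], int]:
    """Predictive-residual cross-validation criterion; lower is better.

    CV(K) = sigma2_K * ((C-1)/(C-1-K))^2 where sigma2_K is the mean
    variance left unexplained after projecting each sample on its
    best-correlated template.
    """
    c = rec.n_channels
    gfp = compute_gfp(rec, find_peaks=(scope == "peaks"))
    idx = gfp.peak_indices if scope == "peaks" else np.arange(len(gfp))
    x = rec.data[:, idx] - rec.data[:, idx].mean(axis=0, keepdims=True)
    scores: dict[int, float] = {}
    for k, model in models.items():
        if k >= c - 1:
            raise ValueError(f"CV undefined for K={k} >= C-1={c - 1}")
        maps = _normalized(model.maps)
        proj = np.abs(maps @ x)            # (K, N) |a_k . x_i|
        best = proj.max(axis=0)
        resid = max(np.sum(x**2) - np.sum(best**2), 0.0)
        sigma2 = resid / (x.shape[1] * (c - 1))
        scores[k] = float(sigma2 * ((c - 1) / (c - 1 - k))**2)
    best_k = min(sorted(scores), key=lambda k: scores[k])
    return scores, int(best_k)


def auxiliary_criteria(peak_maps: np.ndarray,
                       assignments: dict[int, np.ndarray]
                       ) -> dict[str, tuple[dict[int, float], int]]:
    """Davies-Bouldin, Dunn and Frey-Van Groenewoud indices per K.

    All use d = 1 - |r|.  DB is minimised, Dunn maximised, and FVG — the
    ratio of successive changes in mean between- and within-cluster
    distance — is best where closest to 1.
    """
    dist = _distance_matrix(peak_maps)
    xn = _normalized(peak_maps)
    db: dict[int, float] = {}
    dunn: dict[int, float] = {}
    s_between: dict[int, float] = {}
    s_within: dict[int, float] = {}
    for k in sorted(assignments):
        a = np.asarray(assignments[k])
        classes = np.unique(a)
        if classes.size < 2:
            continue
        groups = [np.nonzero(a == cls)[0] for cls in classes]
        # centroid = polarity-invariant dominant component of members
        cents = []
        for idx in groups:
            s = xn[idx].T @ xn[idx]
            w_, v_ = np.linalg.eigh(s)
            cents.append(v_[:, -1])
        cents = np.array(cents)
        cd = np.clip(1 - np.abs(cents @ cents.T), 0, 1)
        spread = np.array([
            np.mean(np.clip(1 - np.abs(xn[idx] @ cents[i]), 0, 1))
            for i, idx in enumerate(groups)
        ])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (spread[:, None] + spread[None, :]) / cd
        np.fill_diagonal(r, -np.inf)
        db[k] = float(np.mean(np.max(r, axis=1)))

        diam = max((dist[np.ix_(i, i)].max() if i.size > 1 else 0.0)
                   for i in groups)
        min_between = min(dist[np.ix_(gi, gj)].min()
                          for ii, gi in enumerate(groups)
                          for gj in groups[ii + 1:])
        if diam <= 0:
            raise ValueError("Dunn undefined: all clusters are singletons")
        dunn[k] = float(min_between / diam)

        within_mask = a[:, None] == a[None, :]
        np.fill_diagonal(within_mask, False)
        between_mask = ~(a[:, None] == a[None, :])
        s_within[k] = float(dist[within_mask].mean()) if within_mask.any() else 0.0
        s_between[k] = float(dist[between_mask].mean())

    fvg: dict[int, float] = {}
    ks = sorted(s_within)
    for k in ks:
        if k + 1 not in s_within:
            continue
        dw = s_within[k + 1] - s_within[k]
        if abs(dw) < 1e-15:
            continue
        fvg[k] = float((s_between[k + 1] - s_between[k]) / dw)

    out: dict[str, tuple[dict[int, float], int]] = {}
    if db:
        out["davies_bouldin"] = (db, int(min(sorted(db), key=lambda k: db[k])))
    if dunn:
        out["dunn"] = (dunn, int(max(sorted(dunn), key=lambda k: dunn[k])))
    if fvg:
        out["frey_van_groenewoud"] = (
            fvg, int(min(sorted(fvg), key=lambda k: abs(fvg[k] - 1))))
    return out


def metacriterion_select(votes: dict[str, int] | CriterionTable) -> int:
    """Median of the per-criterion optima; ties resolve to the smaller K."""
    if isinstance(votes, CriterionTable):
        votes = votes.chosen_k
    vals = sorted(votes.values())
    if not vals:
        raise ValueError("no criteria to combine")
    return int(vals[(len(vals) - 1) // 2])


def score_models(peak_maps: np.ndarray, gfp_at_peaks: np.ndarray,
                 models: dict[int, MicrostateModel],
                 rec: Recording | None = None,
                 k_min: int = 2, k_max: int = 10) -> CriterionTable:
    """Build the full criterion table for AAHC models over a K range.

    Dispersion W(K) is reported directly alongside the criteria derived
    from it; a model at K = k_min - 1 (typically 1) improves the KL
    endpoint handling when present in ``models``.
    """
    assignments = {k: m.training_assignments for k, m in models.items()
                   if m.training_assignments is not None}
    dist = _distance_matrix(peak_maps)
    w_all = {k: cluster_dispersion(peak_maps, a, dist)
             for k, a in assignments.items()}
    kl_scores, kl_best = kl_criterion(w_all, peak_maps.shape[1])

    k_values = np.array([k for k in sorted(models) if k_min <= k <= k_max])
    scores: dict[str, np.ndarray] = {}
    chosen: dict[str, int] = {}

    def col(d: dict[int, float]) -> np.ndarray:
        return np.array([d.get(int(k), np.nan) for k in k_values])

    scores["dispersion"] = col(w_all)
    scores["kl"] = col(kl_scores)
    chosen["kl"] = kl_best

    if rec is not None:
        cv_scores, cv_best = cv_criterion(
            rec, {k: models[k] for k in k_values if k < rec.n_channels - 1})
        scores["cv"] = col(cv_scores)
        chosen["cv"] = cv_best

    aux = auxiliary_criteria(
        peak_maps, {int(k): assignments[int(k)] for k in k_values})
    for name, (sc, best) in aux.items():
        scores[name] = col(sc)
        chosen[name] = best

    return CriterionTable(k_values, scores, chosen)
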