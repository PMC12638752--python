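"""Associating microstate time courses with source-space band power.

For each source, the band-limited power (BLP) envelope — the magnitude of
the analytic signal after a two-pass order-3 Butterworth band-pass — is
regressed on a continuous microstate regressor B_k(t) = |x_t . map_k|
with global field power (GFP) and global map dissimilarity (GMD) as
nuisance terms:

    BLP = b0 + b1 B_k + b2 GFP + b3 GMD + e

Group inference on b1 uses sign-flip Monte Carlo permutations with
threshold-free cluster enhancement (TFCE) over the source neighbourhood
graph and a max-statistic family-wise correction (two-sided, alpha 0.001
by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, hilbert
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Recording
from .microstates import MicrostateModel

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "RegressorSet",
    "GlmResult",
    "StatMap",
    "band_envelope",
    "compute_gmd",
    "build_regressors",
    "fit_source_glm",
    "tfce_enhance",
    "group_permutation_test",
    "summarize_statmaps",
    "pca_orientation",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; ``lo``/``hi`` in Hz, None for broadband."""

    name: str
    lo: float | None
    hi: float | None

    def __post_init__(self) -> None:
        if self.lo is not None and not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band edges ({self.lo}, {self.hi})")


DEFAULT_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 2.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 20.0),
    "broadband": BandDefinition("broadband", None, None),
}


def band_envelope(series: np.ndarray, band: BandDefinition | str,
                  fs: float) -> np.ndarray:
    """Band-limited power envelope of one or more time series.

    Two-pass order-3 Butterworth band-pass followed by the magnitude of
    the analytic (Hilbert) signal; the broadband band skips filtering.
    Accepts shape (T,) or (S, T); filtering runs along the last axis.
    """
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    x = np.asarray(series, float)
    if band.lo is not None:
        if band.hi >= fs / 2:
            raise ValueError(f"band {band.name} exceeds Nyquist ({fs / 2} Hz)")
        b, a = butter(3, [band.lo, band.hi], btype="bandpass", fs=fs)
        x = filtfilt(b, a, x, axis=-1)
    return np.abs(hilbert(x, axis=-1))


def compute_gmd(rec: Recording) -> np.ndarray:
    """Global map dissimilarity between consecutive samples.

    Each topography is normalised to unit GFP; GMD(t) is the RMS channel
    difference between the normalised maps at t and t-1, ranging from 0
    (identical shape) to 2 (same shape, opposite polarity).  GMD(0) is 0
    and pairs involving a zero-GFP sample are NaN (undefined).
    """
    x = rec.data - rec.data.mean(axis=0, keepdims=True)
    gfp = x.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = x / gfp[None, :]
    gmd = np.zeros(rec.n_samples)
    d = u[:, 1:] - u[:, :-1]
    gmd[1:] = np.sqrt(np.mean(d**2, axis=0))
    bad = (gfp[1:] == 0) | (gfp[:-1] == 0)
    gmd[1:][bad] = np.nan
    return gmd


@dataclass
class RegressorSet:
    """Per-sample design variables for the source GLM.

    ``b`` has shape (K, T): the non-negative continuous microstate
    regressors |x_t . map_k|; ``gfp`` and ``gmd`` are the nuisance series.
    """

    b: np.ndarray
    gfp: np.ndarray
    gmd: np.ndarray
    standardized: bool = False

    def design_matrix(self, k: int) -> np.ndarray:
        """(T, 4) design [intercept, B_k, GFP, GMD] for microstate ``k``."""
        cols = [np.ones_like(self.gfp), self.b[k], self.gfp,
                np.nan_to_num(self.gmd)]
        x = np.column_stack(cols)
        if self.standardized:
            sd = x[:, 1:].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x[:, 1:] = (x[:, 1:] - x[:, 1:].mean(axis=0)) / sd
        return x


def build_regressors(rec: Recording, model: MicrostateModel,
                     standardize: bool = False) -> RegressorSet:
    """Continuous microstate regressors plus GFP and GMD nuisances.

    B_k(t) is the absolute inner product of the (average-referenced)
    sample with unit-norm template k, so it tracks how strongly — with
    either polarity — the template is expressed at each moment.
    """
    if rec.n_channels != model.n_channels:
        raise ValueError("channel count mismatch")
    x = rec.data - rec.data.mean(axis=0, keepdims=True)
    maps = model.maps - model.maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    b = np.abs(maps @ x)
    gfp = x.std(axis=0, ddof=0)
    return RegressorSet(b, gfp, compute_gmd(rec), standardized=standardize)


@dataclass
class GlmResult:
    """OLS coefficients per source; ``beta[j]`` is coefficient j (0..3)."""

    beta: np.ndarray  # (4, S)

    @property
    def beta1(self) -> np.ndarray:
        return self.beta[1]


def fit_source_glm(blp: np.ndarray, regs: RegressorSet, k: int) -> GlmResult:
    """Fit BLP = b0 + b1 B_k + b2 GFP + b3 GMD per source by OLS.

    ``blp`` is (S, T) or (T,).  A rank-deficient design yields NaN
    coefficients and a warning.
    """
    y = np.atleast_2d(np.asarray(blp, float))
    x = regs.design_matrix(k)
    if y.shape[1] != x.shape[0]:
        raise ValueError("BLP length does not match the regressors")
    if y.shape[1] < x.shape[1] + 5:
        raise ValueError("need at least 5 more samples than parameters")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("rank-deficient design: coefficients undefined",
                      RuntimeWarning, stacklevel=2)
        return GlmResult(np.full((x.shape[1], y.shape[0]), np.nan))
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return GlmResult(beta)


# ---------------------------------------------------------------------------
# TFCE and group inference

def _adjacency(graph, n: int) -> csr_matrix:
    """Symmetric sparse adjacency from a networkx graph / matrix / edges."""
    import networkx as nx

    if isinstance(graph, nx.Graph):
        a = nx.to_scipy_sparse_array(graph, nodelist=range(n), format="csr")
        a = csr_matrix(a)
    else:
        a = csr_matrix(np.asarray(graph) if not hasattr(graph, "tocsr")
                       else graph)
    if a.shape != (n, n):
        raise ValueError("graph size does not match the statistic map")
    if (abs(a - a.T)).nnz:
        raise ValueError("neighbourhood graph must be symmetric")
    a = a.copy()
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def _tfce_one_sided(v: np.ndarray, adj: csr_matrix, e_exp: float,
                    h_exp: float, n_steps: int) -> np.ndarray:
    out = np.zeros_like(v)
    vmax = v.max(initial=0.0)
    if vmax <= 0:
        return out
    n = v.size
    coo = adj.tocoo()
    eu, ev = coo.row, coo.col
    dh = vmax / n_steps
    prev_count = -1
    idx = labels = sizes = None
    for j in range(n_steps):
        h = (j + 0.5) * dh  # midpoint rule
        mask = v >= h
        count = int(mask.sum())
        if count == 0:
            break
        if count != prev_count:
            # active set changed: rebuild supra-threshold subgraph
            sel = mask[eu] & mask[ev]
            sub = csr_matrix((np.ones(sel.sum()), (eu[sel], ev[sel])),
                             shape=(n, n))
            _, labels = connected_components(sub, directed=False)
            idx = np.nonzero(mask)[0]
            sizes = np.bincount(labels[idx], minlength=labels.max() + 1)
            prev_count = count
        out[idx] += sizes[labels[idx]] ** e_exp * h**h_exp * dh
    return out


def tfce_enhance(stat: np.ndarray, graph, e_exp: float = 0.5,
                 h_exp: float = 2.0, n_steps: int = 100) -> np.ndarray:
    """Threshold-free cluster enhancement over a neighbourhood graph.

    Each node's statistic is replaced by the integral, over thresholds h
    up to its height, of (extent of its supra-threshold connected
    component)^E x h^H dh, approximated with ``n_steps`` midpoint slices.
    Negative values are enhanced on the negated map, giving a signed,
    two-sided enhancement.
    """
    v = np.asarray(stat, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("statistic map must be finite")
    adj = _adjacency(graph, v.size)
    pos = _tfce_one_sided(np.maximum(v, 0), adj, e_exp, h_exp, n_steps)
    neg = _tfce_one_sided(np.maximum(-v, 0), adj, e_exp, h_exp, n_steps)
    return pos - neg


@dataclass
class StatMap:
    """Group β1 map with its TFCE enhancement and corrected significance."""

    beta1: np.ndarray          # group mean coefficient per source
    tstat: np.ndarray
    enhanced: np.ndarray       # signed TFCE values
    p_corrected: np.ndarray
    signif_mask: np.ndarray
    alpha: float
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def cluster_size_fraction(self) -> float:
        """Fraction of sources surviving the corrected threshold."""
        return float(self.signif_mask.mean())


def group_permutation_test(beta1: np.ndarray, graph, alpha: float = 0.001,
                           n_perm: int = 1000, seed: int = 0,
                           e_exp: float = 0.5, h_exp: float = 2.0,
                           n_steps: int = 100) -> StatMap:
    """Sign-flip permutation test of H0: group β1 = 0, TFCE-corrected.

    ``beta1`` is (n_subjects, n_sources).  The observed one-sample t map
    is TFCE-enhanced; under each of ``n_perm`` random subject sign flips
    the maximum absolute enhanced value forms the null distribution, and
    each source's corrected p is the exceedance fraction (two-sided,
    max-statistic family-wise control).
    """
    b = np.asarray(beta1, float)
    if b.ndim != 2 or b.shape[0] < 6:
        raise ValueError("need beta1 as (n_subjects >= 6, n_sources)")
    n_subj, n_src = b.shape
    adj = _adjacency(graph, n_src)
    rng = np.random.default_rng(seed)

    def tmap(x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=0)
        se = x.std(axis=0, ddof=1) / np.sqrt(n_subj)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, m / np.maximum(se, 1e-300), 0.0)
        return t

    def enhance(t: np.ndarray) -> np.ndarray:
        pos = _tfce_one_sided(np.maximum(t, 0), adj, e_exp, h_exp, n_steps)
        neg = _tfce_one_sided(np.maximum(-t, 0), adj, e_exp, h_exp, n_steps)
        return pos - neg

    t_obs = tmap(b)
    enh_obs = enhance(t_obs)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        enh = enhance(tmap(b * flips[:, None]))
        null_max[i] = np.abs(enh).max()
    exceed = (null_max[None, :] >= np.abs(enh_obs)[:, None]).sum(axis=1)
    p_corr = (1 + exceed) / (n_perm + 1)
    mask = p_corr <= alpha
    return StatMap(b.mean(axis=0), t_obs, enh_obs, p_corr, mask, alpha,
                   null_max)


def summarize_statmaps(maps: dict, min_support: int = 2):
    """Cluster-size fractions and the inter-map correlation matrix.

    ``maps`` is keyed by (microstate, band) (or any hashable label).  For
    every map the fraction of significant sources is reported; maps with
    no significant source are omitted from the correlation matrix, whose
    entries are Pearson correlations of the mask-weighted t maps computed
    on the union of the two supports.  Tuple keys appear in the matrix as
    "microstate/band" labels.
    """
    import pandas as pd

    if not maps:
        raise ValueError("no statistical maps supplied")
    n_src = {m.beta1.size for m in maps.values()}
    if len(n_src) != 1:
        raise ValueError("maps must share one source space")
    fractions = {key: m.cluster_size_fraction for key, m in maps.items()}
    keys = [key for key, m in maps.items() if m.signif_mask.any()]
    mat = np.full((len(keys), len(keys)), np.nan)
    for i, ki in enumerate(keys):
        mi = maps[ki]
        vi = mi.tstat * mi.signif_mask
        for j in range(i, len(keys)):
            mj = maps[keys[j]]
            support = np.nonzero(mi.signif_mask | mj.signif_mask)[0]
            if support.size < min_support:
                continue
            a = vi[support]
            c = (mj.tstat * mj.signif_mask)[support]
            if a.std() == 0 or c.std() == 0:
                continue
            mat[i, j] = mat[j, i] = float(np.corrcoef(a, c)[0, 1])
    labels = ["/".join(map(str, k)) if isinstance(k, tuple) else k
              for k in keys]
    corr = pd.DataFrame(mat, index=labels, columns=labels)
    return fractions, corr


def pca_orientation(series: np.ndarray) -> np.ndarray:
    """Project three-orientation source series onto their first principal
    component.

    ``series`` is (3, T) for one source or (S, 3, T); the output drops the
    orientation axis.  Intended for users bringing their own inverse
    solutions, which estimate one time series per orthogonal dipole
    direction.
    """
    x = np.asarray(series, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1] != 3:
        raise ValueError("expected 3 orientation series per source")
    out = np.empty((x.shape[0], x.shape[2]))
    for s in range(x.shape[0]):
        xc = x[s] - x[s].mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(xc.T, full_matrices=False)
        comp = vt[0]
        if comp[np.argmax(np.abs(comp))] < 0:
            comp = -comp
        out[s] = comp @ xc
    return out[0] if single else out
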