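"""Vertex-wise anatomo-behavioral correlation with cluster correction.

At each surface vertex a simple linear model relates the sampled white
matter metric to a behavioral score across subjects; the slope test is
equivalent to the Pearson correlation r with t = r sqrt(df / (1 - r^2)),
df = n - 2.  Multiple comparisons are handled at the cluster level:
supra-threshold vertices (p below the cluster-forming threshold) are
grouped into edge-connected components and the null distribution of the
maximum cluster extent is built by permuting the behavior vector, which
is exact under subject exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["VertexStatsResult", "ROISummary", "vertexwise_correlation",
           "critical_r", "cluster_correction", "roi_aggregate"]


@dataclass
class VertexStatsResult:
    """Per-vertex correlation maps and (optionally) corrected clusters."""

    r_map: np.ndarray            # (V,) Pearson r, NaN where undefined
    r2_map: np.ndarray           # r squared
    p_map: np.ndarray            # two-tailed p from the t transform
    df: np.ndarray               # per-vertex degrees of freedom (n - 2)
    depth_mm: float = np.nan
    clusters: list = field(default_factory=list)
    # each cluster: dict(vertices=array, size=int, p_cluster=float)
    n_zero_variance: int = 0

    def significant_vertices(self, alpha_cluster: float) -> np.ndarray:
        """Union of vertices in clusters with p_cluster < alpha_cluster."""
        out = np.zeros(len(self.r_map), bool)
        for c in self.clusters:
            if c["p_cluster"] < alpha_cluster:
                out[c["vertices"]] = True
        return out


@dataclass
class ROISummary:
    """Per-ROI share of significant vertices and their mean correlation."""

    rois: dict  # {roi_id: {"fraction": f, "mean_r": r, "n_vertices": n}}


def _corr_with_na(Y: np.ndarray, b: np.ndarray, min_n: int = 4):
    """Columnwise Pearson r of Y (n x V, may contain NaN) with b (n,)."""
    n, V = Y.shape
    ok = ~np.isnan(Y)
    n_c = ok.sum(axis=0)
    bm = np.where(ok, b[:, None], np.nan)
    Ym = np.where(ok, Y, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.nanmean(Ym, axis=0)
        bbar = np.nanmean(bm, axis=0)
        yc = Ym - ybar
        bc = bm - bbar
        num = np.nansum(yc * bc, axis=0)
        den = np.sqrt(np.nansum(yc**2, axis=0) * np.nansum(bc**2, axis=0))
        r = num / den
    zero_var = np.nansum(yc**2, axis=0) <= 0
    r[zero_var | (n_c < min_n)] = np.nan
    return r, n_c, int(np.count_nonzero(zero_var & (n_c >= min_n)))


def vertexwise_correlation(samples: np.ndarray, behavior: np.ndarray,
                           depth_mm: float = np.nan) -> VertexStatsResult:
    """Pearson r between per-subject vertex values and a behavioral score.

    ``samples``: (subjects x vertices) array at one depth and metric, NaN
    for missing; ``behavior``: per-subject scalar.  Vertices with fewer
    than 4 complete subjects or zero variance are returned missing.
    """
    samples = np.asarray(samples, float)
    behavior = np.asarray(behavior, float)
    if samples.ndim != 2 or len(behavior) != samples.shape[0]:
        raise ValueError("samples must be subjects x vertices, matching behavior")
    if samples.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    r, n_c, n_zero = _corr_with_na(samples, behavior)
    df = np.maximum(n_c - 2, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    return VertexStatsResult(r_map=r, r2_map=r**2, p_map=p, df=df,
                             depth_mm=depth_mm, n_zero_variance=n_zero)


def critical_r(df: int, alpha: float) -> float:
    """Smallest |r| reaching two-tailed p <= alpha at the given df.

    Inverts p(r) = 2 P(T_df > r sqrt(df / (1 - r^2))) by bisection.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1:
        return 0.0

    def pval(r):
        t = r * np.sqrt(df / (1.0 - r**2))
        return 2.0 * stats.t.sf(t, df)

    return float(brentq(lambda r: pval(r) - alpha, 1e-12, 1 - 1e-12,
                        xtol=1e-12))


def _mesh_edges(surface) -> np.ndarray:
    return np.asarray(surface.edges_unique)


def _components(mask: np.ndarray, edges: np.ndarray):
    """Connected components of the True vertices over mesh edges."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    sub = np.full(len(mask), -1)
    sub[idx] = np.arange(len(idx))
    keep = mask[edges[:, 0]] & mask[edges[:, 1]]
    e = edges[keep]
    g = csr_matrix((np.ones(len(e)), (sub[e[:, 0]], sub[e[:, 1]])),
                   shape=(len(idx), len(idx)))
    ncomp, lab = connected_components(g, directed=False)
    return [idx[lab == c] for c in range(ncomp)]


def cluster_correction(
    result: VertexStatsResult,
    surface,
    samples: np.ndarray,
    behavior: np.ndarray,
    p_cft: float = 0.001,
    n_perm: int = 1000,
    alpha_cluster: float = 0.001,
    seed: int = 0,
) -> VertexStatsResult:
    """Max-extent permutation correction of a vertex-wise correlation map.

    Supra-threshold vertices (p < p_cft) form edge-connected clusters; the
    behavior vector is permuted ``n_perm`` times, the full r map is
    recomputed each time, and each observed cluster gets
    p_cluster = (1 + #{null max extent >= observed}) / (1 + n_perm).
    A constant behavior vector yields an empty (valid) result.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    behavior = np.asarray(behavior, float)
    samples = np.asarray(samples, float)
    edges = _mesh_edges(surface)
    if np.nanstd(behavior) == 0:
        result.clusters = []
        return result

    supra = ~np.isnan(result.p_map) & (result.p_map < p_cft)
    comps = _components(supra, edges)

    # vectorized null: permutations of behavior against complete-case data
    rng = np.random.default_rng(seed)
    complete = ~np.isnan(samples).any(axis=1)
    Yc = samples[complete]
    bc = behavior[complete]
    n = len(bc)
    df = n - 2
    Ys = Yc - Yc.mean(axis=0)
    sd = Ys.std(axis=0)
    good = sd > 0
    Ys[:, good] /= sd[good]
    r_crit = critical_r(df, p_cft) if df > 2 else 1.1

    null_max = np.zeros(n_perm, dtype=int)
    B = np.empty((n_perm, n))
    for i in range(n_perm):
        B[i] = bc[rng.permutation(n)]
    B = (B - B.mean(axis=1, keepdims=True))
    B /= B.std(axis=1, keepdims=True)
    R = (B @ Ys) / n  # (n_perm, V); invalid columns are 0
    R[:, ~good] = 0.0
    hits = np.abs(R) > r_crit
    for i in range(n_perm):
        cs = _components(hits[i], edges)
        null_max[i] = max((len(c) for c in cs), default=0)

    clusters = []
    for c in comps:
        size = len(c)
        p_cl = (1.0 + np.count_nonzero(null_max >= size)) / (1.0 + n_perm)
        clusters.append({"vertices": c, "size": size, "p_cluster": float(p_cl)})
    clusters.sort(key=lambda d: d["p_cluster"])
    result.clusters = clusters
    return result


def roi_aggregate(result: VertexStatsResult, roi_labels: np.ndarray,
                  alpha_cluster: float = 0.001) -> ROISummary:
    """Per ROI: fraction of vertices in significant clusters and their mean r."""
    roi_labels = np.asarray(roi_labels)
    sig = result.significant_vertices(alpha_cluster)
    rois = {}
    for roi in np.unique(roi_labels):
        if roi == 0:
            continue
        m = roi_labels == roi
        n_v = int(m.sum())
        s = sig & m
        frac = float(s.sum() / n_v) if n_v else 0.0
        mean_r = float(np.nanmean(result.r_map[s])) if s.any() else np.nan
        rois[int(roi)] = {"fraction": frac, "mean_r": mean_r, "n_vertices": n_v}
    return ROISummary(rois=rois)
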