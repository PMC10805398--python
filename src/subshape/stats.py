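"""Vertex-wise group statistics with permutation-based inference.

Univariate features (RD, TBM) are compared with two-sample pooled
t-tests, multivariate ones (mTBM, MMS) with Hotelling's T^2.  Inference
is purely permutational: the group labels are shuffled as a whole (one
shared shuffle per permutation, preserving the spatial dependence of the
maps), the statistic map is recomputed, and the vertex p-value is the
fraction of permuted statistics at least as extreme as the observed one.

The global, multiple-comparison-corrected significance uses the count
statistic: the "real effect" is the number of vertices with uncorrected
p below alpha; the same count is computed for every permutation against
the permutation distribution itself, and the global p is the fraction of
permutations whose count exceeds the real effect.

Direction maps classify significant vertices as atrophy (reference group
mean larger) or expansion (smaller); correlation maps relate univariate
features to clinical scores by Pearson's r with parametric p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

CHANNELS_BY_KIND = {"RD": 1, "TBM": 1, "mTBM": 3, "MMS": 4}


@dataclass
class CohortFeatures:
    """Stacked per-subject feature maps for one comparison.

    data         : (n_subjects, n_vertices, n_channels)
    labels       : group id per subject; exactly two distinct values,
                   first-seen value = group 1 (the reference, e.g. HC)
    channel_kind : one of RD / TBM / mTBM / MMS
    """

    data: np.ndarray
    labels: np.ndarray
    channel_kind: str

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim == 2:
            self.data = self.data[..., None]
        if self.channel_kind not in CHANNELS_BY_KIND:
            raise ValueError(f"unknown channel kind {self.channel_kind!r}")
        expect = CHANNELS_BY_KIND[self.channel_kind]
        if self.data.shape[2] != expect:
            raise ValueError(
                f"{self.channel_kind} expects {expect} channels, "
                f"got {self.data.shape[2]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("features must be finite")
        groups = list(dict.fromkeys(self.labels.tolist()))
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        self.groups = groups
        self.g1 = self.labels == groups[0]
        self.g2 = self.labels == groups[1]
        if self.g1.sum() < 2 or self.g2.sum() < 2:
            raise ValueError("each group needs n >= 2")

    @property
    def is_univariate(self) -> bool:
        return CHANNELS_BY_KIND[self.channel_kind] == 1


@dataclass
class StatMap:
    statistic: np.ndarray          # per-vertex t or T^2
    p_vertex: np.ndarray           # multiples of 1/n_perm
    sig_mask: np.ndarray
    real_effect: int               # count of significant vertices
    p_global: float
    n_perm: int
    alpha: float
    seed: int
    stat_kind: str                 # 't' or 'hotelling'
    zero_variance_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def p_global_label(self) -> str:
        if self.p_global < 1.0 / self.n_perm:
            return f"<{1.0 / self.n_perm:g}"
        return f"{self.p_global:g}"


@dataclass
class DirectionMap:
    """Per-vertex label: +1 atrophy, -1 expansion, 0 none."""

    labels: np.ndarray
    alpha: float

    CODES = {1: "atrophy", -1: "expansion", 0: "none"}

    def as_strings(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype=object)
        for code, name in self.CODES.items():
            out[self.labels == code] = name
        return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def vertex_t_stat(cohort: CohortFeatures, *, return_flags: bool = False):
    """Two-sample pooled-variance t per vertex (group 1 minus group 2)."""
    if not cohort.is_univariate:
        raise ValueError("t statistic requires a univariate channel")
    X = cohort.data[..., 0]
    t, flags = _t_stat(X[cohort.g1], X[cohort.g2])
    if return_flags:
        return t, flags
    return t


def _t_stat(X1, X2):
    n1, n2 = len(X1), len(X2)
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    ss = ((X1 - m1) ** 2).sum(axis=0) + ((X2 - m2) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    flags = denom <= 0
    t = np.where(flags, 0.0, (m1 - m2) / np.where(flags, 1.0, denom))
    return t, flags


def vertex_hotelling_t2(cohort: CohortFeatures, *, ridge: float = 1e-8,
                        return_flags: bool = False):
    """Hotelling's T^2 per vertex for multivariate channels.

    T^2 = n1 n2 / (n1 + n2) * d^T S_pooled^{-1} d with d the mean
    difference; a ridge of ``ridge * trace(S)/d`` is added when the
    pooled covariance is singular.
    """
    X = cohort.data
    d = X.shape[2]
    n1, n2 = int(cohort.g1.sum()), int(cohort.g2.sum())
    if n1 + n2 - 2 <= d:
        raise ValueError("need n1 + n2 - 2 > n_channels for Hotelling's T^2")
    t2, flags = _hotelling(X[cohort.g1], X[cohort.g2], ridge)
    if return_flags:
        return t2, flags
    return t2


def _hotelling(X1, X2, ridge=1e-8):
    n1, n2 = len(X1), len(X2)
    d = X1.shape[2]
    m1, m2 = X1.mean(axis=0), X2.mean(axis=0)
    diff = m1 - m2                                     # (V, d)
    c1 = np.einsum("svi,svj->vij", X1 - m1, X1 - m1)
    c2 = np.einsum("svi,svj->vij", X2 - m2, X2 - m2)
    S = (c1 + c2) / (n1 + n2 - 2)                      # (V, d, d)
    tr = np.trace(S, axis1=1, axis2=2)
    flags = tr <= 0
    # ridge only where S is (near-)singular, so the regular case stays exact
    detS = np.linalg.det(S)
    singular = flags | (detS <= 1e-12 * np.maximum(tr / d, 1e-300) ** d)
    lam = np.where(singular, ridge * np.where(flags, 1.0, tr) / d, 0.0)
    S = S + lam[:, None, None] * np.eye(d)
    sol = np.linalg.solve(S, diff[..., None])[..., 0]
    t2 = (n1 * n2 / (n1 + n2)) * np.einsum("vd,vd->v", diff, sol)
    t2 = np.where(flags, 0.0, np.maximum(t2, 0.0))
    return t2, flags


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------

def permutation_test(cohort: CohortFeatures, stat_kind: str | None = None,
                     n_perm: int = 10000, alpha: float = 0.05,
                     seed: int = 0, shuffle_hook=None) -> StatMap:
    """Shared-shuffle permutation test with count-based global correction.

    One label shuffle per permutation is applied to all vertices at
    once.  Vertex p = fraction of permuted statistics >= the observed
    one, comparing |t| for t statistics and the raw value for T^2; both
    vertex and global p are exact multiples of 1/n_perm.  For the global
    correction each permutation's statistic map is converted to a p-map
    against the permutation distribution itself (leave-self-in) and the
    count of vertices below alpha compared with the real effect.

    ``shuffle_hook(perm_index, permuted_labels)`` is called for every
    permutation (instrumentation for the shared-shuffle contract).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if stat_kind is None:
        stat_kind = "t" if cohort.is_univariate else "hotelling"
    if stat_kind not in ("t", "hotelling"):
        raise ValueError(f"unknown stat_kind {stat_kind!r}")

    X = cohort.data
    n, V, d = X.shape
    n1 = int(cohort.g1.sum())
    from math import comb, log
    if log(comb(n, n1)) < np.log(n_perm):
        warnings.warn(
            f"n_perm={n_perm} exceeds the {comb(n, n1)} distinct "
            "group splits; proceeding with random sampling")

    if stat_kind == "t":
        obs, zero_var = _t_stat(X[cohort.g1, :, 0], X[cohort.g2, :, 0])
        extremity = np.abs
    else:
        obs, zero_var = _hotelling(X[cohort.g1], X[cohort.g2])
        extremity = lambda s: s

    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, V))
    idx = np.arange(n)
    for b in range(n_perm):
        p = rng.permutation(idx)
        if shuffle_hook is not None:
            shuffle_hook(b, cohort.labels[p])
        i1, i2 = p[:n1], p[n1:]
        if stat_kind == "t":
            s, _ = _t_stat(X[i1, :, 0], X[i2, :, 0])
        else:
            s, _ = _hotelling(X[i1], X[i2])
        perm_stats[b] = extremity(s)

    obs_ext = extremity(obs)
    p_vertex = (perm_stats >= obs_ext[None, :]).sum(axis=0) / n_perm
    sig = p_vertex < alpha
    real_effect = int(sig.sum())

    # leave-self-in p-maps for every permutation, via per-vertex ranks:
    # count of perm values >= x equals n_perm - (# strictly below x)
    order = np.argsort(perm_stats, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_perm)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, (n_perm, V)), axis=0)
    # handle ties: number strictly below = rank of first occurrence
    sorted_stats = np.take_along_axis(perm_stats, order, axis=0)
    strictly_below = np.empty_like(ranks)
    for vcol in range(V):
        strictly_below[:, vcol] = np.searchsorted(
            sorted_stats[:, vcol], perm_stats[:, vcol], side="left")
    p_perm = (n_perm - strictly_below) / n_perm
    counts = (p_perm < alpha).sum(axis=1)
    p_global = float((counts > real_effect).sum() / n_perm)

    return StatMap(
        statistic=obs, p_vertex=p_vertex, sig_mask=sig,
        real_effect=real_effect, p_global=p_global, n_perm=n_perm,
        alpha=alpha, seed=seed, stat_kind=stat_kind,
        zero_variance_mask=zero_var,
        metadata={"groups": [str(g) for g in cohort.groups],
                  "channel_kind": cohort.channel_kind,
                  "two_sided": stat_kind == "t"})


def direction_map(cohort: CohortFeatures, stat_map: StatMap) -> DirectionMap:
    """Atrophy/expansion labels at significant vertices.

    Group 1 is the reference (e.g. healthy controls): a significant
    vertex where mean(group 1) - mean(group 2) > 0 is atrophy of group 2
    relative to the reference, < 0 is expansion.
    """
    if not cohort.is_univariate:
        raise ValueError("direction maps require a univariate channel (RD/TBM)")
    X = cohort.data[..., 0]
    diff = X[cohort.g1].mean(axis=0) - X[cohort.g2].mean(axis=0)
    labels = np.zeros(diff.shape, dtype=int)
    sig = stat_map.sig_mask
    labels[sig & (diff > 0)] = 1
    labels[sig & (diff < 0)] = -1
    ties = sig & (diff == 0)
    if ties.any():
        warnings.warn(f"{int(ties.sum())} significant vertices with exactly "
                      "zero mean difference left unlabelled")
    return DirectionMap(labels=labels, alpha=stat_map.alpha)


def clinical_correlation(feature_maps: np.ndarray, scores: np.ndarray,
                         alpha: float = 0.05):
    """Vertex-wise Pearson correlation with a clinical score.

    feature_maps : (n_subjects, n_vertices) univariate feature values
    scores       : (n_subjects,) one clinical score per subject

    Returns (r_map, p_map, sig_mask) with two-sided parametric p-values
    and an uncorrected alpha threshold.
    """
    X = np.asarray(feature_maps, float)
    y = np.asarray(scores, float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("feature_maps must be (n_subjects, n_vertices)")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if y.std() == 0:
        raise ValueError("constant score vector")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
    ok = denom > 0
    r = np.zeros(X.shape[1])
    r[ok] = (Xc[:, ok] * yc[:, None]).sum(axis=0) / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p = 2.0 * sstats.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p, p < alpha
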