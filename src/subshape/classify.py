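"""Patch-based dimensionality reduction and GentleBoost classification.

The per-vertex MMS maps are far too high-dimensional for direct
classification (15,000 nodes x 4 channels), and single vertices carry
little statistical power, so features are taken in units of square
patches: a fixed random layout of overlapping windows is sampled once
and shared by all subjects.  Patch vectors are sparse-coded against an
over-complete dictionary learned online by Stochastic Coordinate Coding
(SCC: a few coordinate-descent passes on the code, then a stochastic
gradient step on only the active dictionary columns), pooled by 2x2
max pooling with stride 2, and fed to a GentleBoost ensemble of
regression trees.  Performance is assessed by k-fold cross-validation
with accuracy, sensitivity, specificity, PPV and NPV; the dictionary is
re-learned inside each training fold so no information leaks from the
test subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.tree import DecisionTreeRegressor


# ---------------------------------------------------------------------------
# Patch layout and extraction
# ---------------------------------------------------------------------------

@dataclass
class PatchLayout:
    """Random square windows on the grid, identical across subjects.

    windows : list of (u0, v0, side) top-left corner + side, in vertices
    """

    windows: list
    grid_dims: tuple
    periodic_v: bool
    seed: int

    def __len__(self):
        return len(self.windows)


def generate_patches(grid_dims, n_patches: int = 1008, side: int = 30,
                     seed: int = 0, periodic_v: bool = True) -> PatchLayout:
    """Sample ``n_patches`` square windows uniformly over valid corners.

    Windows may overlap; when the grid is periodic in v the window may
    wrap around the seam, so every v corner is valid.
    """
    nu, nv = grid_dims
    if side > nu:
        raise ValueError(f"side {side} exceeds grid extent in u ({nu})")
    if not periodic_v and side > nv:
        raise ValueError(f"side {side} exceeds grid extent in v ({nv})")
    rng = np.random.default_rng(seed)
    u_max = nu - side + 1
    v_max = nv if periodic_v else nv - side + 1
    u0 = rng.integers(0, u_max, size=n_patches)
    v0 = rng.integers(0, v_max, size=n_patches)
    windows = [(int(a), int(b), int(side)) for a, b in zip(u0, v0)]
    return PatchLayout(windows=windows, grid_dims=(nu, nv),
                       periodic_v=periodic_v, seed=seed)


def extract_patch_features(mms_grid: np.ndarray, layout: PatchLayout) -> np.ndarray:
    """Per-patch row vectors: row-major flattened side x side x C blocks.

    ``mms_grid`` is (nu, nv, C); returns (P, side^2 * C).  v indices wrap
    when the layout is periodic.
    """
    arr = np.asarray(mms_grid, float)
    if arr.shape[:2] != tuple(layout.grid_dims):
        raise ValueError(
            f"grid {arr.shape[:2]} does not match layout {layout.grid_dims}")
    nu, nv, C = arr.shape
    rows = []
    for (u0, v0, side) in layout.windows:
        vi = np.arange(v0, v0 + side)
        vi = vi % nv if layout.periodic_v else vi
        block = arr[u0:u0 + side][:, vi]
        rows.append(block.ravel())
    return np.asarray(rows)


def unflatten_patch(row: np.ndarray, side: int, channels: int) -> np.ndarray:
    """Inverse of the row flattening: back to (side, side, channels)."""
    return np.asarray(row).reshape(side, side, channels)


# ---------------------------------------------------------------------------
# Stochastic Coordinate Coding
# ---------------------------------------------------------------------------

@dataclass
class Dictionary:
    """Over-complete sparse-coding dictionary with unit-norm atoms.

    atoms : (m, k) with m the patch dimension, k the number of atoms
    """

    atoms: np.ndarray
    gamma: float
    epochs: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("dictionary columns must be unit norm")

    @property
    def k(self) -> int:
        return self.atoms.shape[1]


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


@njit(cache=True)
def _scc_epoch(X, D, G, Z, counts, order, gamma, cycles):
    """One streaming pass of Stochastic Coordinate Coding (in place).

    Per sample: a few coordinate-descent cycles on the code, a
    stochastic gradient step on the active dictionary columns with
    per-atom decaying rates, renormalization, and a Gram update.
    """
    m, k = D.shape
    for oi in range(order.shape[0]):
        i = order[oi]
        x = X[i]
        Dtx = np.dot(x, D)
        z = Z[i]
        for _ in range(cycles):
            for j in range(k):
                c = Dtx[j] - np.dot(G[j], z) + G[j, j] * z[j]
                if c > gamma:
                    z[j] = c - gamma
                elif c < -gamma:
                    z[j] = c + gamma
                else:
                    z[j] = 0.0
        resid = x - np.dot(D, z)
        any_support = False
        for j in range(k):
            if z[j] != 0.0:
                any_support = True
                eta = z[j] / np.sqrt(counts[j])
                nrm = 0.0
                for t in range(m):
                    D[t, j] += resid[t] * eta
                    nrm += D[t, j] * D[t, j]
                nrm = np.sqrt(nrm)
                if nrm > 1e-12:
                    for t in range(m):
                        D[t, j] /= nrm
                counts[j] += 1.0
        if any_support:
            for j in range(k):
                if z[j] != 0.0:
                    for l in range(k):
                        g = 0.0
                        for t in range(m):
                            g += D[t, j] * D[t, l]
                        G[j, l] = g
                        G[l, j] = g


@njit(cache=True)
def _lasso_cd_kernel(XD, G, xsq, gamma, tol, max_sweeps):
    """Cyclic coordinate descent per row with an active-set speedup.

    Every tenth sweep visits all coordinates (letting atoms enter the
    support); the others only update the current support.  Stops at a
    relative objective decrease below ``tol``, checked after full sweeps.
    """
    P, k = XD.shape
    Z = np.zeros((P, k))
    for p in range(P):
        z = Z[p]
        obj_prev = 0.5 * xsq[p]
        for s in range(max_sweeps):
            full = (s % 10 == 0) or (s == max_sweeps - 1)
            for j in range(k):
                if not full and z[j] == 0.0:
                    continue
                c = XD[p, j] - np.dot(G[j], z) + z[j]
                if c > gamma:
                    z[j] = c - gamma
                elif c < -gamma:
                    z[j] = c + gamma
                else:
                    z[j] = 0.0
            if full:
                # objective: 0.5 x'x - z'XD + 0.5 z'Gz + gamma |z|_1
                quad = 0.0
                lin = 0.0
                l1 = 0.0
                for j in range(k):
                    if z[j] != 0.0:
                        quad += z[j] * np.dot(G[j], z)
                        lin += z[j] * XD[p, j]
                        l1 += abs(z[j])
                obj = 0.5 * xsq[p] - lin + 0.5 * quad + gamma * l1
                if obj_prev - obj <= tol * max(obj_prev, 1e-12):
                    break
                obj_prev = obj
    return Z


def scc_learn(patch_matrix: np.ndarray, k: int = 256, gamma: float = 0.15,
              epochs: int = 10, seed: int = 0, cd_cycles: int = 3,
              holdout_fraction: float = 0.1, init: str = "data") -> Dictionary:
    """Learn a dictionary by Stochastic Coordinate Coding.

    Streams over shuffled samples; per sample (i) a few coordinate-
    descent cycles update the code (warm-started across epochs), (ii) a
    stochastic gradient step updates only the dictionary columns in the
    code's support with per-atom decaying learning rates, (iii) the
    updated columns are renormalized.  The held-out LASSO objective is
    tracked per epoch in the metadata and is non-increasing in practice.
    """
    X = np.asarray(patch_matrix, float)
    P, m = X.shape
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    rng = np.random.default_rng(seed)
    if init == "data" and P >= 1:
        # seed atoms from random samples (standard dictionary-learning
        # practice: keeps initial correlations on the data scale)
        picks = rng.choice(P, size=k, replace=P < k)
        D = X[picks].T + 1e-6 * rng.standard_normal((m, k))
    else:
        D = rng.standard_normal((m, k))
    norms = np.linalg.norm(D, axis=0, keepdims=True)
    D = D / np.where(norms > 1e-12, norms, 1.0)
    if epochs == 0:
        return Dictionary(D, gamma, 0, seed)

    n_hold = max(1, int(holdout_fraction * P)) if P > 10 else 0
    perm0 = rng.permutation(P)
    hold, train = perm0[:n_hold], perm0[n_hold:]
    if len(train) == 0:
        train, hold = perm0, perm0[:0]
    Z = np.zeros((P, k))
    counts = np.ones(k)
    objective_trace = []
    G = D.T @ D
    for _ in range(epochs):
        order = rng.permutation(train).astype(np.int64)
        _scc_epoch(X, D, G, Z, counts, order, float(gamma), cd_cycles)
        if n_hold:
            codes = sparse_encode(X[hold], Dictionary(D, gamma, 0, seed), gamma)
            obj = 0.5 * np.sum((X[hold] - codes @ D.T) ** 2) \
                + gamma * np.abs(codes).sum()
            objective_trace.append(float(obj) / n_hold)
    if np.abs(Z).sum() == 0:
        warnings.warn(
            f"gamma={gamma} zeroed every code; dictionary never updated "
            f"(max |D^T x| = {np.abs(D.T @ X.T).max():.3g})")
    return Dictionary(D, gamma, epochs, seed,
                      metadata={"holdout_objective": objective_trace,
                                "cd_cycles": cd_cycles})


def sparse_encode(patch_matrix: np.ndarray, dictionary: Dictionary,
                  gamma: float | None = None, tol: float = 1e-6,
                  max_sweeps: int = 500) -> np.ndarray:
    """Full coordinate-descent LASSO codes for every patch row.

    Minimizes 0.5||x - Dz||^2 + gamma||z||_1 per row to a relative
    objective tolerance; all rows are updated coordinate-synchronously,
    which keeps the inner loop vectorized over patches.
    """
    X = np.atleast_2d(np.asarray(patch_matrix, float))
    D = dictionary.atoms
    gamma = dictionary.gamma if gamma is None else gamma
    G = np.ascontiguousarray(D.T @ D)
    XD = np.ascontiguousarray(X @ D)
    xsq = np.einsum("pm,pm->p", X, X)
    return _lasso_cd_kernel(XD, G, xsq, float(gamma), float(tol),
                            int(max_sweeps))


# ---------------------------------------------------------------------------
# Pooling and subject vectors
# ---------------------------------------------------------------------------

def max_pool(matrix: np.ndarray, window: int = 2, stride: int = 2) -> np.ndarray:
    """Max pooling over a 2D array; edge windows are truncated."""
    A = np.asarray(matrix)
    if A.ndim != 2:
        raise ValueError("max_pool expects a 2D array")
    r, c = A.shape
    if window > r and window > c:
        warnings.warn("pooling window exceeds input extent; returning input")
        return A.copy()
    out_r = -(-r // stride)
    out_c = -(-c // stride)
    out = np.empty((out_r, out_c), dtype=A.dtype)
    for i in range(out_r):
        for j in range(out_c):
            out[i, j] = A[i * stride:i * stride + window,
                          j * stride:j * stride + window].max()
    return out


def subject_vector(codes: np.ndarray, pooling: str = "patch_matrix") -> np.ndarray:
    """Classifier input vector for one subject's (P, k) code matrix.

    'patch_matrix' : 2x2/stride-2 max pooling over the code matrix,
                     flattened (the default interpretation)
    'global_max'   : per-atom maximum over all patches (k-vector)
    """
    Z = np.asarray(codes)
    if pooling == "patch_matrix":
        return max_pool(Z, 2, 2).ravel()
    if pooling == "global_max":
        return Z.max(axis=0)
    raise ValueError(f"unknown pooling {pooling!r}")


# ---------------------------------------------------------------------------
# GentleBoost
# ---------------------------------------------------------------------------

@dataclass
class BoostModel:
    trees: list
    n_rounds: int
    max_depth: int

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        F = np.zeros(len(X))
        for tree in self.trees:
            F += tree.predict(X)
        return F

    def predict(self, X) -> np.ndarray:
        s = np.sign(self.decision_function(X))
        s[s == 0] = 1
        return s.astype(int)


def gentleboost_train(X, y, n_rounds: int = 100, max_depth: int = 3,
                      seed: int = 0) -> BoostModel:
    """GentleBoost with regression trees as weak learners.

    Each round fits a tree minimizing the weighted squared error
    sum_i w_i (y_i - f(x_i))^2, adds it to the ensemble F, and updates
    w_i <- w_i exp(-y_i f(x_i)) (renormalized) — the gentle, bounded
    variant of the AdaBoost update.  Prediction is sign(F).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be in {-1, +1}")
    if (y == 1).sum() < 1 or (y == -1).sum() < 1:
        raise ValueError("need samples from both classes")
    n = len(y)
    w = np.full(n, 1.0 / n)
    trees = []
    for r in range(n_rounds):
        tree = DecisionTreeRegressor(max_depth=max_depth,
                                     random_state=seed + r)
        tree.fit(X, y, sample_weight=w)
        f = tree.predict(X)
        trees.append(tree)
        w = w * np.exp(-y * f)
        s = w.sum()
        if s <= 0 or not np.isfinite(s):
            break
        w = w / s
    return BoostModel(trees=trees, n_rounds=n_rounds, max_depth=max_depth)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class SubjectDataset:
    """Per-subject patch matrices plus binary labels for one task.

    patch_matrices : (n_subjects, P, m) array (or list of (P, m))
    labels         : (n_subjects,) in {-1, +1}; +1 is the positive class
    """

    patch_matrices: np.ndarray
    labels: np.ndarray
    k: int = 256
    gamma: float = 0.15
    epochs: int = 10
    pooling: str = "patch_matrix"
    n_rounds: int = 100
    max_depth: int = 3


@dataclass
class CVReport:
    confusions: list               # per-fold 2x2 [[TN, FP], [FN, TP]]
    per_fold: dict                 # metric -> list (NaN where undefined)
    means: dict                    # metric -> unweighted mean over defined folds
    fold_assignment: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)


METRICS = ("ACC", "SEN", "SPE", "PPV", "NPV")


def allocate_folds(n: int, k_folds: int, seed: int) -> np.ndarray:
    """Random unstratified allocation into folds of near-equal size."""
    if n < k_folds:
        raise ValueError("need at least one subject per fold")
    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(k_folds), -(-n // k_folds))[:n]
    return base[rng.permutation(n)]


def confusion_metrics(tn, fp, fn, tp) -> dict:
    n = tn + fp + fn + tp

    def safe(num, den):
        return num / den if den > 0 else np.nan

    return {
        "ACC": safe(tp + tn, n),
        "SEN": safe(tp, tp + fn),
        "SPE": safe(tn, tn + fp),
        "PPV": safe(tp, tp + fp),
        "NPV": safe(tn, tn + fn),
    }


def cross_validate(dataset, k_folds: int = 10, seed: int = 0,
                   model_factory=None) -> CVReport:
    """k-fold cross-validation with the five confusion-matrix metrics.

    ``dataset`` is either a :class:`SubjectDataset` (full sparse-coding
    pipeline: the dictionary is learned on the training folds only, then
    train and test subjects are encoded, pooled and boosted) or a plain
    ``(X, y)`` pair of precomputed feature vectors.  ``model_factory``
    overrides the classifier (a callable ``(X, y, seed) -> model`` with
    a ``predict`` method); the default is GentleBoost.

    Folds with a single class in the test set yield NaN for the
    undefined metrics; those folds are excluded from that metric's mean
    with a warning.
    """
    if isinstance(dataset, SubjectDataset):
        y = np.asarray(dataset.labels)
        n = len(y)
    else:
        X, y = dataset
        X = np.asarray(X, float)
        y = np.asarray(y)
        n = len(y)
    folds = allocate_folds(n, k_folds, seed)

    confusions, per_fold = [], {m: [] for m in METRICS}
    for f in range(k_folds):
        test = folds == f
        train = ~test
        if isinstance(dataset, SubjectDataset):
            Xtr, Xte = _pipeline_fold(dataset, train, test, seed + f)
        else:
            Xtr, Xte = X[train], X[test]
        if model_factory is None:
            n_rounds = dataset.n_rounds if isinstance(dataset, SubjectDataset) else 100
            depth = dataset.max_depth if isinstance(dataset, SubjectDataset) else 3
            model = gentleboost_train(Xtr, y[train], n_rounds=n_rounds,
                                      max_depth=depth, seed=seed)
        else:
            model = model_factory(Xtr, y[train], seed)
        pred = model.predict(Xte)
        yt = y[test]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        tn = int(np.sum((pred == -1) & (yt == -1)))
        fp = int(np.sum((pred == 1) & (yt == -1)))
        fn = int(np.sum((pred == -1) & (yt == 1)))
        confusions.append([[tn, fp], [fn, tp]])
        for m, v in confusion_metrics(tn, fp, fn, tp).items():
            per_fold[m].append(v)

    means = {}
    for m in METRICS:
        vals = np.asarray(per_fold[m], float)
        ok = ~np.isnan(vals)
        if not ok.all():
            warnings.warn(f"{m}: {int((~ok).sum())} folds undefined (single-"
                          "class test fold), excluded from the mean")
        means[m] = float(vals[ok].mean()) if ok.any() else np.nan
    config = {}
    if isinstance(dataset, SubjectDataset):
        config = {"k": dataset.k, "gamma": dataset.gamma,
                  "epochs": dataset.epochs, "pooling": dataset.pooling,
                  "n_rounds": dataset.n_rounds, "max_depth": dataset.max_depth}
    return CVReport(confusions=confusions, per_fold=per_fold, means=means,
                    fold_assignment=folds, seed=seed, config=config)


def _pipeline_fold(ds: SubjectDataset, train, test, seed):
    """Dictionary on training patches only; encode + pool train and test.

    Patches are scaled by the median training-patch norm so the sparsity
    weight gamma acts on an O(1) scale; the factor comes from the
    training folds only (no test leakage) and preserves relative
    amplitudes across subjects.
    """
    mats = np.asarray(ds.patch_matrices, float)
    train_patches = mats[train].reshape(-1, mats.shape[2])
    scale = np.median(np.linalg.norm(train_patches, axis=1))
    scale = scale if scale > 1e-12 else 1.0
    dictionary = scc_learn(train_patches / scale, k=ds.k, gamma=ds.gamma,
                           epochs=ds.epochs, seed=seed)

    def encode(idx):
        out = []
        for i in np.flatnonzero(idx):
            codes = sparse_encode(mats[i] / scale, dictionary)
            out.append(subject_vector(codes, ds.pooling))
        return np.asarray(out)

    return encode(train), encode(test)
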