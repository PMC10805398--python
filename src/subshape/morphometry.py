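"""Per-vertex morphometry features: RD, TBM, mTBM and MMS.

Four features per grid node:

* RD (radial distance, mm): distance from the node to the medial axis,
  estimated as the centroid of the node's iso-parametric ring — a
  thickness surrogate sensitive to radial atrophy/expansion.
* TBM: the Jacobian determinant det J of the registration map — local
  area expansion (> 1) or contraction (< 1), a tangential measure.
* mTBM: the Log-Euclidean deformation tensor log(J J^T) vectorized as
  (L11, sqrt(2) L12, L22); the sqrt(2) makes the Euclidean norm of the
  3-vector equal the Frobenius norm of L, so vector distances realize
  the Log-Euclidean metric on tensors.
* MMS: the 4-vector (RD, mTBM) carrying radial and tangential
  information jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registration import DeformationField, warp_scalar_field
from .surface import ConformalGrid


@dataclass
class VertexFeatureSet:
    """Per-node feature maps on the template grid indexing.

    RD (nu, nv) mm; TBM (nu, nv) det J; mTBM (nu, nv, 3); MMS (nu, nv, 4)
    with MMS[..., 0] = RD and MMS[..., 1:] = mTBM exactly.
    """

    RD: np.ndarray
    TBM: np.ndarray
    mTBM: np.ndarray
    MMS: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.TBM <= 0):
            raise ValueError("TBM (det J) must be positive everywhere")
        for name in ("RD", "TBM", "mTBM", "MMS"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")
        if not (np.array_equal(self.MMS[..., 0], self.RD)
                and np.array_equal(self.MMS[..., 1:], self.mTBM)):
            raise ValueError("MMS must be the exact concatenation (RD, mTBM)")

    def channel(self, kind: str) -> np.ndarray:
        """Feature stack for a channel kind, shaped (nu, nv, channels)."""
        if kind == "RD":
            return self.RD[..., None]
        if kind == "TBM":
            return self.TBM[..., None]
        if kind == "mTBM":
            return self.mTBM
        if kind == "MMS":
            return self.MMS
        raise ValueError(f"unknown channel kind {kind!r}")


def radial_distance(grid: ConformalGrid) -> np.ndarray:
    """RD(u, v): distance to the centroid of the iso-parametric ring u.

    On a tube grid the ring centroid lies on the medial axis and the
    ring is perpendicular to it, so the centroid distance measures local
    thickness.  Units mm; translation-invariant by construction.
    """
    pos = grid.positions
    nu, nv = grid.dims
    for i in range(nu):
        if len(np.unique(np.round(pos[i], 9), axis=0)) < 3:
            raise ValueError(f"ring u={i} has < 3 distinct positions")
    ctr = pos.mean(axis=1, keepdims=True)
    return np.linalg.norm(pos - ctr, axis=-1)


def tbm(jacobian: np.ndarray) -> np.ndarray:
    """TBM = det J per node; raises if any determinant is <= 0."""
    J = np.asarray(jacobian, float)
    det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    if np.any(det <= 0):
        raise ValueError(
            f"det J <= 0 at {int(np.sum(det <= 0))} nodes; "
            "registration diffeomorphism invariant violated")
    return det


def mtbm(jacobian: np.ndarray) -> np.ndarray:
    """Log-Euclidean tensor components (L11, sqrt(2) L12, L22).

    L = log(J J^T) computed by eigendecomposition of the SPD 2x2 tensor.
    """
    J = np.asarray(jacobian, float)
    S = np.einsum("...ij,...kj->...ik", J, J)   # J J^T
    w, U = np.linalg.eigh(S)
    if np.any(w <= 0):
        raise ValueError("J J^T not SPD within tolerance")
    logw = np.log(w)
    L = np.einsum("...ij,...j,...kj->...ik", U, logw, U)
    out = np.stack([L[..., 0, 0], np.sqrt(2.0) * L[..., 0, 1], L[..., 1, 1]],
                   axis=-1)
    return out


def mms(RD: np.ndarray, mTBM: np.ndarray) -> np.ndarray:
    """Concatenate RD and mTBM into the per-node 4-vector (RD, mTBM)."""
    RD = np.asarray(RD, float)
    mTBM = np.asarray(mTBM, float)
    if RD.shape != mTBM.shape[:-1] or mTBM.shape[-1] != 3:
        raise ValueError("RD and mTBM shapes disagree")
    return np.concatenate([RD[..., None], mTBM], axis=-1)


def subject_features(subject_grid: ConformalGrid,
                     deformation: DeformationField) -> VertexFeatureSet:
    """Full feature set for one registered subject, template-indexed.

    RD is computed on the subject's own grid and pulled back through the
    registration correspondence (template node x reads the subject at
    x + u(x)); TBM and mTBM come from the registration Jacobian at x.
    """
    rd_subject = radial_distance(subject_grid)
    rd = warp_scalar_field(rd_subject, deformation)
    t = tbm(deformation.jacobian)
    m = mtbm(deformation.jacobian)
    return VertexFeatureSet(RD=rd, TBM=t, mTBM=m, MMS=mms(rd, m),
                            metadata={"indexing": "template-node"})


def features_long_table(feature_set: VertexFeatureSet, subject: str):
    """Long-format (subject, u, v, channel, value) table for stats interop."""
    import pandas as pd

    nu, nv = feature_set.RD.shape
    uu, vv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    frames = []
    for name in ("RD", "TBM"):
        arr = getattr(feature_set, name)
        frames.append(pd.DataFrame({
            "subject": subject, "u": uu.ravel(), "v": vv.ravel(),
            "channel": name, "value": arr.ravel()}))
    for k in range(3):
        frames.append(pd.DataFrame({
            "subject": subject, "u": uu.ravel(), "v": vv.ravel(),
            "channel": f"mTBM{k + 1}", "value": feature_set.mTBM[..., k].ravel()}))
    return pd.concat(frames, ignore_index=True)
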