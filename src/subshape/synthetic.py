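"""Synthetic cohorts of subcortical-like surfaces with known ground truth.

Real inputs to this kind of analysis are segmented hippocampus/amygdala
surfaces in a common spatial frame.  This module emulates their product:
smooth genus-zero tube-like template shapes, per-subject smooth random
shape variation, group-localized radial atrophy or expansion effects of
known magnitude and location, and synthetic cognitive scores correlated
with each subject's realized deformation.  Every quantity the downstream
statistics try to recover (effect masks, true radial offsets, the
score-deformation correlation) is returned as explicit ground truth, so
the whole pipeline can be exercised as a recovery experiment.

Templates are analytic: a ``hippocampus_like`` surface is a tube of
varying elliptical cross-section swept along a C-shaped (banana) arc;
an ``amygdala_like`` surface is a smoothed superellipsoid.  Both come
with their exact parameterization as a :class:`~subshape.surface.ConformalGrid`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import (
    ConformalGrid,
    TriangleMesh,
    conformal_factor_from_positions,
    grid_mean_curvature,
    repair_mesh,
    write_mesh,
)

STRUCTURE_KINDS = ("hippocampus_like", "amygdala_like")


# ---------------------------------------------------------------------------
# Config / truth containers
# ---------------------------------------------------------------------------

@dataclass
class EffectRegion:
    """Rectangular parameter-domain region carrying a radial group effect.

    u_range / v_range : (lo, hi) in the parameter domain, u in [0, 1],
                        v in [0, 2*pi); v ranges may wrap (lo > hi).
    delta             : radial offset magnitude, mm (> 0)
    direction         : 'atrophy' (inward) or 'expansion' (outward)
    edge_fraction     : width of the raised-cosine falloff band at the
                        region edges, as a fraction of the region extent
    """

    u_range: tuple
    v_range: tuple
    delta: float
    direction: str = "atrophy"
    edge_fraction: float = 0.25

    def __post_init__(self):
        if self.direction not in ("atrophy", "expansion"):
            raise ValueError(f"direction must be atrophy|expansion, got {self.direction}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (sign comes from direction)")
        if not (0 <= self.u_range[0] < self.u_range[1] <= 1):
            raise ValueError(f"u_range {self.u_range} outside [0, 1]")

    @property
    def signed_delta(self) -> float:
        return -self.delta if self.direction == "atrophy" else self.delta


@dataclass
class ScoreSpec:
    """One synthetic clinical score: Normal(mean, sd) with Pearson
    correlation ``rho`` to the subject's mean effect-region deformation."""

    name: str
    mean: float = 25.0
    sd: float = 3.0
    rho: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")


@dataclass
class SimulationConfig:
    structure_kind: str = "hippocampus_like"
    n_per_group: dict = field(default_factory=lambda: {"HC": 20, "PD": 20})
    effect_regions: list = field(default_factory=list)
    noise_sd: float = 0.3
    score_specs: list = field(default_factory=list)
    grid_dims: tuple = (100, 150)
    param_jitter_cells: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.structure_kind not in STRUCTURE_KINDS:
            raise ValueError(f"unknown structure_kind {self.structure_kind!r}")
        if len(self.n_per_group) < 1:
            raise ValueError("need at least one group")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2, got {n}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def groups(self) -> list:
        return list(self.n_per_group)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group.values()))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort.

    effect_masks   : list of (nu, nv) boolean arrays, one per region
    true_delta     : (nu, nv) signed radial offset in mm (sum of regions)
    subject_labels : group name per subject, length n_subjects
    subject_scores : DataFrame (subject x score), includes the latent
                     mean effect-region deformation column '_deformation'
    """

    effect_masks: list
    true_delta: np.ndarray
    subject_labels: list
    subject_scores: pd.DataFrame

    @property
    def combined_mask(self) -> np.ndarray:
        if not self.effect_masks:
            return np.zeros_like(self.true_delta, dtype=bool)
        return np.logical_or.reduce(self.effect_masks)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_template_surface(kind: str, grid_dims=(100, 150), seed: int = 0):
    """Analytic template surface: closed genus-0 mesh + exact grid.

    hippocampus_like : elliptical tube swept along a circular (banana)
                       arc, ~40 mm long, radius ~4-6 mm.
    amygdala_like    : smoothed superellipsoid, semi-axes ~(10, 8, 7) mm.

    The ``seed`` adds small deterministic low-order radius undulations so
    each template has curvature texture (needed by intensity-driven
    registration); identical arguments give byte-identical output.
    """
    if kind not in STRUCTURE_KINDS:
        raise ValueError(f"unknown template kind {kind!r}")
    nu, nv = grid_dims
    if nu < 3 or nv < 3:
        raise ValueError(f"degenerate grid dims {grid_dims}")
    rng = np.random.default_rng(seed)
    u = (np.arange(nu) + 0.5) / nu
    v = 2.0 * np.pi * np.arange(nv) / nv
    U, Vv = np.meshgrid(u, v, indexing="ij")

    # deterministic low-order texture, a few percent of the radius
    amp = 0.06
    texture = np.zeros((nu, nv))
    for p in range(1, 4):
        for q in range(0, 4):
            a = rng.normal() * amp / (1 + p + q)
            b = rng.normal() * amp / (1 + p + q)
            texture += a * np.sin(np.pi * p * U) * np.cos(q * Vv)
            texture += b * np.sin(np.pi * p * U) * np.sin(q * Vv)

    if kind == "hippocampus_like":
        pos, pole_a, pole_b = _banana_tube(U, Vv, texture)
    else:
        pos, pole_a, pole_b = _superellipsoid(U, Vv, texture)

    lam = conformal_factor_from_positions(pos, 1.0 / nu, 2.0 * np.pi / nv)
    H = grid_mean_curvature(pos, 1.0 / nu, 2.0 * np.pi / nv)
    grid = ConformalGrid(
        (nu, nv), pos, lam, H, periodic_v=True,
        metadata={"kind": kind, "seed": int(seed), "analytic": True,
                  "u_samples": "cell centers (i + 0.5)/nu"})
    mesh = grid_to_mesh(grid, pole_a, pole_b)
    return mesh, grid


def _banana_tube(U, Vv, texture):
    """Elliptical tube along a circular arc; returns positions + poles."""
    arc_radius = 20.0        # mm, bend of the C
    bend = np.deg2rad(110.0)  # total arc angle
    theta = (U - 0.5) * bend
    # centerline and its frame
    c = np.stack([arc_radius * np.sin(theta),
                  arc_radius * (1 - np.cos(theta)),
                  np.zeros_like(theta)], axis=-1)
    t_hat = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
    n_hat = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    b_hat = np.broadcast_to(np.array([0.0, 0.0, 1.0]), n_hat.shape)
    # radius profile: tapered ends, mild axial variation, elliptical section
    taper = np.sqrt(np.clip(np.sin(np.pi * U), 1e-3, None))
    r0 = 5.0 * taper * (1.0 + 0.15 * np.sin(2 * np.pi * U)) * (1.0 + texture)
    ra, rb = r0 * 1.0, r0 * 0.75
    pos = (c + ra[..., None] * np.cos(Vv)[..., None] * n_hat
           + rb[..., None] * np.sin(Vv)[..., None] * b_hat)
    th0, th1 = (-0.5) * np.deg2rad(110.0), 0.5 * np.deg2rad(110.0)
    pole_a = np.array([20.0 * np.sin(th0), 20.0 * (1 - np.cos(th0)), 0.0])
    pole_b = np.array([20.0 * np.sin(th1), 20.0 * (1 - np.cos(th1)), 0.0])
    return pos, pole_a, pole_b


def _superellipsoid(U, Vv, texture):
    a, b, c = 10.0, 8.0, 7.0
    eps = 0.8   # < 1 -> slightly boxy, still smooth
    theta = np.pi * U           # polar angle from +z
    def spow(x, e):
        return np.sign(x) * np.abs(x) ** e
    st, ct = np.sin(theta), np.cos(theta)
    scale = 1.0 + texture
    x = a * spow(st, eps) * spow(np.cos(Vv), eps) * scale
    y = b * spow(st, eps) * spow(np.sin(Vv), eps) * scale
    z = c * spow(ct, eps) * scale
    pos = np.stack([x, y, z], axis=-1)
    return pos, np.array([0.0, 0.0, c]), np.array([0.0, 0.0, -c])


def grid_to_mesh(grid: ConformalGrid, pole_a, pole_b) -> TriangleMesh:
    """Triangulate a periodic grid into a closed mesh with two pole caps."""
    nu, nv = grid.dims
    V = grid.positions.reshape(-1, 3)
    idx = np.arange(nu * nv).reshape(nu, nv)
    faces = []
    for i in range(nu - 1):
        j = np.arange(nv)
        jn = (j + 1) % nv
        a, b = idx[i, j], idx[i, jn]
        c, d = idx[i + 1, j], idx[i + 1, jn]
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([b, d, c], axis=1))
    F = np.vstack(faces)
    # pole caps: fan from the two apex vertices
    ia, ib = nu * nv, nu * nv + 1
    j = np.arange(nv)
    jn = (j + 1) % nv
    cap_a = np.stack([np.full(nv, ia), idx[0, jn], idx[0, j]], axis=1)
    cap_b = np.stack([np.full(nv, ib), idx[nu - 1, j], idx[nu - 1, jn]], axis=1)
    V = np.vstack([V, pole_a[None, :], pole_b[None, :]])
    mesh = TriangleMesh(V, np.vstack([F, cap_a, cap_b]))
    mesh = repair_mesh(mesh)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def region_weight(region: EffectRegion, dims) -> np.ndarray:
    """Raised-cosine weight of a region over the grid, 1 in the core."""
    nu, nv = dims
    u = (np.arange(nu) + 0.5) / nu
    v = 2.0 * np.pi * np.arange(nv) / nv

    def ramp(x, lo, hi, frac):
        width = (hi - lo) * frac
        w = np.zeros_like(x)
        core = (x >= lo + width) & (x <= hi - width)
        w[core] = 1.0
        rise = (x >= lo) & (x < lo + width)
        w[rise] = 0.5 * (1 - np.cos(np.pi * (x[rise] - lo) / max(width, 1e-12)))
        fall = (x > hi - width) & (x <= hi)
        w[fall] = 0.5 * (1 - np.cos(np.pi * (hi - x[fall]) / max(width, 1e-12)))
        return w

    wu = ramp(u, *region.u_range, region.edge_fraction)
    v0, v1 = region.v_range
    if v0 <= v1:
        wv = ramp(v, v0, v1, region.edge_fraction)
    else:   # wrapped interval
        shift = 2 * np.pi - v0
        wv = ramp((v + shift) % (2 * np.pi), 0.0, (v1 + shift), region.edge_fraction)
    return np.outer(wu, wv)


def smooth_noise_field(dims, rng, n_bands=(8, 8)) -> np.ndarray:
    """Unit-RMS smooth random field: low-order harmonics, periodic in v."""
    nu, nv = dims
    u = (np.arange(nu) + 0.5) / nu
    v = 2.0 * np.pi * np.arange(nv) / nv
    U, Vv = np.meshgrid(u, v, indexing="ij")
    field = np.zeros(dims)
    pu, pv = n_bands
    for p in range(1, pu + 1):
        for q in range(0, pv + 1):
            decay = 1.0 / (1.0 + p * p + q * q)
            field += rng.normal(0, decay) * np.sin(np.pi * p * U) * np.cos(q * Vv)
            if q > 0:
                field += rng.normal(0, decay) * np.sin(np.pi * p * U) * np.sin(q * Vv)
    rms = field.std()
    return field / (rms if rms > 1e-12 else 1.0)


def _outward_normals(positions: np.ndarray) -> np.ndarray:
    """Unit radial directions: from each ring centroid to its nodes."""
    ctr = positions.mean(axis=1, keepdims=True)
    d = positions - ctr
    n = np.linalg.norm(d, axis=-1, keepdims=True)
    return d / np.where(n > 1e-12, n, 1.0)


def simulate_cohort(config: SimulationConfig, *, return_grids: bool = False):
    """Simulate a cohort of surfaces from the template.

    Each subject is the template deformed radially by (a) a smooth
    Gaussian-random-field noise of per-subject RMS ``noise_sd`` and
    (b) for non-reference groups, the configured effect-region offsets.
    Scores are drawn with the configured correlation to the subject's
    realized mean deformation inside the effect regions.  The first
    group listed in ``n_per_group`` is the reference and receives no
    effect.

    Returns ``(meshes, truth)``; with ``return_grids=True`` returns
    ``(meshes, truth, grids)`` where grids are the subjects' analytic
    parameterizations (useful to skip mesh re-parameterization at small
    scale; the honest pipeline path re-parameterizes the meshes).
    """
    rng = np.random.default_rng(config.seed)
    _, template = make_template_surface(config.structure_kind,
                                        config.grid_dims, seed=config.seed)
    dims = config.grid_dims
    normals = _outward_normals(template.positions)

    # ground-truth effect field (same for every affected subject)
    true_delta = np.zeros(dims)
    masks = []
    for region in config.effect_regions:
        w = region_weight(region, dims)
        true_delta = true_delta + region.signed_delta * w
        masks.append(w > 0)
    radii = np.linalg.norm(
        template.positions - template.positions.mean(axis=1, keepdims=True),
        axis=-1)
    support = np.abs(true_delta) > 0
    if support.any() and np.any(np.abs(true_delta[support]) >= radii[support]):
        worst = np.max(np.abs(true_delta[support]) - radii[support])
        raise ValueError(
            f"effect offset exceeds local template radius by {worst:.2f} mm "
            "inside the region (surface would self-intersect)")

    labels = [g for g, ng in config.n_per_group.items() for _ in range(ng)]
    reference = config.groups[0]
    combined = np.logical_or.reduce(masks) if masks else np.zeros(dims, bool)

    meshes, grids, realized = [], [], []
    for lab in labels:
        noise = (config.noise_sd * smooth_noise_field(dims, rng)
                 if config.noise_sd > 0 else np.zeros(dims))
        offset = noise + (true_delta if lab != reference else 0.0)
        pos = template.positions + offset[..., None] * normals
        if config.param_jitter_cells > 0:
            # tangential misalignment: re-index the grid by a smooth
            # random parameter-domain warp (what independent per-subject
            # parameterization produces; registration must undo it)
            ju = config.param_jitter_cells * smooth_noise_field(dims, rng, (2, 2))
            jv = config.param_jitter_cells * smooth_noise_field(dims, rng, (2, 2))
            u_taper = np.sin(np.pi * (np.arange(dims[0]) + 0.5) / dims[0])
            ju *= u_taper[:, None]     # cuts stay fixed in u
            pos = _resample_positions(pos, ju, jv)
        radii = np.linalg.norm(pos - pos.mean(axis=1, keepdims=True), axis=-1)
        if np.any(radii <= 0):
            raise RuntimeError("subject surface self-intersects (radius <= 0)")
        lam = conformal_factor_from_positions(pos, 1.0 / dims[0],
                                              2.0 * np.pi / dims[1])
        H = grid_mean_curvature(pos, 1.0 / dims[0], 2.0 * np.pi / dims[1])
        g = ConformalGrid(dims, pos, lam, H, periodic_v=True,
                          metadata={"group": lab, "analytic": True})
        grids.append(g)
        meshes.append(_subject_mesh(g))
        realized.append(float(offset[combined].mean()) if combined.any() else 0.0)

    scores = _draw_scores(config.score_specs, np.asarray(realized), rng)
    scores["_deformation"] = realized
    scores.insert(0, "group", labels)
    truth = SimulationTruth(masks, true_delta, labels, scores)
    if return_grids:
        return meshes, truth, grids
    return meshes, truth


def _resample_positions(pos: np.ndarray, ju: np.ndarray, jv: np.ndarray) -> np.ndarray:
    """Bilinear re-indexing of a grid by per-node cell offsets (ju, jv)."""
    from .registration import _sample
    nu, nv = pos.shape[:2]
    gx, gy = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    coords = np.stack([gx + ju, gy + jv], axis=-1)
    return np.stack([_sample(pos[..., d], coords) for d in range(3)], axis=-1)


def _subject_mesh(grid: ConformalGrid) -> TriangleMesh:
    pole_a = grid.positions[0].mean(axis=0) * 1.0
    pole_b = grid.positions[-1].mean(axis=0) * 1.0
    # place pole apices slightly beyond the end rings along the axis
    axis_a = pole_a - grid.positions[1].mean(axis=0)
    axis_b = pole_b - grid.positions[-2].mean(axis=0)
    ring_r = np.linalg.norm(grid.positions[0] - pole_a, axis=-1).mean()
    ring_r_b = np.linalg.norm(grid.positions[-1] - pole_b, axis=-1).mean()
    na = np.linalg.norm(axis_a)
    nb = np.linalg.norm(axis_b)
    if na > 1e-9:
        pole_a = pole_a + axis_a / na * 0.5 * ring_r
    if nb > 1e-9:
        pole_b = pole_b + axis_b / nb * 0.5 * ring_r_b
    return grid_to_mesh(grid, pole_a, pole_b)


def _draw_scores(specs, realized, rng) -> pd.DataFrame:
    n = len(realized)
    out = {}
    sd_d = realized.std()
    z = ((realized - realized.mean()) / sd_d) if sd_d > 1e-12 else np.zeros(n)
    for spec in specs:
        eps = rng.standard_normal(n)
        eps = (eps - eps.mean()) / max(eps.std(), 1e-12)
        latent = spec.rho * z + np.sqrt(max(0.0, 1 - spec.rho ** 2)) * eps
        out[spec.name] = spec.mean + spec.sd * latent
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> dict:
    flat = mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.r_[0, change]
    lengths = np.diff(np.r_[starts, len(flat)])
    return {"shape": list(mask.shape), "first": int(flat[0]),
            "lengths": lengths.tolist()}


def _rle_decode(d: dict) -> np.ndarray:
    vals = []
    cur = d["first"]
    for ln in d["lengths"]:
        vals.append(np.full(ln, cur, dtype=bool))
        cur = 1 - cur
    return np.concatenate(vals).reshape(d["shape"])


def write_cohort(meshes, truth: SimulationTruth, out_dir, fmt: str = "ply"):
    """Write meshes (PLY or VTK), truth JSON (RLE masks) and score TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mesh in enumerate(meshes):
        p = out / f"subject_{i:04d}.{fmt}"
        write_mesh(mesh, p)
        paths.append(p.name)
    (out / "truth.json").write_text(json.dumps({
        "effect_masks": [_rle_encode(m) for m in truth.effect_masks],
        "true_delta": truth.true_delta.tolist(),
        "subject_labels": truth.subject_labels,
        "meshes": paths,
    }))
    truth.subject_scores.to_csv(out / "scores.tsv", sep="\t",
                                index_label="subject")
    return out


def read_truth(path) -> SimulationTruth:
    d = json.loads((Path(path) / "truth.json").read_text())
    scores = pd.read_csv(Path(path) / "scores.tsv", sep="\t", index_col=0)
    return SimulationTruth(
        [_rle_decode(m) for m in d["effect_masks"]],
        np.asarray(d["true_delta"]),
        d["subject_labels"],
        scores,
    )
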