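"""End-to-end orchestration: simulate -> parameterize -> register ->
features -> stats -> classify, with a resumable run manifest.

Each stage reads only the serialized outputs of the previous stage from
the run directory, so a run can be resumed stage-by-stage; the manifest
records seeds, content hashes and wall times for every completed stage.
The template is a designated subject (the first reference-group subject)
by default; an external template mesh may be supplied instead.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify as cls
from . import stats as vstats
from .morphometry import subject_features
from .registration import RegistrationParams, fluid_register
from .surface import ConformalGrid, conformal_parameterize, conformal_representation, read_mesh
from .synthetic import (EffectRegion, ScoreSpec, SimulationConfig,
                        read_truth, simulate_cohort, write_cohort)

STAGES = ("simulate", "parameterize", "register", "features", "stats", "classify")


class StageError(RuntimeError):
    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    stages: tuple = STAGES
    structure_kind: str = "hippocampus_like"
    grid_dims: tuple = (40, 60)
    n_per_group: dict = field(default_factory=lambda: {"HC": 20, "PD": 20})
    effect_regions: list = field(default_factory=list)   # EffectRegion kwargs
    noise_sd: float = 0.3
    score_specs: list = field(default_factory=list)      # ScoreSpec kwargs
    template_policy: str = "designated_subject"
    template_mesh: str | None = None
    registration: dict = field(default_factory=dict)     # RegistrationParams kwargs
    measures: tuple = ("RD", "TBM", "mTBM", "MMS")
    n_perm: int = 500
    alpha: float = 0.05
    n_patches: int = 120
    patch_side: int = 10
    k_atoms: int = 48
    gamma: float = 0.15
    scc_epochs: int = 3
    folds: int = 10
    use_analytic_grids: bool = False
    seeds: dict = field(default_factory=lambda: {
        "simulate": 0, "patches": 1, "scc": 2, "folds": 3, "permutations": 4})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["grid_dims"] = tuple(d.get("grid_dims", (40, 60)))
        d["stages"] = tuple(d.get("stages", STAGES))
        d["measures"] = tuple(d.get("measures", ("RD", "TBM", "mTBM", "MMS")))
        return cls(**d)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute the enabled stages in order; return the run manifest.

    A stage whose outputs already exist (and whose recorded input hashes
    still match) is skipped unless ``force`` is set; a stale intermediate
    raises :class:`StageError` instead of silently recomputing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() and not force
                else {"stages": {}, "config": json.loads(config.to_json())})
    if manifest_path.exists() and not force:
        if manifest.get("config") != json.loads(config.to_json()):
            raise StageError("resume", "config changed; rerun with force=True")

    enabled = [s for s in STAGES if s in config.stages]
    for i, stage in enumerate(enabled):
        deps = STAGES[:STAGES.index(stage)]
        for dep in deps:
            if dep not in manifest["stages"] and dep not in config.stages:
                raise StageError(
                    stage, f"requires stage {dep!r}, which is disabled and "
                    "has no recorded output")
        if stage in manifest["stages"] and not force:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FNS[stage](config, out)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "seed": config.seeds.get(stage),
            "outputs": {name: _hash_file(out / name) for name in outputs},
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
    manifest["complete"] = all(s in manifest["stages"] for s in enabled)
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, out: Path):
    sim = SimulationConfig(
        structure_kind=config.structure_kind,
        n_per_group=dict(config.n_per_group),
        effect_regions=[EffectRegion(**{**r, "u_range": tuple(r["u_range"]),
                                        "v_range": tuple(r["v_range"])})
                        for r in config.effect_regions],
        noise_sd=config.noise_sd,
        score_specs=[ScoreSpec(**s) for s in config.score_specs],
        grid_dims=config.grid_dims,
        seed=config.seeds.get("simulate", 0),
    )
    meshes, truth, grids = simulate_cohort(sim, return_grids=True)
    cohort_dir = out / "cohort"
    write_cohort(meshes, truth, cohort_dir)
    if config.use_analytic_grids:
        gdir = out / "grids"
        gdir.mkdir(exist_ok=True)
        for i, g in enumerate(grids):
            g.save(gdir / f"subject_{i:04d}.npz")
    return ["cohort/truth.json", "cohort/scores.tsv"]


def _stage_parameterize(config: PipelineConfig, out: Path):
    cohort_dir = out / "cohort"
    if not (cohort_dir / "truth.json").exists():
        raise StageError("parameterize", "missing cohort/truth.json "
                         "(run the simulate stage or provide a cohort)")
    gdir = out / "grids"
    gdir.mkdir(exist_ok=True)
    truth = json.loads((cohort_dir / "truth.json").read_text())
    if config.use_analytic_grids:
        missing = [m for m in truth["meshes"]
                   if not (gdir / (Path(m).stem + ".npz")).exists()]
        if missing:
            raise StageError("parameterize",
                             f"analytic grids requested but missing: {missing[:3]}")
        return ["grids"]
    for name in truth["meshes"]:
        mesh = read_mesh(cohort_dir / name)
        grid = conformal_parameterize(mesh, config.grid_dims)
        grid.save(gdir / (Path(name).stem + ".npz"))
    return ["cohort/truth.json"]


def _load_grids(config, out):
    truth = json.loads((out / "cohort" / "truth.json").read_text())
    grids = [ConformalGrid.load(out / "grids" / (Path(n).stem + ".npz"))
             for n in truth["meshes"]]
    return grids, truth


def _stage_register(config: PipelineConfig, out: Path):
    grids, truth = _load_grids(config, out)
    labels = truth["subject_labels"]
    if config.template_policy == "external_mesh":
        if not config.template_mesh:
            raise StageError("register", "template_policy external_mesh "
                             "requires template_mesh")
        tgrid = conformal_parameterize(read_mesh(config.template_mesh),
                                       config.grid_dims)
    else:
        tgrid = grids[0]     # first (reference-group) subject
    t_rep, _ = conformal_representation(tgrid)
    ddir = out / "deformations"
    ddir.mkdir(exist_ok=True)
    params = RegistrationParams(**config.registration)
    for i, g in enumerate(grids):
        rep, _ = conformal_representation(g)
        defo = fluid_register(rep, t_rep, params)
        np.savez(ddir / f"subject_{i:04d}.npz",
                 displacement=defo.displacement, jacobian=defo.jacobian,
                 mi_trace=np.asarray(defo.mi_trace),
                 converged=np.array(defo.converged))
    (ddir / "template.json").write_text(json.dumps(
        {"policy": config.template_policy, "n_subjects": len(labels)}))
    return ["deformations/template.json"]


def _stage_features(config: PipelineConfig, out: Path):
    from .registration import DeformationField
    grids, truth = _load_grids(config, out)
    ddir = out / "deformations"
    if not (ddir / "template.json").exists():
        raise StageError("features", "missing deformations/ (run register)")
    stacks = {m: [] for m in ("RD", "TBM", "mTBM", "MMS")}
    for i, g in enumerate(grids):
        with np.load(ddir / f"subject_{i:04d}.npz") as z:
            defo = DeformationField(z["displacement"], z["jacobian"],
                                    z["mi_trace"].tolist(), bool(z["converged"]))
        fs = subject_features(g, defo)
        for m in stacks:
            stacks[m].append(fs.channel(m))
    np.savez(out / "features.npz",
             **{m: np.asarray(v) for m, v in stacks.items()},
             labels=np.asarray(truth["subject_labels"]))
    return ["features.npz"]


def _stage_stats(config: PipelineConfig, out: Path):
    fpath = out / "features.npz"
    if not fpath.exists():
        raise StageError("stats", "missing features.npz (run features)")
    results = {}
    with np.load(fpath, allow_pickle=False) as z:
        labels = z["labels"]
        seed = config.seeds.get("permutations", 0)
        for measure in config.measures:
            data = z[measure]       # (n, nu, nv, ch)
            n = data.shape[0]
            flat = data.reshape(n, -1, data.shape[-1])
            cohort = vstats.CohortFeatures(flat, labels, measure)
            sm = vstats.permutation_test(cohort, n_perm=config.n_perm,
                                         alpha=config.alpha, seed=seed)
            entry = {"p_global": sm.p_global, "p_global_label": sm.p_global_label,
                     "real_effect": sm.real_effect, "n_perm": sm.n_perm}
            if cohort.is_univariate:
                dm = vstats.direction_map(cohort, sm)
                entry["n_atrophy"] = int(np.sum(dm.labels == 1))
                entry["n_expansion"] = int(np.sum(dm.labels == -1))
            results[measure] = entry
    (out / "stats.json").write_text(json.dumps(results, indent=1))
    return ["stats.json"]


def _stage_classify(config: PipelineConfig, out: Path):
    fpath = out / "features.npz"
    if not fpath.exists():
        raise StageError("classify", "missing features.npz (run features)")
    with np.load(fpath, allow_pickle=False) as z:
        mms_stack = z["MMS"]
        labels = z["labels"]
    groups = list(dict.fromkeys(labels.tolist()))
    y = np.where(labels == groups[0], -1, 1)
    layout = cls.generate_patches(config.grid_dims, config.n_patches,
                                  config.patch_side,
                                  seed=config.seeds.get("patches", 0))
    mats = np.asarray([cls.extract_patch_features(m, layout)
                       for m in mms_stack])
    ds = cls.SubjectDataset(mats, y, k=config.k_atoms, gamma=config.gamma,
                            epochs=config.scc_epochs)
    report = cls.cross_validate(ds, k_folds=config.folds,
                                seed=config.seeds.get("folds", 0))
    (out / "cv_report.json").write_text(json.dumps({
        "means": report.means, "per_fold": report.per_fold,
        "confusions": report.confusions, "config": report.config,
        "groups": [str(g) for g in groups],
    }, indent=1, default=float))
    return ["cv_report.json"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "parameterize": _stage_parameterize,
    "register": _stage_register,
    "features": _stage_features,
    "stats": _stage_stats,
    "classify": _stage_classify,
}


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def make_comparison_report(stat_entries, cv_entries=()):
    """Summary tables: global p per structure/measure/comparison and the
    five CV metrics per structure/task.

    stat_entries : iterable of dicts with keys structure, measure,
                   comparison and either a StatMap under 'stat_map' or a
                   'p_global' float
    cv_entries   : iterable of dicts with structure, task and 'means'
                   (metric -> value) or a CVReport under 'report'

    Returns ``(report_dict, markdown)``; p-values below 0.05 carry a
    significance flag (rendered bold in the markdown table).
    """
    rows = []
    for e in stat_entries:
        p = e["stat_map"].p_global if "stat_map" in e else e["p_global"]
        rows.append({"structure": e.get("structure", ""),
                     "measure": e["measure"],
                     "comparison": e.get("comparison", ""),
                     "p_global": float(p), "significant": bool(p < 0.05)})
    cv_rows = []
    for e in cv_entries:
        means = e["report"].means if "report" in e else e["means"]
        cv_rows.append({"structure": e.get("structure", ""),
                        "task": e.get("task", ""),
                        **{m: float(means[m]) for m in cls.METRICS}})
    report = {"global_p": rows}
    if cv_rows:
        report["classification"] = cv_rows

    md = ["| Structure | Measure | Comparison | Global p |",
          "|---|---|---|---|"]
    for r in rows:
        p = f"**{r['p_global']:.4g}**" if r["significant"] else f"{r['p_global']:.4g}"
        md.append(f"| {r['structure']} | {r['measure']} | {r['comparison']} | {p} |")
    if cv_rows:
        md += ["", "| Structure | Task | ACC | SEN | SPE | PPV | NPV |",
               "|---|---|---|---|---|---|---|"]
        for r in cv_rows:
            md.append("| " + " | ".join(
                [str(r["structure"]), str(r["task"])]
                + [f"{r[m]:.4f}" for m in cls.METRICS]) + " |")
    return report, "\n".join(md)
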