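"""End-to-end orchestration, configuration and file I/O.

Ties the analysis stages into one reproducible pipeline:

    simulate → quantize → texture → train → explain → cluster / associate

Volumes travel as NIfTI-1 (.nii.gz), feature maps as NIfTI plus a JSON
sidecar with the extraction configuration, tables as CSV.  Every run writes
a manifest recording the configuration hash, the seed, input hashes and the
hash of every output file; rerunning with identical configuration and
inputs reproduces all outputs bit-identically (stage seeds are derived from
the global seed by stable hashing).  Wall-clock timings are kept in a
separate ``timings`` key that is not part of the determinism contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import classify as clf_mod
from . import cluster as cluster_mod
from . import relevance as rel_mod
from . import stats as stats_mod
from .quantize import QuantizedVolume, equalize_histogram
from .synthetic import (INSTRUMENT_RANGES, RawVolume, SyntheticCohortSpec,
                        compartment_atlas, generate_cohort)
from .texture import DEFAULT_OFFSETS, TextureFeatureMap, texture_feature_maps

__all__ = [
    "PipelineConfig", "run_pipeline", "STAGES",
    "read_volume", "write_volume", "read_clinical_csv", "write_clinical_csv",
    "read_feature_map", "write_feature_map",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantize", "texture", "train", "explain", "cluster",
          "associate")

#: Hard stage prerequisites (outputs that must exist before a stage runs).
_DEPENDS = {
    "simulate": (),
    "quantize": ("volumes",),
    "texture": ("volumes", "quantized"),
    "train": ("maps", "clinical"),
    "explain": ("maps", "model"),
    "cluster": ("heatmaps", "clinical"),
    "associate": ("heatmaps", "clinical", "predictions"),
}

REQUIRED_CLINICAL_COLUMNS = ("subject_id", "group", "visdys_label",
                             "timepoint")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, YAML-serializable."""

    output_dir: str = "braintexture_out"
    volumes_dir: str | None = None  # default: <output_dir>/volumes
    clinical_csv: str | None = None  # default: <output_dir>/clinical.csv
    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)
    quantization: dict = field(
        default_factory=lambda: {"n_levels": 16})
    texture: dict = field(default_factory=lambda: {
        "cube_size": 5, "stride": 1, "features": ["energy", "entropy"],
        "offsets": [list(o) for o in DEFAULT_OFFSETS]})
    classify: dict = field(default_factory=lambda: {
        "feature": "energy", "outer_k": 5, "inner_k": 3, "epochs": 120,
        "hyper_grid": {"lr": [3e-3, 1e-2], "weight_decay": [0.0, 1e-4]}})
    relevance: dict = field(default_factory=lambda: {
        "percentile": 95.0, "eps": 1e-6})
    cluster: dict = field(default_factory=lambda: {
        "preference": "median", "damping": 0.9, "max_iter": 500})
    stats: dict = field(default_factory=lambda: {
        "variables": ["panss_positive", "panss_negative", "gaf", "bdi_ii",
                      "visdys"],
        "alpha": 0.05, "subset": "correct"})

    def __post_init__(self):
        if self.volumes_dir is None:
            self.volumes_dir = str(Path(self.output_dir) / "volumes")
        if self.clinical_csv is None:
            self.clinical_csv = str(Path(self.output_dir) / "clinical.csv")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (filesystem locations are
        excluded so the same analysis hashes the same anywhere)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("output_dir", "volumes_dir", "clinical_csv")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------
def write_volume(path, volume: RawVolume):
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float64), affine),
             str(path))


def read_volume(path) -> RawVolume:
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RawVolume(voxels=voxels, spacing=spacing)


def write_quantized(path, q: QuantizedVolume):
    affine = np.diag(list(q.spacing) + [1.0])
    nib.save(nib.Nifti1Image(q.levels.astype(np.int16), affine), str(path))
    Path(str(path) + ".json").write_text(
        json.dumps({"n_levels": q.n_levels}))


def read_quantized(path, raw: RawVolume) -> QuantizedVolume:
    """Quantized levels from disk; masks re-derived from the raw volume."""
    img = nib.load(str(path))
    levels = np.asarray(img.dataobj, dtype=np.int16)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return QuantizedVolume(
        levels=levels, n_levels=int(meta["n_levels"]),
        source_mapping=(np.empty(0), np.empty(0, dtype=np.int16)),
        brain_mask=raw.brain_mask, nonzero_mask=raw.voxels != 0,
        spacing=raw.spacing)


def write_feature_map(path, fmap: TextureFeatureMap):
    nib.save(nib.Nifti1Image(fmap.values.astype(np.float64), np.eye(4)),
             str(path))
    sidecar = dict(fmap.config, feature_name=fmap.feature_name)
    sidecar["offsets"] = [list(o) for o in sidecar["offsets"]]
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_feature_map(path) -> TextureFeatureMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return TextureFeatureMap(
        feature_name=meta["feature_name"],
        values=values,
        valid_mask=np.isfinite(values),
        cube_size=int(meta["cube_size"]),
        stride=int(meta["stride"]),
        n_levels=int(meta["n_levels"]),
        offsets=tuple(tuple(o) for o in meta["offsets"]),
    )


def write_clinical_csv(path, table: pd.DataFrame):
    table.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    """Read and schema-check a clinical table.

    Requires the subject/group/label/timepoint columns; score values outside
    the declared instrument range trigger a warning but are retained.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"clinical table {path} is missing required columns: {missing}")
    bad_tp = set(table["timepoint"].unique()) - {"T0", "T1"}
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected T0/T1")
    for var, (lo, hi) in INSTRUMENT_RANGES.items():
        if var in table.columns:
            vals = pd.to_numeric(table[var], errors="coerce")
            out = ((vals < lo) | (vals > hi)) & vals.notna()
            if out.any():
                logger.warning(
                    "%d %s values outside instrument range [%g, %g]; retained",
                    int(out.sum()), var, lo, hi)
    return table


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------
class _Run:
    """Mutable state shared by the stages of one pipeline invocation."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.volumes_dir = Path(config.volumes_dir)
        self.clinical_csv = Path(config.clinical_csv)
        self.outputs: dict[str, list[str]] = {}

    # -- artifact discovery -------------------------------------------
    def volume_paths(self) -> dict[str, Path]:
        if not self.volumes_dir.is_dir():
            return {}
        return {p.name.split(".")[0]: p
                for p in sorted(self.volumes_dir.glob("*.nii*"))}

    def has(self, artifact: str) -> bool:
        checks = {
            "volumes": lambda: bool(self.volume_paths()),
            "clinical": self.clinical_csv.exists,
            "quantized": lambda: any((self.out / "quantized").glob("*.nii*"))
            if (self.out / "quantized").is_dir() else False,
            "maps": lambda: any((self.out / "maps").glob("*.nii*"))
            if (self.out / "maps").is_dir() else False,
            "model": (self.out / "model.pkl").exists,
            "heatmaps": lambda: any((self.out / "heatmaps").glob("*.nii*"))
            if (self.out / "heatmaps").is_dir() else False,
            "predictions": (self.out / "cv_predictions.csv").exists,
        }
        return bool(checks[artifact]())

    def record(self, stage, paths):
        self.outputs[stage] = sorted(
            str(Path(p).relative_to(self.out)) if str(p).startswith(str(self.out))
            else str(p)
            for p in paths)

    # -- loading helpers ----------------------------------------------
    def load_maps(self, feature) -> dict[str, TextureFeatureMap]:
        maps = {}
        for p in sorted((self.out / "maps").glob(f"*_{feature}.nii.gz")):
            sid = p.name.rsplit(f"_{feature}", 1)[0]
            maps[sid] = read_feature_map(p)
        if not maps:
            raise FileNotFoundError(
                f"no {feature!r} feature maps under {self.out / 'maps'}")
        return maps

    def load_labels(self) -> dict[str, str]:
        clin = read_clinical_csv(self.clinical_csv)
        t0 = clin[clin["timepoint"] == "T0"]
        return dict(zip(t0["subject_id"], t0["visdys_label"]))

    def load_heatmaps(self) -> dict[str, rel_mod.RelevanceHeatmap]:
        meta = pd.read_csv(self.out / "heatmap_scores.csv").set_index(
            "subject_id")
        heatmaps = {}
        for p in sorted((self.out / "heatmaps").glob("*.nii.gz")):
            sid = p.name.split(".")[0]
            rel = np.asarray(nib.load(str(p)).dataobj, dtype=np.float64)
            heatmaps[sid] = rel_mod.RelevanceHeatmap(
                relevance=rel, subject_id=sid,
                predicted_class=int(meta.loc[sid, "predicted_class"]),
                output_score=float(meta.loc[sid, "output_score"]))
        return heatmaps


def _stage_simulate(run: _Run):
    cfg = dict(run.config.synthetic)
    cfg.setdefault("seed", stage_seed(run.config.seed, "simulate"))
    spec = SyntheticCohortSpec(**cfg)
    cohort = generate_cohort(spec)
    run.volumes_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, vol in cohort.volumes.items():
        path = run.volumes_dir / f"{sid}.nii.gz"
        write_volume(path, vol)
        written.append(path)
    write_clinical_csv(run.clinical_csv, cohort.clinical)
    written.append(run.clinical_csv)
    spec_path = run.out / "cohort_spec.yaml"
    spec_path.write_text(spec.to_yaml())
    written.append(spec_path)
    return written


def _stage_quantize(run: _Run):
    g = int(run.config.quantization.get("n_levels", 16))
    qdir = run.out / "quantized"
    qdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, path in run.volume_paths().items():
        q = equalize_histogram(read_volume(path), g)
        qpath = qdir / f"{sid}.nii.gz"
        write_quantized(qpath, q)
        written += [qpath, Path(str(qpath) + ".json")]
    return written


def _stage_texture(run: _Run):
    tcfg = run.config.texture
    mdir = run.out / "maps"
    mdir.mkdir(parents=True, exist_ok=True)
    written = []
    for sid, vpath in run.volume_paths().items():
        raw = read_volume(vpath)
        q = read_quantized(run.out / "quantized" / f"{sid}.nii.gz", raw)
        maps = texture_feature_maps(
            q, cube_size=int(tcfg.get("cube_size", 5)),
            stride=int(tcfg.get("stride", 1)),
            features=tuple(tcfg.get("features", ("energy", "entropy"))),
            offsets=tuple(tuple(o) for o in
                          tcfg.get("offsets", DEFAULT_OFFSETS)))
        for feat, fmap in maps.items():
            fpath = mdir / f"{sid}_{feat}.nii.gz"
            write_feature_map(fpath, fmap)
            written += [fpath, Path(str(fpath) + ".json")]
    return written


def _stage_train(run: _Run):
    ccfg = run.config.classify
    maps = run.load_maps(ccfg.get("feature", "energy"))
    labels = run.load_labels()
    result = clf_mod.nested_cv_train(
        maps, labels,
        outer_k=int(ccfg.get("outer_k", 5)),
        inner_k=int(ccfg.get("inner_k", 3)),
        hyper_grid=ccfg.get("hyper_grid"),
        seed=stage_seed(run.config.seed, "train"),
        epochs=int(ccfg.get("epochs", 120)),
        n_repeats=int(ccfg.get("n_repeats", 1)))
    rows = [dict(cohort="pooled CV", **result.pooled_metrics.as_dict())]
    for i, m in enumerate(result.per_fold_metrics):
        if m is not None:
            rows.append(dict(cohort=f"outer fold {i}", **m.as_dict()))
    metrics_path = run.out / "cv_metrics.csv"
    pd.DataFrame(rows).to_csv(metrics_path, index=False)
    pred_path = run.out / "cv_predictions.csv"
    pred = pd.DataFrame(
        [(s, labels[s], p) for s, p in result.pooled_predictions.items()],
        columns=["subject_id", "true_label", "predicted_label"])
    pred.to_csv(pred_path, index=False)
    model_path = run.out / "model.pkl"
    with open(model_path, "wb") as fh:
        pickle.dump({"model": result.winner_model,
                     "hyperparams": result.selected_hyperparams,
                     "config_hash": run.config.config_hash}, fh)
    return [metrics_path, pred_path, model_path]


def _stage_explain(run: _Run):
    rcfg = run.config.relevance
    with open(run.out / "model.pkl", "rb") as fh:
        model = pickle.load(fh)["model"]
    feature = run.config.classify.get("feature", "energy")
    maps = run.load_maps(feature)
    hdir = run.out / "heatmaps"
    hdir.mkdir(parents=True, exist_ok=True)
    written = []
    score_rows, mean_rows, frac_rows = [], [], []
    common_valid = np.logical_and.reduce(
        [m.valid_mask for m in maps.values()])
    tcfg = next(iter(maps.values()))
    atlas_vox = compartment_atlas(
        _volume_shape_from_grid(tcfg), folding_amplitude=0.0, seed=0)
    atlas = rel_mod.atlas_on_map_grid(atlas_vox, tcfg.cube_size, tcfg.stride)
    for sid, fmap in maps.items():
        hm = rel_mod.lrp_relevance(model, fmap, subject_id=sid,
                                   eps=float(rcfg.get("eps", 1e-6)))
        hpath = hdir / f"{sid}.nii.gz"
        nib.save(nib.Nifti1Image(hm.relevance, np.eye(4)), str(hpath))
        written.append(hpath)
        score_rows.append({"subject_id": sid,
                           "predicted_class": hm.predicted_class,
                           "output_score": hm.output_score})
        mean_rows.append({"subject_id": sid,
                          "mean_relevance": rel_mod.mean_relevance(
                              hm, common_valid)})
        fr = rel_mod.significant_region_fractions(
            hm, atlas, percentile=float(rcfg.get("percentile", 95.0)),
            brain_mask=common_valid & (atlas > 0))
        for region, frac in fr.items():
            frac_rows.append({"subject_id": sid, "region": region,
                              "n_voxels": int((atlas == region).sum()),
                              "fraction": frac})
    for name, rows in (("heatmap_scores", score_rows),
                       ("mean_relevance", mean_rows),
                       ("region_fractions", frac_rows)):
        path = run.out / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    np.save(run.out / "common_valid_mask.npy", common_valid)
    written.append(run.out / "common_valid_mask.npy")
    return written


def _volume_shape_from_grid(fmap: TextureFeatureMap):
    """Voxel-volume shape implied by a map grid (inverse of the cube slide)."""
    return tuple((n - 1) * fmap.stride + fmap.cube_size
                 for n in fmap.values.shape)


def _stage_cluster(run: _Run):
    ccfg = run.config.cluster
    heatmaps = run.load_heatmaps()
    mask = np.load(run.out / "common_valid_mask.npy")
    sol = cluster_mod.affinity_propagation(
        heatmaps, mask=mask,
        preference=ccfg.get("preference", "median"),
        damping=float(ccfg.get("damping", 0.9)),
        max_iter=int(ccfg.get("max_iter", 500)),
        seed=stage_seed(run.config.seed, "cluster"))
    idx = sol.cluster_index()
    sol_path = run.out / "clusters.csv"
    pd.DataFrame(
        [{"subject_id": s, "cluster": idx[s],
          "exemplar": int(s == sol.assignment[s])}
         for s in sorted(sol.assignment)]).to_csv(sol_path, index=False)
    clin = read_clinical_csv(run.clinical_csv)
    profiles = cluster_mod.cluster_profiles(
        sol, clin, run.config.stats.get("variables", []))
    prof_path = run.out / "cluster_profiles.csv"
    profiles.to_csv(prof_path, index=False)
    return [sol_path, prof_path]


def _stage_associate(run: _Run):
    scfg = run.config.stats
    heatmaps = run.load_heatmaps()
    mask = np.load(run.out / "common_valid_mask.npy")
    clin = read_clinical_csv(run.clinical_csv)
    pred = pd.read_csv(run.out / "cv_predictions.csv")
    if scfg.get("subset_file"):
        subset = [s.strip()
                  for s in Path(scfg["subset_file"]).read_text().split()
                  if s.strip()]
    elif scfg.get("subset", "correct") == "correct":
        subset = list(pred[pred["true_label"] == pred["predicted_label"]]
                      ["subject_id"])
    else:
        subset = list(heatmaps)
    tp_mode = scfg.get("timepoint", "both") or "both"
    modes = ("t0", "change") if tp_mode == "both" else (tp_mode,)
    written = []
    for mode in modes:
        results = stats_mod.associate_relevance(
            heatmaps, mask, clin, scfg.get("variables", []),
            timepoint_mode=mode, subset=subset,
            alpha=float(scfg.get("alpha", 0.05)))
        path = run.out / f"associations_{mode}.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            path, index=False)
        written.append(path)
    return written


_STAGE_FN = {
    "simulate": _stage_simulate,
    "quantize": _stage_quantize,
    "texture": _stage_texture,
    "train": _stage_train,
    "explain": _stage_explain,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
}


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------
def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage dependencies are validated before any work: a stage may run only
    if its prerequisites are produced by an earlier requested stage or
    already exist on disk.  The manifest (written to
    ``<output_dir>/manifest.json``) records the configuration hash, seed,
    input hashes and per-output hashes; ``timings`` holds wall-clock seconds
    and is excluded from the determinism contract.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, "INFO"))
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    run = _Run(config)

    produces = {"simulate": {"volumes", "clinical"},
                "quantize": {"quantized"}, "texture": {"maps"},
                "train": {"model", "predictions"}, "explain": {"heatmaps"},
                "cluster": set(), "associate": set()}
    available = set()
    for s in stages:
        for dep in _DEPENDS[s]:
            if dep not in available and not run.has(dep):
                raise ValueError(
                    f"stage {s!r} requires {dep!r}, which is neither "
                    "produced by an earlier requested stage nor on disk")
        available |= produces[s]

    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs_hash": None,
        "stages": {},
        "timings": {},
    }
    for s in stages:
        logger.info("stage %s: starting", s)
        t0 = time.perf_counter()
        try:
            written = _STAGE_FN[s](run)
        except Exception:
            manifest["stages"][s] = {"status": "failed"}
            _write_manifest(run, manifest)
            raise
        manifest["timings"][s] = round(time.perf_counter() - t0, 3)
        rels = []
        hashes = {}
        for p in written:
            p = Path(p)
            key = str(p.relative_to(run.out)) if str(p).startswith(
                str(run.out)) else str(p)
            rels.append(key)
            hashes[key] = _hash_file(p)
        manifest["stages"][s] = {"status": "complete", "outputs": sorted(rels),
                                 "output_hashes": dict(sorted(hashes.items()))}
        logger.info("stage %s: complete (%d outputs)", s, len(rels))
    vols = run.volume_paths()
    if vols:
        h = hashlib.sha256()
        for sid in sorted(vols):
            h.update(sid.encode())
            h.update(Path(vols[sid]).read_bytes())
        if run.clinical_csv.exists():
            h.update(run.clinical_csv.read_bytes())
        manifest["inputs_hash"] = h.hexdigest()[:16]
    _write_manifest(run, manifest)
    return manifest


def _write_manifest(run: _Run, manifest: dict):
    (run.out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
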