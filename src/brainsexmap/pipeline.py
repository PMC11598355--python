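"""Orchestrate the full experiment from one config and one seed.

Stages mirror the study workflow: simulate -> preprocess -> split -> train ->
evaluate -> tiv-audit -> saliency -> score. Each stage persists its outputs
under the run directory so any stage can be rerun in isolation; stage seeds
are derived by hashing (global seed, stage name). The final manifest records
the config, stage seeds, library versions, and content hashes of the
CSV/JSON artifacts, so identical seeds yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_scoring import region_scores, top_k
from .errors import ConfigurationError, DegenerateInputError
from .evaluation import compute_metrics, make_predictions, subgroup_report
from .experiments import derive_seed, predict_cohort
from .phantoms import PhantomConfig, generate_cohort, make_atlas
from .preprocess import estimate_tiv, stratified_split, zscore_normalize
from .saliency import average_maps, gradient_saliency, sexwise_average
from .sfcn import TrainConfig, build_sfcn, train
from .tiv_bias import balanced_correct_subset, kde_overlap, tertile_performance
from .volume import Atlas, Volume

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_all", "STAGES", "ARTIFACTS"]

STAGES = ("simulate", "preprocess", "split", "train", "evaluate",
          "tiv-audit", "saliency", "score")

ARTIFACTS = (
    "cohort.csv", "atlas.nii.gz", "split.csv", "checkpoint.npz",
    "history.json", "predictions.csv", "metrics.json", "tertiles.csv",
    "rtiv.json", "saliency_female.nii.gz", "saliency_male.nii.gz",
    "sex_differences_map.nii.gz", "region_scores.csv", "topk.json",
    "manifest.json",
)


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    channels: tuple[int, ...] = (4, 8, 8, 16, 16, 8)
    n_regions: int = 6
    tau: float = 0.1
    density_threshold: float = 0.2
    k: int = 5
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    out_dir: str = "runs/demo"

    def validate(self) -> None:
        errs = []
        for sub in (self.phantom, self.training):
            try:
                sub.validate()
            except (ValueError, ConfigurationError) as e:
                errs.extend(str(e).split("; "))
        if not np.isclose(sum(self.split_fractions), 1.0):
            errs.append(f"split_fractions must sum to 1, got {self.split_fractions}")
        if not 0.0 <= self.tau < 1.0:
            errs.append(f"tau must be in [0, 1), got {self.tau}")
        if not 0.0 < self.density_threshold < 1.0:
            errs.append(f"density_threshold must be in (0, 1), got {self.density_threshold}")
        if self.k <= 0 or self.k > self.n_regions:
            errs.append(f"k must be in [1, n_regions], got {self.k}")
        if errs:
            raise ConfigurationError(errs)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errs = []
        kwargs = dict(raw)
        try:
            phantom = PhantomConfig(**kwargs.pop("phantom", {}))
        except TypeError as e:
            errs.append(f"phantom: {e}")
            phantom = PhantomConfig()
        try:
            training = TrainConfig(**kwargs.pop("training", {}))
        except TypeError as e:
            errs.append(f"training: {e}")
            training = TrainConfig()
        for key in ("channels", "split_fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            errs.append(f"unknown config fields: {sorted(unknown)}")
            for u in unknown:
                kwargs.pop(u)
        cfg = cls(phantom=phantom, training=training, **kwargs)
        try:
            cfg.validate()
        except ConfigurationError as e:
            errs.extend(e.errors)
        if errs:
            raise ConfigurationError(errs)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in list(d["phantom"].items()):
            if isinstance(v, tuple):
                d["phantom"][k] = list(v)
        d["channels"] = list(self.channels)
        d["split_fractions"] = list(self.split_fractions)
        return d


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run config; errors are aggregated, not
    first-fail."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError([f"config root must be a mapping, got {type(raw).__name__}"])
    return RunConfig.from_dict(raw)


def _json_dump(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_cohort(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "cohort.csv", dtype={"subject_id": str, "sex": str})


def _load_volumes(out: Path, table: pd.DataFrame):
    vols = {}
    for sid in table["subject_id"]:
        vol = Volume.from_nifti(out / "volumes" / f"{sid}.nii.gz")
        mask = Volume.from_nifti(out / "masks" / f"{sid}.nii.gz").data > 0.5
        vols[sid] = (vol, mask)
    return vols


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    atlas = make_atlas(cfg.phantom.grid_shape, cfg.n_regions,
                       seed=derive_seed(cfg.seed, "atlas"),
                       voxel_mm=cfg.phantom.voxel_mm,
                       envelope_tiv_ml=0.9 * cfg.phantom.min_tiv())
    phantom = dataclasses.replace(cfg.phantom,
                                  seed=derive_seed(cfg.seed, "cohort"))
    generate_cohort(phantom, atlas, out_dir=out)
    atlas.to_nifti(out / "atlas.nii.gz")
    _json_dump({"names": {str(k): v for k, v in atlas.names.items()}},
               out / "atlas_names.json")


def stage_preprocess(cfg: RunConfig, out: Path) -> None:
    """Z-score each volume within its brain mask and replace the sampled TIV
    with the mask-based estimate (the value the audit uses)."""
    table = _load_cohort(out)
    tivs = []
    (out / "preprocessed").mkdir(exist_ok=True)
    for sid in table["subject_id"]:
        vol = Volume.from_nifti(out / "volumes" / f"{sid}.nii.gz")
        mask = Volume.from_nifti(out / "masks" / f"{sid}.nii.gz").data > 0.5
        zscore_normalize(vol, mask).to_nifti(out / "preprocessed" / f"{sid}.nii.gz")
        tivs.append(estimate_tiv(mask, vol.voxel_mm))
    table.assign(tiv_ml=tivs).to_csv(out / "cohort.csv", index=False)


def stage_split(cfg: RunConfig, out: Path) -> None:
    table = _load_cohort(out)
    split = stratified_split(table, fractions=cfg.split_fractions,
                             seed=derive_seed(cfg.seed, "split"))
    split.to_csv(out / "split.csv", index=False)


def _load_arrays(out: Path, table: pd.DataFrame):
    x = np.stack([Volume.from_nifti(out / "preprocessed" / f"{sid}.nii.gz").data
                  for sid in table["subject_id"]])
    y = (table["sex"] == "M").to_numpy(dtype=np.float32)
    return x, y


def stage_train(cfg: RunConfig, out: Path) -> None:
    table = _load_cohort(out)
    split = pd.read_csv(out / "split.csv")
    merged = table.merge(split, on="subject_id")
    model = build_sfcn(cfg.phantom.grid_shape, channels=cfg.channels,
                       seed=derive_seed(cfg.seed, "init"))
    tr_cfg = dataclasses.replace(cfg.training,
                                 seed=derive_seed(cfg.seed, "train"))
    x_tr, y_tr = _load_arrays(out, merged[merged["split"] == "train"])
    x_va, y_va = _load_arrays(out, merged[merged["split"] == "val"])
    trained = train(model, (x_tr, y_tr), (x_va, y_va), tr_cfg)
    np.savez(out / "checkpoint.npz",
             **{f"p{i}": p for i, (p, _) in enumerate(model.net.parameters())},
             **{f"bn_{i}_{name}": getattr(layer, name)
                for i, layer in enumerate(model.net.layers)
                if hasattr(layer, "running_mean")
                for name in ("running_mean", "running_var")})
    _json_dump({"history": trained.history,
                "selected_epoch": trained.selected_epoch},
               out / "history.json")


def _restore_model(cfg: RunConfig, out: Path):
    model = build_sfcn(cfg.phantom.grid_shape, channels=cfg.channels,
                       seed=derive_seed(cfg.seed, "init"))
    ckpt = np.load(out / "checkpoint.npz")
    model.net.load_state_dict([ckpt[f"p{i}"]
                               for i in range(len(model.net.parameters()))])
    for i, layer in enumerate(model.net.layers):
        if hasattr(layer, "running_mean"):
            layer.running_mean = ckpt[f"bn_{i}_running_mean"]
            layer.running_var = ckpt[f"bn_{i}_running_var"]
    return model


def stage_evaluate(cfg: RunConfig, out: Path) -> None:
    table = _load_cohort(out)
    split = pd.read_csv(out / "split.csv")
    test = table.merge(split, on="subject_id")
    test = test[test["split"] == "test"].reset_index(drop=True)
    model = _restore_model(cfg, out)
    x, _ = _load_arrays(out, test)
    prob = predict_cohort(model, x, cfg.training.batch_size)
    preds = make_predictions(test["subject_id"], prob, test["sex"])
    preds.to_csv(out / "predictions.csv", index=False)
    report = {"global": compute_metrics(preds).to_dict(),
              "subgroups": {k: {label: r.to_dict() for label, r in sub.items()}
                            for k, sub in subgroup_report(preds, table).items()}}
    _json_dump(report, out / "metrics.json")


def stage_tiv_audit(cfg: RunConfig, out: Path) -> None:
    table = _load_cohort(out)
    preds = pd.read_csv(out / "predictions.csv", dtype=str)
    merged = preds.merge(table[["subject_id", "sex", "tiv_ml"]], on="subject_id")
    tivs = merged["tiv_ml"].to_numpy(dtype=float)
    tertile_performance(preds, tivs).to_csv(out / "tertiles.csv", index=False)
    try:
        interval = kde_overlap(tivs[merged["sex"] == "F"],
                               tivs[merged["sex"] == "M"],
                               threshold=cfg.density_threshold)
        record = interval.to_dict()
    except DegenerateInputError as e:
        log.warning("KDE overlap unavailable (%s); empty interval", e)
        interval = None
        record = {"lo": None, "hi": None,
                  "density_threshold": cfg.density_threshold,
                  "bandwidth_f": None, "bandwidth_m": None,
                  "empty": True, "note": str(e)}
    subset = [] if interval is None or interval.empty else \
        balanced_correct_subset(preds, tivs, interval,
                                np.random.default_rng(derive_seed(cfg.seed, "subset")))
    _json_dump({**record, "balanced_subset": subset}, out / "rtiv.json")


def stage_saliency(cfg: RunConfig, out: Path) -> None:
    table = _load_cohort(out)
    preds = pd.read_csv(out / "predictions.csv", dtype=str)
    rtiv = json.loads((out / "rtiv.json").read_text())
    model = _restore_model(cfg, out)
    voxel = (cfg.phantom.voxel_mm,) * 3
    maps, template_mask = {}, np.zeros(cfg.phantom.grid_shape, dtype=bool)
    correct = preds[preds["pred"] == preds["true"]]
    (out / "saliency").mkdir(exist_ok=True)
    for sid in correct["subject_id"]:
        vol = Volume.from_nifti(out / "preprocessed" / f"{sid}.nii.gz")
        mask = Volume.from_nifti(out / "masks" / f"{sid}.nii.gz").data > 0.5
        try:
            smap = gradient_saliency(model, vol, mask)
        except DegenerateInputError as e:
            log.warning("subject %s: %s; excluded from averaged maps", sid, e)
            continue
        maps[sid] = smap
        template_mask |= mask
        Volume(smap.values, voxel).to_nifti(out / "saliency" / f"{sid}.nii.gz")
    if not maps:
        raise DegenerateInputError(
            "no usable saliency maps among correctly classified subjects")
    map_f, map_m = sexwise_average(maps, preds, template_mask)
    for smap, name in ((map_f, "saliency_female.nii.gz"),
                       (map_m, "saliency_male.nii.gz")):
        if smap is not None:
            Volume(smap.values, voxel).to_nifti(out / name)
    subset = [s for s in rtiv["balanced_subset"] if s in maps]
    chosen = subset if subset else list(maps)
    composite = average_maps([maps[s] for s in chosen], template_mask)
    Volume(composite.values, voxel).to_nifti(out / "sex_differences_map.nii.gz")


def stage_score(cfg: RunConfig, out: Path) -> None:
    atlas = Atlas.from_nifti(
        out / "atlas.nii.gz",
        names={int(k): v for k, v in json.loads(
            (out / "atlas_names.json").read_text())["names"].items()})
    composite = Volume.from_nifti(out / "sex_differences_map.nii.gz")
    table = region_scores(composite.data, atlas, tau=cfg.tau)
    table.to_csv(out / "region_scores.csv", index=False)
    ranked = top_k(table, k=min(cfg.k, len(table)))
    _json_dump({"k": int(min(cfg.k, len(table))),
                "regions": [{"name": r["name"],
                             "weighted_score": r["weighted_score"]}
                            for _, r in ranked.iterrows()]},
               out / "topk.json")


_STAGE_FN = {
    "simulate": stage_simulate, "preprocess": stage_preprocess,
    "split": stage_split, "train": stage_train, "evaluate": stage_evaluate,
    "tiv-audit": stage_tiv_audit, "saliency": stage_saliency,
    "score": stage_score,
}


def run_stage(name: str, cfg: RunConfig, out: Path) -> None:
    log.info("stage %s -> %s", name, out)
    _STAGE_FN[name](cfg, out)


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    hashes = {}
    for name in ARTIFACTS:
        p = out / name
        if p.suffix in (".csv", ".json") and p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    _json_dump({
        "config": cfg.to_dict(),
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in
                        ("atlas", "cohort", "split", "init", "train", "subset")},
        "versions": {"brainsexmap": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "artifact_sha256": hashes,
    }, out / "manifest.json")


def run_all(cfg: RunConfig) -> Path:
    """Run every stage; any failure aborts with the stage name while prior
    artifacts persist. Returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in STAGES:
        try:
            run_stage(name, cfg, out)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
    _write_manifest(cfg, out)
    return out
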