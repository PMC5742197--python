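"""Configured, logged, resumable pipeline: phantom -> contour -> dents ->
segmentation -> skeleton -> quantification.

Each stage reads only files written by earlier stages, is keyed by a content
hash of its inputs plus its parameter snapshot, and is skipped on rerun when
the key and the outputs are unchanged.  A :class:`RunManifest` records, per
stage, the parameter snapshot, input hashes, outputs, wall time, and warnings.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import contour as contour_mod
from . import graph as graph_mod
from . import phantom as phantom_mod
from . import quant as quant_mod
from . import segment as segment_mod
from .contour import ContourParams
from .graph import SkeletonParams
from .phantom import PhantomParams
from .stack import BinaryVolume, ImageStack, LabelVolume, read_volume, write_volume

log = logging.getLogger("vascatlas")

STAGES = ("phantom", "contour", "dents", "segment", "trace", "quant")


class ConfigError(ValueError):
    """Schema violation in a pipeline config."""


@dataclass
class SegmentConfig:
    recall_min: float = 0.94
    precision_min: float = 0.94
    candidate_offsets: tuple[int, int] = (5, 40)  # thresholds mean+lo .. mean+hi
    connectivity: int = 26
    closing_radius: int = 0  # optional gap-bridging closing of grown volumes

    def __post_init__(self) -> None:
        if not (0 < self.recall_min <= 1 and 0 < self.precision_min <= 1):
            raise ConfigError("recall_min/precision_min must lie in (0, 1]")
        if self.closing_radius < 0:
            raise ConfigError("closing_radius must be >= 0")


@dataclass
class QuantConfig:
    shrinkage: float = quant_mod.DEFAULT_SHRINKAGE
    validation_interval_um: float = 70.0

    def __post_init__(self) -> None:
        if not 0 <= self.shrinkage < 1:
            raise ConfigError("shrinkage must lie in [0, 1)")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("vascatlas_run")
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    resume: bool = True
    log_level: str = "INFO"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    contour: ContourParams = field(default_factory=ContourParams)
    skeleton: SkeletonParams = field(default_factory=SkeletonParams)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")


_SECTION_TYPES = {
    "phantom": PhantomParams,
    "contour": ContourParams,
    "skeleton": SkeletonParams,
    "segment": SegmentConfig,
    "quant": QuantConfig,
}
_TOP_KEYS = {"out_dir", "seed", "stages", "resume", "log_level", *_SECTION_TYPES}


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, sorted(allowed), n=1)
            extra = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown key '{where}{key}'{extra}")


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a YAML pipeline config; defaults fill gaps.

    Unknown keys are rejected with a nearest-match suggestion; invalid values
    (e.g. a negative closing radius) raise :class:`ConfigError` naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "")
    kwargs = {}
    for key in ("out_dir", "seed", "resume", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            sub = raw[section] or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            fields_ = set(cls.__dataclass_fields__)
            _check_keys(sub, fields_, f"{section}.")
            for name in ("shape", "voxel_size_um", "radius_range_um", "candidate_offsets"):
                if name in sub and isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            try:
                kwargs[section] = cls(**sub)
            except (ValueError, TypeError) as exc:
                raise ConfigError(f"section '{section}': {exc}") from exc
    cfg = PipelineConfig(**kwargs)
    if "seed" in raw:  # seed propagates to the phantom generator
        cfg.phantom.seed = int(raw["seed"])
    return cfg


# ---------------------------------------------------------------------------
# Manifest / caching
# ---------------------------------------------------------------------------


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(params_snapshot: dict, input_hashes: dict) -> str:
    blob = json.dumps({"params": params_snapshot, "inputs": input_hashes}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.stages, indent=2, sort_keys=True, default=str)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order, with caching.

    On rerun with unchanged inputs and parameters a stage is skipped
    ("skipped (cached)"); corrupting an intermediate file invalidates only the
    stages downstream of it.  A failure aborts with the stage name; partial
    outputs are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    config.phantom.seed = config.seed

    runners = {
        "phantom": _stage_phantom,
        "contour": _stage_contour,
        "dents": _stage_dents,
        "segment": _stage_segment,
        "trace": _stage_trace,
        "quant": _stage_quant,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            params_snapshot, inputs, outputs = runners[stage](config, out, dry=True)
            input_hashes = {str(p): _hash_file(Path(p)) for p in inputs if Path(p).exists()}
            key = _stage_key(params_snapshot, input_hashes)
            stage_meta = out / stage / "stage.json"
            cached = False
            if config.resume and stage_meta.exists():
                prev = json.loads(stage_meta.read_text())
                cached = prev.get("key") == key and all(Path(p).exists() for p in prev["outputs"])
            if cached:
                status = "skipped (cached)"
                log.info("stage %s: %s", stage, status)
                outputs = prev["outputs"]
                stage_warnings = prev.get("warnings", [])
            else:
                with warnings.catch_warnings(record=True) as wrec:
                    warnings.simplefilter("always")
                    _, _, outputs = runners[stage](config, out, dry=False)
                stage_warnings = [str(w.message) for w in wrec]
                status = "completed"
                stage_meta.parent.mkdir(parents=True, exist_ok=True)
                stage_meta.write_text(
                    json.dumps(
                        {"key": key, "outputs": [str(o) for o in outputs], "warnings": stage_warnings},
                        indent=2,
                    )
                )
                log.info("stage %s: completed in %.2fs", stage, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            raise StageFailure(stage, exc) from exc
        manifest.stages[stage] = {
            "status": status,
            "params": params_snapshot,
            "input_hashes": input_hashes,
            "outputs": [str(o) for o in outputs],
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "warnings": stage_warnings,
        }
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# --- stage implementations --------------------------------------------------


def _stage_phantom(cfg: PipelineConfig, out: Path, dry: bool):
    params = asdict(cfg.phantom)
    stage_dir = out / "phantom"
    outputs = [stage_dir / name for name in phantom_mod._FILES.values()]
    if not dry:
        scene = phantom_mod.make_phantom(cfg.phantom)
        phantom_mod.scene_to_disk(scene, stage_dir)
    return params, [], outputs


def _stage_contour(cfg: PipelineConfig, out: Path, dry: bool):
    params = asdict(cfg.contour)
    src = out / "phantom" / "intensity.tif"
    stage_dir = out / "contour"
    outputs = [stage_dir / "brain_mask_est.tif"]
    if not dry:
        stack = ImageStack(read_volume(src), cfg.phantom.voxel_size_um)
        mask = contour_mod.binarize_brain(stack, cfg.contour)
        write_volume(mask.voxels, outputs[0])
    return params, [src], outputs


def _stage_dents(cfg: PipelineConfig, out: Path, dry: bool):
    params = {"closing_disc_radius_px": cfg.contour.closing_disc_radius_px,
              "skeleton": asdict(cfg.skeleton)}
    src = out / "contour" / "brain_mask_est.tif"
    stage_dir = out / "dents"
    outputs = [stage_dir / "dents.tif", stage_dir / "pial.swc"]
    if not dry:
        mask = BinaryVolume(read_volume(src) > 0, cfg.phantom.voxel_size_um, "brain_mask")
        dents = contour_mod.extract_dents(mask, cfg.contour.closing_disc_radius_px)
        write_volume(dents.voxels, outputs[0])
        pial = graph_mod.trace_dents(dents, cfg.skeleton)
        graph_mod.write_swc(pial, outputs[1])
    return params, [src], outputs


def _stage_segment(cfg: PipelineConfig, out: Path, dry: bool):
    params = asdict(cfg.segment)
    src_img = out / "phantom" / "intensity.tif"
    src_truth = out / "phantom" / "vessel_mask.tif"
    src_swc = out / "phantom" / "truth.swc"
    stage_dir = out / "segment"
    outputs = [stage_dir / "vessel_labels_est.tif", stage_dir / "calibration.json"]
    src_brain = out / "phantom" / "brain_mask.tif"
    if not dry:
        stack = ImageStack(read_volume(src_img), cfg.phantom.voxel_size_um)
        truth = BinaryVolume(read_volume(src_truth) > 0, cfg.phantom.voxel_size_um, "vessel_mask")
        brain = read_volume(src_brain) > 0
        # calibrate on a represented interior cube (tissue + vessels, no
        # outside-brain background), like a manually cropped evaluation stack
        sh = np.asarray(stack.shape)
        lo_i = (sh * 0.3).astype(int)
        hi_i = (sh * 0.7).astype(int)
        crop = tuple(slice(a, b) for a, b in zip(lo_i, hi_i))
        sub = ImageStack(stack.voxels[crop], cfg.phantom.voxel_size_um)
        sub_truth = BinaryVolume(truth.voxels[crop], cfg.phantom.voxel_size_um, "vessel_mask")
        mean = float(sub.voxels.mean())
        lo, hi = cfg.segment.candidate_offsets
        candidates = [int(round(mean)) + k for k in range(lo, hi + 1)]
        cal = segment_mod.calibrate_threshold(sub, sub_truth, candidates)
        t = segment_mod.select_min_threshold(cal, cfg.segment.recall_min, cfg.segment.precision_min)
        # seeds: the root node of every penetrating tree in the ground truth
        # (inside the brain, radius above capillary scale; pial paths sit in
        # surface dents and capillaries are thinner than a voxel)
        tg = graph_mod.read_swc(src_swc)
        grown = []
        vs = np.asarray(cfg.phantom.voxel_size_um)
        min_seed_radius = 1.5 * float(vs.min())
        for vid, k in enumerate(tg.roots(), start=1):
            pos = np.rint(np.array([tg.z[k], tg.y[k], tg.x[k]]) / vs).astype(int)
            pos = tuple(np.clip(pos, 0, np.asarray(stack.shape) - 1))
            if not brain[pos] or tg.radius[k] < min_seed_radius:
                continue
            if stack.voxels[pos] < t:
                continue  # noise dropped the seed voxel below threshold
            seed = segment_mod.SeedPoint(pos, vessel_id=vid)
            vol = segment_mod.region_grow(stack, seed, t, cfg.segment.connectivity)
            if vol.count() > 0.5 * int(brain.sum()):
                warnings.warn(
                    f"seed {pos}: grown region covers background, discarded", stacklevel=2
                )
                continue
            grown.append((vol, seed))
        labels, conflicts = segment_mod.assign_vessel_labels(
            grown, shape=stack.shape, voxel_size_um=cfg.phantom.voxel_size_um
        )
        write_volume(labels.voxels, outputs[0])
        report = cal.to_frame().to_dict(orient="list")
        report.update(
            {"selected_threshold": t, "image_mean": cal.image_mean,
             "offset_above_mean": t - cal.image_mean, "label_conflicts": conflicts}
        )
        outputs[1].parent.mkdir(parents=True, exist_ok=True)
        outputs[1].write_text(json.dumps(report, indent=2))
    return params, [src_img, src_truth, src_brain, src_swc], outputs


def _stage_trace(cfg: PipelineConfig, out: Path, dry: bool):
    params = asdict(cfg.skeleton)
    src = out / "segment" / "vessel_labels_est.tif"
    stage_dir = out / "trace"
    outputs = [stage_dir / "traced.swc", stage_dir / "skeleton.tif"]
    if not dry:
        from scipy import ndimage

        labels = read_volume(src)
        # fill interior noise holes: sub-threshold speckle inside a lumen would
        # otherwise truncate the inscribed-sphere radii
        filled_mask = ndimage.binary_fill_holes(labels > 0)
        mask = BinaryVolume(filled_mask, cfg.phantom.voxel_size_um, "vessel_mask")
        skel = graph_mod.skeletonize(mask, cfg.skeleton)
        write_volume(skel.voxels, outputs[1])
        g = graph_mod.build_graph(skel, cfg.skeleton)
        g = graph_mod.estimate_radii(g, mask, cfg.skeleton)
        graph_mod.write_swc(g, outputs[0])
    return params, [src], outputs


def _stage_quant(cfg: PipelineConfig, out: Path, dry: bool):
    params = asdict(cfg.quant)
    src_truth = out / "phantom" / "vessel_mask.tif"
    src_brain = out / "phantom" / "brain_mask.tif"
    src_regions = out / "phantom" / "region_labels.tif"
    src_vlabels = out / "phantom" / "vessel_labels.tif"
    src_seg = out / "segment" / "vessel_labels_est.tif"
    src_swc = out / "trace" / "traced.swc"
    stage_dir = out / "quant"
    outputs = [
        stage_dir / "density.csv",
        stage_dir / "distribution.csv",
        stage_dir / "validation.csv",
        stage_dir / "branch_levels.csv",
        stage_dir / "summary.json",
    ]
    if not dry:
        stage_dir.mkdir(parents=True, exist_ok=True)
        vs = cfg.phantom.voxel_size_um
        truth = BinaryVolume(read_volume(src_truth) > 0, vs, "vessel_mask")
        regions = LabelVolume(read_volume(src_regions).astype(np.uint16), vs)
        vlabels = LabelVolume(read_volume(src_vlabels).astype(np.uint16), vs)
        traced = graph_mod.read_swc(src_swc)

        rep = quant_mod.density_report(traced, regions, shrinkage=cfg.quant.shrinkage)
        dens = rep.fv.add_prefix("fv_").join(rep.nl.add_prefix("nl_"))
        dens.to_csv(outputs[0], index_label="region")

        # vessel lumina carry no region label: attribute them to the nearest
        # region within the brain + vessel domain before counting
        brain = read_volume(src_brain) > 0
        filled = LabelVolume(
            quant_mod.fill_region_labels(regions, domain=brain | truth.voxels).astype(np.uint16),
            vs,
        )
        dist = quant_mod.distribution_proportions(vlabels, filled)
        dist.frame.to_csv(outputs[1], index_label="vessel")

        # validate the vectorization against the mask it traced
        seg_mask = BinaryVolume(read_volume(src_seg) > 0, vs, "vessel_mask")
        val = quant_mod.validate_tracing(traced, seg_mask, cfg.quant.validation_interval_um)
        val.per_slice.to_csv(outputs[2], index=False)

        levels = quant_mod.count_branch_levels(traced)
        levels.to_csv(outputs[3])

        summary = {
            "validation": {
                "pooled_recall": val.pooled_recall,
                "pooled_precision": val.pooled_precision,
                "pooled_diameter_ratio": val.pooled_diameter_ratio,
            },
            "shrinkage": cfg.quant.shrinkage,
            "total_traced_length_mm": traced.total_length_um() / 1000.0,
        }
        outputs[4].write_text(json.dumps(summary, indent=2))
    return params, [src_truth, src_brain, src_regions, src_vlabels, src_seg, src_swc], outputs
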