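"""End-to-end orchestration with reproducible configuration.

The stage order mirrors the analysis: train → classify → threshold →
fiber split → watershed → measure → fluorescence count → summarize.  A run
directory always contains the exact configuration that produced it, every
stage's tables, and a structured log; re-running an identical configuration
reproduces byte-identical tables and summaries.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from . import io as dio
from .classify import classify, compute_features, sample_scribbles, train_classifier
from .fluor import match_stained_to_particles, quantify_stained
from .metrics import measure_particles, particles_to_frame
from .segment import segment_debris_map
from .specs import (
    AcquisitionSpec,
    FilterSpec,
    Micrograph,
    SampleConfig,
    SceneSpec,
    spec_to_dict,
)
from .summary import IMAGE_COLUMNS, summarize
from .synth import generate_scene

__all__ = [
    "RunConfig",
    "run_pipeline",
    "PipelineStageError",
    "ConfigError",
    "rescale_for_segmentation",
]

#: Images wider than this are downscaled before classification; the scale
#: factor propagates to metrology through the adjusted pixel scale.
MAX_SEGMENTATION_WIDTH = 2000


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage
        self.detail = detail


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "images"
    seed: int = 0
    n_replicates: int = 3
    images_per_replicate: int = 3
    scene: SceneSpec = field(default_factory=SceneSpec)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    acq_dic: AcquisitionSpec = field(default_factory=AcquisitionSpec.dic)
    acq_fluo: AcquisitionSpec = field(default_factory=AcquisitionSpec.fluorescence)
    sample: SampleConfig = field(default_factory=SampleConfig)
    classifier_mode: str = "random_forest"  # or "idealized" (synthetic only)
    n_trees: int = 200
    scales: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    scribble_regions: int = 8
    images: Tuple[str, ...] = ()
    fluo_images: Tuple[str, ...] = ()
    scribbles_path: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "images"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "images":
            if not self.images:
                raise ConfigError("mode 'images' requires a nonempty image list")
            if self.scribbles_path is None and self.classifier_mode == "random_forest":
                raise ConfigError("mode 'images' requires a scribbles file")
            for p in list(self.images) + list(self.fluo_images):
                if not Path(p).exists():
                    raise ConfigError(f"input image {p} does not exist")
        if self.classifier_mode not in ("random_forest", "idealized"):
            raise ConfigError(f"unknown classifier_mode {self.classifier_mode!r}")
        if self.classifier_mode == "idealized" and self.mode != "synthetic":
            raise ConfigError("idealized debris maps exist only for synthetic scenes")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            sd = dict(d["scene"])
            from .specs import NoiseModel, SizeDistribution

            if isinstance(sd.get("size_distribution"), dict):
                sd["size_distribution"] = SizeDistribution(**sd["size_distribution"])
            if isinstance(sd.get("noise_model"), dict):
                sd["noise_model"] = NoiseModel(**sd["noise_model"])
            if sd.get("fiber_diameters_um") is not None:
                sd["fiber_diameters_um"] = tuple(sd["fiber_diameters_um"])
            d["scene"] = SceneSpec(**sd)
        for key, cls in (
            ("filter_spec", FilterSpec),
            ("sample", SampleConfig),
        ):
            if isinstance(d.get(key), dict):
                kw = dict(d[key])
                if "window_dims_mm" in kw:
                    kw["window_dims_mm"] = tuple(kw["window_dims_mm"])
                d[key] = cls(**kw)
        for key in ("acq_dic", "acq_fluo"):
            if isinstance(d.get(key), dict):
                kw = dict(d[key])
                if kw.get("image_shape") is not None:
                    kw["image_shape"] = tuple(kw["image_shape"])
                d[key] = AcquisitionSpec(**kw)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        for key in ("images", "fluo_images"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return RunConfig(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert tuples/numpy scalars for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def rescale_for_segmentation(
    img: Micrograph, max_width: int = MAX_SEGMENTATION_WIDTH
) -> Tuple[Micrograph, float]:
    """Downscale images wider than ``max_width`` px, preserving aspect.

    Returns the (possibly unchanged) image and the applied scale factor;
    the image's pixel scale is adjusted so metrology stays in μm.
    """
    h, w = img.data.shape[-2:]
    if w <= max_width:
        return img, 1.0
    factor = max_width / w
    new_shape = (int(round(h * factor)), max_width)
    data = resize(img.data, new_shape, preserve_range=True, anti_aliasing=True)
    return Micrograph(data, img.pixel_scale * factor, img.modality), factor


def _field_area_fraction(
    acq: AcquisitionSpec, filter_spec: FilterSpec, n_images: int
) -> float:
    """Fraction of the active area covered by ``n_images`` fields of view."""
    h, w = acq.image_shape
    field_mm2 = (h / acq.pixel_scale / 1000.0) * (w / acq.pixel_scale / 1000.0)
    return min(1.0, n_images * field_mm2 / filter_spec.active_area_mm2)


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute the full pipeline into ``out_dir`` and return that path.

    Stage failures raise :class:`PipelineStageError` naming the stage; any
    partial outputs stay in place next to a ``FAILED`` marker.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_entries: List[dict] = []

    def stage(name: str, fn, *a, **kw):
        t0 = time.perf_counter()
        try:
            result = fn(*a, **kw)
        except Exception as exc:  # noqa: BLE001 - report stage and re-raise
            (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineStageError(name, str(exc)) from exc
        log_entries.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    cfg.to_yaml(out / "run_config.yaml")

    if cfg.mode == "synthetic":
        replicate_tables = stage("analyze", _run_synthetic, cfg, out)
        n_images = cfg.n_replicates * cfg.images_per_replicate
        frac = _field_area_fraction(cfg.acq_dic, cfg.filter_spec, cfg.images_per_replicate)
    else:
        replicate_tables = stage("analyze", _run_images, cfg, out)
        n_images = len(cfg.images)
        frac = _field_area_fraction(cfg.acq_dic, cfg.filter_spec, n_images)

    sample_cfg = SampleConfig(
        filtered_volume_ml=cfg.sample.filtered_volume_ml,
        daily_consumption_ml=cfg.sample.daily_consumption_ml,
        imaged_area_fraction=frac,
        n_replicates=len(replicate_tables),
        outlier_factor=cfg.sample.outlier_factor,
        density_low_g_cm3=cfg.sample.density_low_g_cm3,
        density_high_g_cm3=cfg.sample.density_high_g_cm3,
        stage=cfg.sample.stage,
    )
    summary = stage("summarize", summarize, replicate_tables, sample_cfg)
    dio.write_json(out / "summary.json", summary.to_dict())

    tidy = _tidy_frame(summary, cfg)
    dio.write_table(out / "summary_long.csv", tidy)
    dio.write_json(out / "run.log.json", {"stages": log_entries})
    return out


def _analyze_one(
    dic_img: Micrograph,
    fluo_img: Optional[Micrograph],
    debris_map: np.ndarray,
    acq_dic: AcquisitionSpec,
    acq_fluo: AcquisitionSpec,
    image_id: str,
    out: Path,
) -> dict:
    seg = segment_debris_map(debris_map, acq_dic)
    particles = measure_particles(seg.particle_labels, acq_dic)
    stained_count = 0
    stained_volume = 0.0
    if fluo_img is not None:
        stained_set = quantify_stained(fluo_img, acq_fluo)
        particles, unmatched = match_stained_to_particles(stained_set, particles)
        stained_count = stained_set.count
        stained_volume = sum(r.volume_um3 for r in stained_set.records)
    frame = particles_to_frame(particles)
    dio.write_table(out / f"{image_id}_particles.csv", frame)
    fiber_frame = pd.DataFrame(
        [
            {
                "id": i + 1,
                "diameter_um": fb.diameter_um,
                "size_bin": fb.size_bin,
                "length_um": fb.length_um,
            }
            for i, fb in enumerate(seg.fibers)
        ],
        columns=["id", "diameter_um", "size_bin", "length_um"],
    )
    dio.write_table(out / f"{image_id}_fibers.csv", fiber_frame)
    return {
        "image_id": image_id,
        "particle_count": len(particles),
        "fiber_count": len(seg.fibers),
        "stained_count": stained_count,
        "total_volume_um3": float(frame["volume_um3"].sum()) if len(frame) else 0.0,
        "stained_volume_um3": stained_volume,
    }


def _run_synthetic(cfg: RunConfig, out: Path) -> List[pd.DataFrame]:
    from dataclasses import replace

    tables: List[pd.DataFrame] = []
    clf = None
    for r in range(cfg.n_replicates):
        rows = []
        for i in range(cfg.images_per_replicate):
            seed = (cfg.seed * 9973 + r * 131 + i) % (2**31)
            scene = generate_scene(
                replace(cfg.scene, seed=seed), cfg.filter_spec, cfg.acq_dic, cfg.acq_fluo
            )
            if cfg.classifier_mode == "random_forest":
                if clf is None:  # one classifier per sample, applied to all images
                    feats = compute_features(scene.dic_image.data, cfg.scales)
                    scribbles = sample_scribbles(
                        scene.class_map, n_regions=cfg.scribble_regions, seed=seed
                    )
                    clf = train_classifier(
                        feats, scribbles, n_trees=cfg.n_trees, seed=cfg.seed
                    )
                prob = classify(scene.dic_image, clf)
                debris_map = prob["particle"]
            else:
                debris_map = scene.synthetic_debris_probability()
            acq_fluo = AcquisitionSpec.fluorescence(image_shape=scene.fluo_shape)
            rows.append(
                _analyze_one(
                    scene.dic_image,
                    scene.fluo_image,
                    debris_map,
                    cfg.acq_dic,
                    acq_fluo,
                    f"rep{r}_img{i}",
                    out,
                )
            )
        tables.append(pd.DataFrame(rows, columns=list(IMAGE_COLUMNS)))
    return tables


def _run_images(cfg: RunConfig, out: Path) -> List[pd.DataFrame]:
    from .io import read_image, read_scribbles_csv

    imgs = [read_image(p, cfg.acq_dic.pixel_scale, "brightfield_dic") for p in cfg.images]
    fluo = [
        read_image(p, cfg.acq_fluo.pixel_scale, "fluorescence") for p in cfg.fluo_images
    ]
    img0, _ = rescale_for_segmentation(imgs[0])
    feats = compute_features(img0.data, cfg.scales)
    scribbles = read_scribbles_csv(cfg.scribbles_path, img0.data.shape)
    clf = train_classifier(feats, scribbles, n_trees=cfg.n_trees, seed=cfg.seed)
    rows = []
    for i, img in enumerate(imgs):
        img_s, _ = rescale_for_segmentation(img)
        prob = classify(img_s, clf)
        acq = AcquisitionSpec(
            pixel_scale=img_s.pixel_scale, modality="brightfield_dic", image_shape=img_s.data.shape
        )
        fl = fluo[i] if i < len(fluo) else None
        rows.append(
            _analyze_one(img_s, fl, prob["particle"], acq, cfg.acq_fluo, f"img{i}", out)
        )
    return [pd.DataFrame(rows, columns=list(IMAGE_COLUMNS))]


def _tidy_frame(summary, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    d = summary.to_dict()
    for metric in (
        "particle_concentration_per_ml",
        "particle_concentration_sem",
        "fiber_concentration_per_ml",
        "stained_fraction_pct",
        "mean_particle_volume_um3",
        "total_stained_volume_um3",
        "mass_low_ng",
        "mass_high_ng",
        "daily_exposure_per_day",
    ):
        rows.append(
            {
                "sample": "synthetic" if cfg.mode == "synthetic" else "images",
                "stage": summary.stage,
                "metric": metric,
                "value": d[metric],
            }
        )
    return pd.DataFrame(rows, columns=["sample", "stage", "metric", "value"])
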