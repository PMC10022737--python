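"""Domain types describing the filter, the microscopes, and the sample.

Physical conventions used throughout the package:

* lengths in micrometres (μm) unless a suffix says otherwise,
* pixel scales in pixels per micrometre (px/μm),
* images are 2-D ``float64`` arrays in ``[0, 1]``, row-major, 0-based,
  half-open bounds; physical coordinates are measured in μm from the
  image's top-left corner (``x`` along columns, ``y`` along rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FilterSpec",
    "AcquisitionSpec",
    "SizeDistribution",
    "NoiseModel",
    "SceneSpec",
    "SampleConfig",
    "Micrograph",
    "DIC_PIXEL_SCALE",
    "FLUO_PIXEL_SCALE",
    "CLASS_NAMES",
    "GeometryError",
]

#: Default pixel scales of the two imaging modalities (px/μm).
DIC_PIXEL_SCALE = 2.5625
FLUO_PIXEL_SCALE = 0.6107

#: The five pixel classes, in canonical order.  ``class_map`` images use the
#: index into this tuple as the per-pixel code.
CLASS_NAMES: Tuple[str, ...] = ("particle", "slot", "residue", "membrane", "edge")


class GeometryError(ValueError):
    """Raised when the requested raster cannot represent the filter geometry."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class FilterSpec:
    """Geometry of a microslit silicon nanomembrane filter.

    Defaults describe an ultrathin (400 nm) SiN membrane with 8 μm wide slit
    pores, three 0.7 × 3.0 mm windows and 6.3 mm² of active (porous) area.
    The centre-to-centre slit pitch is not a property of the chip's data
    sheet here; 20 μm keeps porosity above 10% and is configurable.
    """

    slit_width_um: float = 8.0
    membrane_thickness_nm: float = 400.0
    window_dims_mm: Tuple[float, float] = (0.7, 3.0)
    n_windows: int = 3
    active_area_mm2: float = 6.3
    slit_pitch_um: float = 20.0

    def __post_init__(self) -> None:
        if self.slit_width_um <= 0:
            raise ValueError("slit_width_um must be > 0")
        if self.active_area_mm2 <= 0:
            raise ValueError("active_area_mm2 must be > 0")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.slit_pitch_um <= self.slit_width_um:
            raise ValueError("slit_pitch_um must exceed slit_width_um")

    def slit_width_px(self, pixel_scale: float) -> int:
        """Nearest-integer rasterized slit width at ``pixel_scale`` px/μm."""
        return _round_half_up(self.slit_width_um * pixel_scale)

    def slit_pitch_px(self, pixel_scale: float) -> int:
        return _round_half_up(self.slit_pitch_um * pixel_scale)


@dataclass(frozen=True)
class AcquisitionSpec:
    """How a channel was (or is to be) acquired.

    ``imaged_area_fraction`` is the fraction of the filter's active area
    covered by the analysed images; counts are scaled up by its inverse
    before being normalised to the filtered volume.
    """

    pixel_scale: float
    modality: str = "brightfield_dic"
    image_shape: Optional[Tuple[int, int]] = (512, 512)
    imaged_area_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if not (0.0 < self.imaged_area_fraction <= 1.0):
            raise ValueError("imaged_area_fraction must be in (0, 1]")
        if self.modality not in ("brightfield_dic", "fluorescence"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @staticmethod
    def dic(**kw) -> "AcquisitionSpec":
        kw.setdefault("pixel_scale", DIC_PIXEL_SCALE)
        kw.setdefault("modality", "brightfield_dic")
        return AcquisitionSpec(**kw)

    @staticmethod
    def fluorescence(**kw) -> "AcquisitionSpec":
        kw.setdefault("pixel_scale", FLUO_PIXEL_SCALE)
        kw.setdefault("modality", "fluorescence")
        kw.setdefault("image_shape", None)  # derived from the DIC field of view
        return AcquisitionSpec(**kw)


@dataclass(frozen=True)
class SizeDistribution:
    """Log-normal equivalent-diameter distribution, truncated to a support.

    The default (median 2 μm, σ_log 0.6, support [0.5, 25] μm) is heavily
    skewed toward the smallest observable particles (~1 μm).
    """

    median_um: float = 2.0
    sigma_log: float = 0.6
    min_um: float = 0.5
    max_um: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.min_um < self.max_um):
            raise ValueError("require 0 < min_um < max_um")
        if self.median_um <= 0 or self.sigma_log <= 0:
            raise ValueError("median_um and sigma_log must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` diameters (μm) by rejection against the support."""
        out = np.empty(0)
        while out.size < n:
            d = rng.lognormal(np.log(self.median_um), self.sigma_log, size=max(n, 16))
            d = d[(d >= self.min_um) & (d <= self.max_um)]
            out = np.concatenate([out, d])
        return out[:n]


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian sensor noise plus a low-order illumination gradient.

    ``sigma`` is expressed as a fraction of the dynamic range.
    """

    sigma: float = 0.02
    gradient_amplitude: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.gradient_amplitude < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic debris-laden field of view."""

    n_particles: int = 150
    size_distribution: SizeDistribution = field(default_factory=SizeDistribution)
    aggregate_fraction: float = 0.15
    n_fibers: int = 2
    fiber_diameters_um: Optional[Sequence[float]] = None
    fibers_span_fov: bool = True
    stained_fraction: float = 0.03
    residue_patches: int = 4
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0 or self.n_fibers < 0 or self.residue_patches < 0:
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.stained_fraction <= 1.0):
            raise ValueError("stained_fraction must be in [0, 1]")
        if not (0.0 <= self.aggregate_fraction <= 1.0):
            raise ValueError("aggregate_fraction must be in [0, 1]")
        if self.fiber_diameters_um is not None:
            if len(self.fiber_diameters_um) != self.n_fibers:
                raise ValueError("fiber_diameters_um length must equal n_fibers")
            if any(d <= 0 for d in self.fiber_diameters_um):
                raise ValueError("all fiber diameters must be > 0")


@dataclass(frozen=True)
class SampleConfig:
    """Normalisation constants for per-sample reporting.

    50 mL filtered per sample and a 500 mL/day consumption scenario are the
    study defaults; ``outlier_factor`` automates the "orders of magnitude"
    exclusion of anomalous images (×10 by default, ``inf`` disables).
    """

    filtered_volume_ml: float = 50.0
    daily_consumption_ml: float = 500.0
    imaged_area_fraction: float = 1.0
    n_replicates: int = 3
    outlier_factor: float = 10.0
    density_low_g_cm3: float = 0.8
    density_high_g_cm3: float = 1.8
    stage: str = "filtered"

    def __post_init__(self) -> None:
        if self.filtered_volume_ml <= 0:
            raise ValueError("filtered_volume_ml must be > 0")
        if not (0.0 < self.imaged_area_fraction <= 1.0):
            raise ValueError("imaged_area_fraction must be in (0, 1]")
        if self.outlier_factor < 1:
            raise ValueError("outlier_factor must be >= 1")


@dataclass
class Micrograph:
    """A single-channel image plus the acquisition metadata needed downstream."""

    data: np.ndarray
    pixel_scale: float
    modality: str = "brightfield_dic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("Micrograph data must be 2-D (or 3-D for a z-stack)")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def to_um(self, px: float) -> float:
        return px / self.pixel_scale


def spec_to_dict(spec) -> dict:
    """Serializable view of any of the frozen spec dataclasses."""
    return asdict(spec)
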