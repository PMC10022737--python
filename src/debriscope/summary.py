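"""Per-sample reporting: concentrations, stained fraction, mass, exposure.

Counts from the imaged fields are scaled up to the filter's full active
area (divide by the imaged-area fraction), then normalised to the filtered
water volume.  Replicate dispersion is reported as the standard error of
the mean over replicate concentrations (never pooled images).  Images whose
particle count departs from the replicate median by more than a
configurable factor (×10 by default — an automated analogue of the manual
"orders of magnitude" exclusions) are flagged and excluded, never silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import mass_band
from .specs import SampleConfig

__all__ = [
    "concentration",
    "daily_exposure",
    "flag_outliers",
    "summarize",
    "SampleSummary",
    "ExcludedImage",
    "IMAGE_COLUMNS",
    "ConsistencyError",
]

log = logging.getLogger(__name__)

#: Per-image rows consumed by :func:`summarize`.
IMAGE_COLUMNS = (
    "image_id",
    "particle_count",
    "fiber_count",
    "stained_count",
    "total_volume_um3",
    "stained_volume_um3",
)


class ConsistencyError(ValueError):
    """Stained counts present where the total concentration is zero."""


def concentration(count: float, imaged_area_fraction: float, filtered_volume_ml: float) -> float:
    """Objects per mL of filtered water.

    Counts are scaled to the full active area before dividing by volume:
    ``count / (imaged_area_fraction × filtered_volume)``.
    """
    if not (0.0 < imaged_area_fraction <= 1.0):
        raise ValueError("imaged_area_fraction must be in (0, 1]")
    if filtered_volume_ml <= 0:
        raise ValueError("filtered_volume_ml must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / (imaged_area_fraction * filtered_volume_ml)


def daily_exposure(conc_per_ml: float, daily_consumption_ml: float = 500.0) -> float:
    """Objects ingested per day at the given consumption (mL/day)."""
    if conc_per_ml < 0 or daily_consumption_ml < 0:
        raise ValueError("inputs must be >= 0")
    return conc_per_ml * daily_consumption_ml


@dataclass
class ExcludedImage:
    replicate: int
    image_id: str
    count: float
    median: float
    reason: str


def flag_outliers(
    counts: Sequence[float], factor: float = 10.0, image_ids: Optional[Sequence] = None
) -> Tuple[List[int], List[ExcludedImage]]:
    """Indices of kept images and the excluded ones with reasons.

    An image is excluded when its count exceeds ``factor × median`` or falls
    below ``median / factor`` (for a positive median).  With fewer than 3
    images, or a zero median, nothing is excluded (a warning is logged in
    the former case; with a zero median there is no scale to judge against).
    ``factor = inf`` disables exclusion entirely.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    counts = list(counts)
    ids = list(image_ids) if image_ids is not None else list(range(len(counts)))
    if len(counts) < 3:
        log.warning("fewer than 3 images; outlier flagging skipped")
        return list(range(len(counts))), []
    med = float(np.median(counts))
    if med == 0 or not np.isfinite(factor):
        return list(range(len(counts))), []
    kept, excluded = [], []
    for i, c in enumerate(counts):
        if c > factor * med:
            excluded.append(
                ExcludedImage(0, str(ids[i]), c, med, f"count {c} > {factor} x median {med}")
            )
        elif c < med / factor:
            excluded.append(
                ExcludedImage(0, str(ids[i]), c, med, f"count {c} < median {med} / {factor}")
            )
        else:
            kept.append(i)
    return kept, excluded


@dataclass
class SampleSummary:
    """Per-sample concentrations and derived exposure/mass estimates."""

    particle_concentration_per_ml: float
    particle_concentration_sem: float
    fiber_concentration_per_ml: float
    fiber_concentration_sem: float
    stained_fraction_pct: float
    mean_particle_volume_um3: float
    total_stained_volume_um3: float
    mass_low_ng: float
    mass_high_ng: float
    daily_exposure_per_day: float
    n_replicates: int
    excluded_images: List[ExcludedImage] = field(default_factory=list)
    stage: str = "filtered"
    imaged_area_fraction: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_images"] = [asdict(e) for e in self.excluded_images]
        return d

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


def _sem(values: np.ndarray) -> float:
    """sd of replicate means / sqrt(N); 0 for a single replicate."""
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def summarize(replicates: Iterable[pd.DataFrame], cfg: SampleConfig) -> SampleSummary:
    """Aggregate per-image tables of each replicate into a sample summary.

    Each replicate is a DataFrame with :data:`IMAGE_COLUMNS`.  Outlier
    images are flagged per replicate on particle counts before any
    normalisation.  The stained/total volume totals are scaled to the full
    active area (divided by the imaged-area fraction) so the mass band
    refers to the whole membrane.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("at least one replicate is required")
    f = cfg.imaged_area_fraction
    v = cfg.filtered_volume_ml
    part_c, fib_c, stain_c = [], [], []
    excluded: List[ExcludedImage] = []
    tot_volume = 0.0
    tot_count = 0.0
    stained_volume = 0.0
    for ri, rep in enumerate(replicates):
        missing = set(IMAGE_COLUMNS) - set(rep.columns)
        if missing:
            raise ValueError(f"replicate {ri} lacks columns {sorted(missing)}")
        kept, exc = flag_outliers(
            rep["particle_count"].tolist(), cfg.outlier_factor, rep["image_id"].tolist()
        )
        for e in exc:
            e.replicate = ri
        excluded.extend(exc)
        sub = rep.iloc[kept]
        part_c.append(concentration(float(sub["particle_count"].sum()), f, v))
        fib_c.append(concentration(float(sub["fiber_count"].sum()), f, v))
        stain_c.append(concentration(float(sub["stained_count"].sum()), f, v))
        tot_volume += float(sub["total_volume_um3"].sum())
        tot_count += float(sub["particle_count"].sum())
        stained_volume += float(sub["stained_volume_um3"].sum())
    part_c, fib_c, stain_c = map(np.asarray, (part_c, fib_c, stain_c))
    mean_part = float(part_c.mean())
    mean_stain = float(stain_c.mean())
    if mean_part == 0 and mean_stain > 0:
        raise ConsistencyError("stained objects counted but total concentration is zero")
    stained_fraction = 100.0 * mean_stain / mean_part if mean_part > 0 else 0.0
    membrane_stained_volume = stained_volume / f
    mb = mass_band(membrane_stained_volume, cfg.density_low_g_cm3, cfg.density_high_g_cm3)
    return SampleSummary(
        particle_concentration_per_ml=mean_part,
        particle_concentration_sem=_sem(part_c),
        fiber_concentration_per_ml=float(fib_c.mean()),
        fiber_concentration_sem=_sem(fib_c),
        stained_fraction_pct=stained_fraction,
        mean_particle_volume_um3=tot_volume / tot_count if tot_count else 0.0,
        total_stained_volume_um3=membrane_stained_volume,
        mass_low_ng=mb.mass_low_ng,
        mass_high_ng=mb.mass_high_ng,
        daily_exposure_per_day=daily_exposure(mean_part, cfg.daily_consumption_ml),
        n_replicates=len(replicates),
        excluded_images=excluded,
        stage=cfg.stage,
        imaged_area_fraction=f,
    )
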