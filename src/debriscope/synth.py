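"""Synthetic micrographs of debris-laden microslit membranes with ground truth.

Every downstream stage of the pipeline (pixel classification, debris
thresholding, fiber extraction, watershed separation, metrology,
fluorescence counting) is validated against scenes produced here: a
patterned membrane background (slit openings, membrane, window edge),
polydisperse particulates skewed toward ~1 μm, touching aggregates,
curvilinear fibers spanning the field of view, diffuse residue patches, and
a co-registered fluorescence channel in which a configurable fraction of
particles is stained.

Photometric realism is explicitly not a goal — the brightfield channel only
approximates differential-interference relief with a signed bas-relief
term.  What the generator does guarantee is an exhaustive, exact ground
truth: a per-pixel object label map, a per-pixel class map over
{particle, slot, residue, membrane, edge}, and per-object truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .specs import (
    CLASS_NAMES,
    AcquisitionSpec,
    FilterSpec,
    GeometryError,
    Micrograph,
    SceneSpec,
)

__all__ = [
    "PackingError",
    "CLASS_CODES",
    "render_membrane",
    "generate_scene",
    "GroundTruthScene",
]

CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}
_PARTICLE = CLASS_CODES["particle"]
_SLOT = CLASS_CODES["slot"]
_RESIDUE = CLASS_CODES["residue"]
_MEMBRANE = CLASS_CODES["membrane"]
_EDGE = CLASS_CODES["edge"]

# Noiseless class intensities of the brightfield background (fraction of range).
_INTENSITY = {_EDGE: 0.82, _MEMBRANE: 0.55, _SLOT: 0.18}

_FLUO_BACKGROUND = 0.05
_FLUO_AMPLITUDE = 0.85
_FLUO_PSF_SIGMA = 0.6  # px; coarse low-NA epifluorescence blur


class PackingError(ValueError):
    """Requested debris load cannot be placed on the available membrane area."""


# ---------------------------------------------------------------------------
# membrane background


def _membrane_base(
    filter_spec: FilterSpec, acq: AcquisitionSpec, edge_width_um: float = 8.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless background image and its class map.

    The field of view sits inside one filter window with the window's
    silicon frame visible as an ``edge`` band along the left border; slits
    are vertical stripes of rasterized width ``round(slit_width × scale)``
    repeating at the slit pitch.
    """
    if acq.image_shape is None:
        raise ValueError("acquisition image_shape is required to render a membrane")
    h, w = acq.image_shape
    scale = acq.pixel_scale
    slit_px = filter_spec.slit_width_px(scale)
    pitch_px = filter_spec.slit_pitch_px(scale)
    if slit_px < 1:
        raise GeometryError(
            f"slit width {filter_spec.slit_width_um} um rasterizes to < 1 px "
            f"at {scale} px/um"
        )
    edge_px = int(np.floor(edge_width_um * scale + 0.5))
    x0 = edge_px + max(1, (pitch_px - slit_px) // 2)
    if x0 + slit_px > w:
        raise GeometryError(
            f"image width {w} px cannot contain one {slit_px} px slit "
            f"(first slit would end at {x0 + slit_px})"
        )

    class_map = np.full((h, w), _MEMBRANE, dtype=np.uint8)
    class_map[:, :edge_px] = _EDGE
    cols = np.arange(w)
    in_slit = (cols >= x0) & (((cols - x0) % pitch_px) < slit_px)
    class_map[:, in_slit] = _SLOT

    img = np.empty((h, w), dtype=np.float64)
    for code, value in _INTENSITY.items():
        img[class_map == code] = value
    return img, class_map


def render_membrane(
    filter_spec: FilterSpec,
    acq: AcquisitionSpec,
    seed: int,
    edge_width_um: float = 8.0,
    noise_sigma: float = 0.02,
    gradient_amplitude: float = 0.03,
) -> Tuple[Micrograph, np.ndarray]:
    """Render a debris-free membrane background.

    Returns the noisy micrograph and a class map containing only the
    ``slot``, ``membrane`` and ``edge`` classes.  Identical seeds produce
    bit-identical images.
    """
    base, class_map = _membrane_base(filter_spec, acq, edge_width_um)
    rng = np.random.default_rng(seed)
    img = np.clip(
        base
        + _illumination_gradient(base.shape, gradient_amplitude, rng)
        + rng.normal(0.0, noise_sigma, base.shape),
        0.0,
        1.0,
    )
    return Micrograph(img, acq.pixel_scale, acq.modality), class_map


def _illumination_gradient(
    shape: Tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = shape
    gx, gy = rng.uniform(-1.0, 1.0, size=2)
    yy, xx = np.mgrid[0:h, 0:w]
    return amplitude * (gx * (xx / max(w - 1, 1) - 0.5) + gy * (yy / max(h - 1, 1) - 0.5))


# ---------------------------------------------------------------------------
# object rasterization


def _ellipse_coverage(
    shape: Tuple[int, int],
    cx: float,
    cy: float,
    a_px: float,
    b_px: float,
    theta: float,
    supersample: int = 3,
) -> Tuple[slice, slice, np.ndarray]:
    """Anti-aliased coverage of a rotated ellipse inside its bounding box.

    Coverage per pixel is the fraction of a ``supersample × supersample``
    subgrid falling inside the ellipse.
    """
    h, w = shape
    r = max(a_px, b_px) + 1.5
    r0 = max(int(np.floor(cy - r)), 0)
    r1 = min(int(np.ceil(cy + r)) + 1, h)
    c0 = max(int(np.floor(cx - r)), 0)
    c1 = min(int(np.ceil(cx + r)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = (np.arange(r0, r1)[:, None] + offs[None, :]).ravel()
    xs = (np.arange(c0, c1)[:, None] + offs[None, :]).ravel()
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    n = supersample
    cov = inside.reshape(r1 - r0, n, c1 - c0, n).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _fiber_path(
    shape: Tuple[int, int], rng: np.random.Generator, span: bool
) -> Tuple[np.ndarray, np.ndarray]:
    """Sinusoidally perturbed polyline across (or inside) the field of view."""
    h, w = shape
    horizontal = bool(rng.integers(0, 2))
    n = 4 * max(h, w)
    t = np.linspace(0.0, 1.0, n)
    amp = rng.uniform(0.02, 0.08)
    periods = rng.uniform(0.8, 2.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    offset = rng.uniform(0.25, 0.75)
    if horizontal:
        x = t * (w - 1) if span else (0.15 + 0.7 * t) * (w - 1)
        y = np.clip(offset * h + amp * h * np.sin(2 * np.pi * periods * t + phase), 0, h - 1)
    else:
        y = t * (h - 1) if span else (0.15 + 0.7 * t) * (h - 1)
        x = np.clip(offset * w + amp * w * np.sin(2 * np.pi * periods * t + phase), 0, w - 1)
    return y, x


# ---------------------------------------------------------------------------
# the scene container


@dataclass
class GroundTruthScene:
    """A co-registered synthetic image pair plus exhaustive object tables."""

    dic_image: Micrograph
    fluo_image: Micrograph
    dic_noiseless: np.ndarray
    fluo_noiseless: np.ndarray
    label_map: np.ndarray
    class_map: np.ndarray
    particle_table: pd.DataFrame
    fiber_table: pd.DataFrame
    debris_coverage: np.ndarray
    scene_spec: SceneSpec
    filter_spec: FilterSpec
    acq_dic: AcquisitionSpec
    acq_fluo: AcquisitionSpec
    fluo_shape: Tuple[int, int] = field(default=(0, 0))

    def debris_mask(self) -> np.ndarray:
        return self.label_map > 0

    def synthetic_debris_probability(self) -> np.ndarray:
        """Idealized debris-class probability map for this scene.

        Emulates the output of a well-trained pixel classifier without
        running one: high probability on debris, low elsewhere, slightly
        blurred at object boundaries and perturbed by seeded noise.  Useful
        for exercising the thresholding/segmentation stages in isolation.
        """
        rng = np.random.default_rng(self.scene_spec.seed + 101)
        p = 0.08 + 0.84 * ndi.gaussian_filter(self.debris_coverage, 1.0)
        p = p + rng.normal(0.0, 0.02, p.shape)
        return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(
    scene: SceneSpec,
    filter_spec: Optional[FilterSpec] = None,
    acq_dic: Optional[AcquisitionSpec] = None,
    acq_fluo: Optional[AcquisitionSpec] = None,
) -> GroundTruthScene:
    """Generate one synthetic field of view with exhaustive ground truth.

    Deterministic: identical specs (including ``scene.seed``) yield
    bit-identical images and tables.  Raises :class:`PackingError` when the
    requested debris area exceeds 80% of the non-slot membrane area, and
    :class:`~debriscope.specs.GeometryError` for degenerate rasters.
    """
    filter_spec = filter_spec or FilterSpec()
    acq_dic = acq_dic or AcquisitionSpec.dic()
    acq_fluo = acq_fluo or AcquisitionSpec.fluorescence()
    base, class_map = _membrane_base(filter_spec, acq_dic)
    h, w = base.shape
    scale = acq_dic.pixel_scale
    rng = np.random.default_rng(scene.seed)

    label_map = np.zeros((h, w), dtype=np.int32)
    debris_field = np.zeros((h, w))  # signed contrast contributions
    debris_cov = np.zeros((h, w))  # geometric coverage in [0, 1]
    # over an open slit the membrane is absent, so debris lying there is lit
    # against the dark opening: contrast flips to bright regardless of sign
    slot_mask = class_map == _SLOT

    # --- fibers (placed first; particles avoid them) -----------------------
    n_fib = scene.n_fibers
    if scene.fiber_diameters_um is not None:
        fib_diam = np.asarray(scene.fiber_diameters_um, dtype=float)
    else:
        fib_diam = rng.uniform(3.0, 12.0, size=n_fib)
    fiber_rows: List[dict] = []
    fiber_mask_total = np.zeros((h, w), dtype=bool)
    for i in range(n_fib):
        fid = scene.n_particles + i + 1
        r_px = fib_diam[i] * scale / 2.0
        # rejection-sample a path that does not cross already-placed fibers,
        # so each fiber stays its own connected component (crossing fibers
        # would merge and be counted as one)
        for _ in range(50):
            y, x = _fiber_path((h, w), rng, scene.fibers_span_fov)
            path_mask = np.zeros((h, w), dtype=bool)
            path_mask[np.round(y).astype(int), np.round(x).astype(int)] = True
            dist = ndi.distance_transform_edt(~path_mask)
            cov = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
            mask = cov >= 0.5
            if not (ndi.binary_dilation(mask, iterations=2) & fiber_mask_total).any():
                break
        contrast = rng.uniform(0.18, 0.30) * (1 if rng.integers(0, 2) else -1)
        debris_field += np.where(slot_mask, abs(contrast), contrast) * cov
        debris_cov = np.maximum(debris_cov, cov)
        label_map[mask] = fid
        fiber_mask_total |= mask
        length_um = float(np.hypot(np.diff(x), np.diff(y)).sum() / scale)
        fiber_rows.append(
            {
                "id": fid,
                "diameter_um": float(fib_diam[i]),
                "path_length_um": length_um,
                "spans_fov": bool(scene.fibers_span_fov),
            }
        )
    fiber_avoid = (
        ndi.binary_dilation(fiber_mask_total, iterations=2)
        if fiber_mask_total.any()
        else fiber_mask_total
    )

    # --- particles ---------------------------------------------------------
    n = scene.n_particles
    diam = scene.size_distribution.sample(n, rng) if n else np.empty(0)
    aspect = rng.uniform(0.5, 1.0, size=n)
    theta = rng.uniform(0.0, np.pi, size=n)
    a_um = diam / 2.0 / np.sqrt(aspect)
    b_um = diam / 2.0 * np.sqrt(aspect)
    a_px, b_px = a_um * scale, b_um * scale

    non_slot = int(np.count_nonzero(class_map != _SLOT))
    requested = float(np.pi * (a_px * b_px).sum() + fiber_mask_total.sum())
    if requested > 0.8 * non_slot:
        raise PackingError(
            f"requested debris area {requested:.0f} px^2 exceeds 80% of the "
            f"non-slot area ({non_slot} px^2)"
        )

    n_agg = int(np.floor(scene.aggregate_fraction * n))
    centers = np.zeros((n, 2))  # (cy, cx) px
    agg_ids = np.zeros(n, dtype=np.int64)
    next_group = 1
    particle_rows: List[dict] = []
    for i in range(n):
        is_agg = i >= n - n_agg and i > 0
        margin = min(a_px[i] + 1.0, (min(h, w) - 2) / 2.0)
        placed = False
        for _ in range(200):
            if is_agg:
                j = int(rng.integers(0, i))
                r_i = np.sqrt(a_px[i] * b_px[i])
                r_j = np.sqrt(a_px[j] * b_px[j])
                phi = rng.uniform(0.0, 2 * np.pi)
                d = 0.8 * (r_i + r_j)
                cy = centers[j, 0] + d * np.sin(phi)
                cx = centers[j, 1] + d * np.cos(phi)
                if not (margin <= cy <= h - 1 - margin and margin <= cx <= w - 1 - margin):
                    continue
            else:
                cy = rng.uniform(margin, h - 1 - margin)
                cx = rng.uniform(margin, w - 1 - margin)
            rs, cs, cov = _ellipse_coverage((h, w), cx, cy, a_px[i], b_px[i], theta[i])
            if fiber_avoid.any() and fiber_avoid[rs, cs][cov >= 0.5].any():
                continue
            placed = True
            break
        if not placed:  # dense scene fallback: accept the last candidate
            rs, cs, cov = _ellipse_coverage((h, w), cx, cy, a_px[i], b_px[i], theta[i])
        centers[i] = (cy, cx)
        if is_agg:
            if agg_ids[j] == 0:
                agg_ids[j] = next_group
                next_group += 1
            agg_ids[i] = agg_ids[j]
        contrast = rng.uniform(0.18, 0.35) * (1 if rng.integers(0, 2) else -1)
        debris_field[rs, cs] += np.where(slot_mask[rs, cs], abs(contrast), contrast) * cov
        debris_cov[rs, cs] = np.maximum(debris_cov[rs, cs], cov)
        mask = cov >= 0.5
        sub = label_map[rs, cs]
        sub[mask] = i + 1
        label_map[rs, cs] = sub
        particle_rows.append(
            {
                "id": i + 1,
                "x_um": cx / scale,
                "y_um": cy / scale,
                "major_um": 2.0 * a_um[i],
                "minor_um": 2.0 * b_um[i],
                "stained": False,
                "aggregate_id": 0,
            }
        )
    for i in range(n):
        particle_rows[i]["aggregate_id"] = int(agg_ids[i])

    # --- staining ----------------------------------------------------------
    k = int(np.floor(scene.stained_fraction * n + 0.5))
    stained_ids = (
        np.sort(rng.choice(np.arange(1, n + 1), size=k, replace=False))
        if k
        else np.empty(0, dtype=int)
    )
    for sid in stained_ids:
        particle_rows[sid - 1]["stained"] = True

    # --- residue patches ---------------------------------------------------
    residue_field = np.zeros((h, w))
    for _ in range(scene.residue_patches):
        pr = rng.uniform(10.0, 28.0)
        cy = rng.uniform(pr, h - 1 - pr)
        cx = rng.uniform(pr, w - 1 - pr)
        s = int(2 * pr) + 1
        patch = ndi.gaussian_filter(rng.random((s, s)), pr / 4.0)
        yy, xx = np.mgrid[0:s, 0:s]
        disk = (yy - pr) ** 2 + (xx - pr) ** 2 <= pr**2
        patch = np.where(disk, patch, 0.0)
        thr = np.quantile(patch[disk], 0.55)
        blob = disk & (patch > thr)
        r0, c0 = int(cy - pr), int(cx - pr)
        rs = slice(max(r0, 0), min(r0 + s, h))
        cs = slice(max(c0, 0), min(c0 + s, w))
        brs = slice(rs.start - r0, rs.stop - r0)
        bcs = slice(cs.start - c0, cs.stop - c0)
        # residues are "non-uniform": a soft footprint plus a mottled texture
        soft = ndi.gaussian_filter(blob.astype(float), 1.5)
        mottle = ndi.gaussian_filter(rng.random((s, s)) - 0.5, 1.0) * blob
        residue_field[rs, cs] += 0.10 * soft[brs, bcs] + 0.25 * mottle[brs, bcs]
        region = class_map[rs, cs]
        sel = blob[brs, bcs] & (region == _MEMBRANE)
        region[sel] = _RESIDUE
        class_map[rs, cs] = region

    class_map = class_map.copy()
    class_map[label_map > 0] = _PARTICLE

    # --- brightfield compositing -------------------------------------------
    relief = 0.5 * (debris_field - np.roll(debris_field, (1, 1), axis=(0, 1)))
    dic_noiseless = np.clip(base + residue_field + 0.8 * debris_field + relief, 0.0, 1.0)
    nm = scene.noise_model
    dic_noisy = np.clip(
        dic_noiseless
        + _illumination_gradient((h, w), nm.gradient_amplitude, rng)
        + rng.normal(0.0, nm.sigma, (h, w)),
        0.0,
        1.0,
    )

    # --- fluorescence channel ----------------------------------------------
    sf = acq_fluo.pixel_scale
    if acq_fluo.image_shape is not None:
        fh, fw = acq_fluo.image_shape
    else:
        fh = max(1, int(np.floor(h * sf / scale + 0.5)))
        fw = max(1, int(np.floor(w * sf / scale + 0.5)))
    fluo_cov = np.zeros((fh, fw))
    for sid in stained_ids:
        row = particle_rows[sid - 1]
        cyf, cxf = row["y_um"] * sf, row["x_um"] * sf
        af = max(row["major_um"] / 2.0 * sf, 1e-3)
        bf = max(row["minor_um"] / 2.0 * sf, 1e-3)
        rs, cs, cov = _ellipse_coverage((fh, fw), cxf, cyf, af, bf, theta[sid - 1])
        if cov.size:
            fluo_cov[rs, cs] = np.maximum(fluo_cov[rs, cs], cov)
        # a sub-resolution emitter still lights up its containing pixel
        iy, ix = int(np.clip(round(cyf), 0, fh - 1)), int(np.clip(round(cxf), 0, fw - 1))
        fluo_cov[iy, ix] = max(fluo_cov[iy, ix], 0.75)
    # Exposure is set for the dye channel and stacks are max-projected, so
    # stained debris renders near-saturated with PSF-blurred skirts rather
    # than dimming with size.
    emitted = np.clip(
        2.5 * ndi.gaussian_filter(np.clip(fluo_cov, 0.0, 1.0), _FLUO_PSF_SIGMA), 0.0, 1.0
    )
    fluo_noiseless = _FLUO_BACKGROUND + _FLUO_AMPLITUDE * emitted
    fluo_noisy = np.clip(
        fluo_noiseless + rng.normal(0.0, 0.02, (fh, fw)), 0.0, 1.0
    )

    # --- truth tables -------------------------------------------------------
    area_counts = np.bincount(label_map.ravel(), minlength=n + n_fib + 1)
    particle_table = pd.DataFrame(
        particle_rows,
        columns=["id", "x_um", "y_um", "major_um", "minor_um", "stained", "aggregate_id"],
    )
    particle_table["rendered_area_px"] = area_counts[1 : n + 1] if n else np.empty(0, int)
    fiber_table = pd.DataFrame(
        fiber_rows, columns=["id", "diameter_um", "path_length_um", "spans_fov"]
    )
    fiber_table["rendered_area_px"] = (
        area_counts[n + 1 : n + n_fib + 1] if n_fib else np.empty(0, int)
    )

    return GroundTruthScene(
        dic_image=Micrograph(dic_noisy, scale, "brightfield_dic"),
        fluo_image=Micrograph(fluo_noisy, sf, "fluorescence"),
        dic_noiseless=dic_noiseless,
        fluo_noiseless=fluo_noiseless,
        label_map=label_map,
        class_map=class_map,
        particle_table=particle_table,
        fiber_table=fiber_table,
        debris_coverage=debris_cov,
        scene_spec=scene,
        filter_spec=filter_spec,
        acq_dic=acq_dic,
        acq_fluo=acq_fluo,
        fluo_shape=(fh, fw),
    )
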