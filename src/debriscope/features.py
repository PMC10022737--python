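"""Per-pixel feature stacks for trainable segmentation.

The recipe is fixed and self-describing: raw intensity plus, for each
Gaussian scale σ, the smoothed intensity, gradient magnitude, Laplacian,
and the two eigenvalues of the Hessian.  With the default four scales this
yields 1 + 4 × 5 = 21 features per pixel.  All filters use reflective
boundary handling, so interior pixels are translation equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import scipy.ndimage as ndi

__all__ = ["FeatureStack", "compute_features", "DEFAULT_SCALES"]

DEFAULT_SCALES: Tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)

_PER_SCALE = ("gauss", "gradmag", "laplace", "hess_max", "hess_min")


@dataclass
class FeatureStack:
    """Feature images of shape ``(n_features, H, W)`` plus their recipe."""

    data: np.ndarray
    names: Tuple[str, ...]
    scales: Tuple[float, ...]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def matrix(self) -> np.ndarray:
        """Pixels as rows: shape ``(H*W, n_features)``."""
        return self.data.reshape(self.n_features, -1).T

    def at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Feature vectors at the given pixel coordinates."""
        return self.data[:, rows, cols].T


def compute_features(img, scales: Sequence[float] = DEFAULT_SCALES) -> FeatureStack:
    """Compute the fixed per-pixel feature recipe of an image.

    ``img`` may be a 2-D array or a :class:`~debriscope.specs.Micrograph`.
    Deterministic given ``(img, scales)``.
    """
    data = np.asarray(getattr(img, "data", img), dtype=np.float64)
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {data.shape}")
    scales = tuple(float(s) for s in scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be nonempty and positive")

    planes = [data]
    names = ["intensity"]
    for s in scales:
        g = ndi.gaussian_filter(data, s, mode="reflect")
        dx = ndi.gaussian_filter(data, s, order=(0, 1), mode="reflect")
        dy = ndi.gaussian_filter(data, s, order=(1, 0), mode="reflect")
        hxx = ndi.gaussian_filter(data, s, order=(0, 2), mode="reflect")
        hyy = ndi.gaussian_filter(data, s, order=(2, 0), mode="reflect")
        hxy = ndi.gaussian_filter(data, s, order=(1, 1), mode="reflect")
        half_tr = (hxx + hyy) / 2.0
        disc = np.sqrt(((hxx - hyy) / 2.0) ** 2 + hxy**2)
        planes.extend([g, np.hypot(dx, dy), hxx + hyy, half_tr + disc, half_tr - disc])
        names.extend(f"{base}_s{s:g}" for base in _PER_SCALE)
    return FeatureStack(np.stack(planes), tuple(names), scales)
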