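"""Probability map -> discrete predicted cell centers.

Foreground probability is thresholded, connected components are labeled at
the configured connectivity, small components dropped, and each surviving
component reported as its probability-weighted centroid (sub-pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .unet import ProbabilityMap


@dataclass(frozen=True)
class DetectionConfig:
    prob_threshold: float = 0.5
    min_component_px: int = 2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class DetectionResult:
    image_id: str
    centers: np.ndarray  # (n, 2) float (x, y) at working resolution

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)

    @property
    def n_centers(self) -> int:
        return int(self.centers.shape[0])


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def extract_centers(pmap: ProbabilityMap, cfg: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """Threshold, label, filter, and return weighted component centroids."""
    fg = pmap.foreground
    binary = fg >= cfg.prob_threshold
    labels, n = ndimage.label(binary, structure=_STRUCTURES[cfg.connectivity])
    if n == 0:
        return DetectionResult(image_id=pmap.image_id, centers=np.empty((0, 2)))
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(binary, labels, idx)
    keep = idx[sizes >= cfg.min_component_px]
    if keep.size == 0:
        return DetectionResult(image_id=pmap.image_id, centers=np.empty((0, 2)))
    cms = ndimage.center_of_mass(fg, labels, keep)  # (row, col) weighted by prob
    centers = np.array([(c, r) for r, c in cms], dtype=np.float64)
    return DetectionResult(image_id=pmap.image_id, centers=centers)
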