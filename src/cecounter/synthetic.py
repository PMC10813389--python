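"""Synthetic phase-contrast-like monolayer images with known cell centers.

Cells are rendered as a Voronoi mosaic seeded at randomly placed centers:
bright polygonal interiors with mild radial shading, dark ~2 px boundaries
drawn at 30% of the interior intensity, an optional bright halo band just
inside each boundary, and additive Gaussian noise. Center counts are
Poisson-drawn from the target density and placed by dart throwing with a
minimum spacing of 0.8x the mean cell diameter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .dataset_io import AnnotatedImage, save_annotations, save_image

DENSITY_REGIMES = ("low", "middle", "high")

#: per-regime defaults: (target density cells/mm^2, mean cell radius um)
REGIME_DEFAULTS: dict[str, tuple[float, float]] = {
    "low": (500.0, 18.0),
    "middle": (1500.0, 11.0),
    "high": (3000.0, 8.0),
}

BOUNDARY_BAND_PX = 2.0     # width of the dark Voronoi-edge band
HALO_BAND_PX = 2.0         # width of the bright halo band inside the edge
BOUNDARY_LEVEL = 0.30      # boundary intensity as fraction of interior
INTERIOR_BASE = 200.0
SHADING_DEPTH = 35.0
HALO_GAIN = 45.0
MAX_PACKING = 0.9


class PlacementInfeasibleError(ValueError):
    """Requested density/spacing exceeds what the field can hold."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view."""

    width_px: int = 128
    height_px: int = 128
    target_density: float = 1500.0        # cells / mm^2
    density_regime: str = "middle"
    um_per_px: float = 2.0
    cell_radius_mean_um: float = 11.0
    cell_radius_cv: float = 0.15
    halo_strength: float = 0.5            # [0, 1]
    noise_sigma: float = 6.0              # gray levels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("width_px and height_px must be positive")
        if self.target_density <= 0:
            raise ValueError("target_density must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.density_regime not in DENSITY_REGIMES:
            raise ValueError(f"density_regime must be one of {DENSITY_REGIMES}")
        if not 0.0 <= self.halo_strength <= 1.0:
            raise ValueError("halo_strength must be in [0, 1]")
        if self.cell_radius_mean_um <= 0:
            raise ValueError("cell_radius_mean_um must be positive")

    @classmethod
    def for_regime(cls, regime: str, seed: int = 0, **overrides) -> "SceneSpec":
        density, radius = REGIME_DEFAULTS[regime]
        kw = dict(
            target_density=density,
            density_regime=regime,
            cell_radius_mean_um=radius,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def field_area_mm2(self) -> float:
        return self.width_px * self.height_px * (self.um_per_px / 1000.0) ** 2

    @property
    def min_spacing_px(self) -> float:
        diameter_px = 2.0 * self.cell_radius_mean_um / self.um_per_px
        return 0.8 * diameter_px


@dataclass
class SyntheticSample:
    image: np.ndarray        # uint8, shape (height_px, width_px)
    centers: np.ndarray      # (n, 2) float (x, y) pixel coordinates
    spec: SceneSpec

    def to_annotated(self, image_id: str, source: str = "manual") -> AnnotatedImage:
        return AnnotatedImage(
            image_id=image_id,
            pixels=self.image,
            centers=self.centers,
            source=source,
            um_per_px=self.spec.um_per_px,
        )


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Poisson-count dart throwing with a hard minimum spacing."""
    mean_count = spec.target_density * spec.field_area_mm2
    n = int(rng.poisson(mean_count))
    if mean_count >= 1.0:
        n = max(n, 1)
    spacing = spec.min_spacing_px
    packing = n * np.pi * (spacing / 2.0) ** 2 / (spec.width_px * spec.height_px)
    if packing > MAX_PACKING:
        raise PlacementInfeasibleError(
            f"packing fraction {packing:.2f} > {MAX_PACKING} "
            f"(n={n}, spacing={spacing:.1f} px): density unsatisfiable"
        )
    placed = np.empty((n, 2), dtype=np.float64)
    k = 0
    sq = spacing * spacing
    max_attempts = 2000 * max(n, 1)
    attempts = 0
    while k < n and attempts < max_attempts:
        attempts += 1
        p = rng.uniform([0.0, 0.0], [spec.width_px - 1.0, spec.height_px - 1.0])
        if k:
            d2 = np.sum((placed[:k] - p) ** 2, axis=1)
            if d2.min() < sq:
                continue
        placed[k] = p
        k += 1
    return placed[:k]


def _render(spec: SceneSpec, centers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    if len(centers) == 0:
        img = np.full((h, w), INTERIOR_BASE, dtype=np.float64)
    else:
        ys, xs = np.mgrid[0:h, 0:w]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
        tree = cKDTree(centers)
        k = min(2, len(centers))
        dist, _ = tree.query(pts, k=k)
        if k == 1:
            d1 = dist.reshape(h, w)
            d2 = np.full_like(d1, np.inf)
        else:
            d1 = dist[:, 0].reshape(h, w)
            d2 = dist[:, 1].reshape(h, w)
        r_px = spec.cell_radius_mean_um / spec.um_per_px
        interior = INTERIOR_BASE - SHADING_DEPTH * np.clip(d1 / r_px, 0.0, 1.2)
        gap = d2 - d1
        img = interior.copy()
        halo = (gap >= BOUNDARY_BAND_PX) & (gap < BOUNDARY_BAND_PX + HALO_BAND_PX)
        img[halo] += spec.halo_strength * HALO_GAIN
        boundary = gap < BOUNDARY_BAND_PX
        img[boundary] = BOUNDARY_LEVEL * interior[boundary]
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec) -> SyntheticSample:
    """Render one field of view; fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    image = _render(spec, centers, rng)
    return SyntheticSample(image=image, centers=centers, spec=spec)


def voronoi_regions(sample: SyntheticSample) -> np.ndarray:
    """Label map assigning every pixel to its nearest center (render geometry)."""
    h, w = sample.spec.height_px, sample.spec.width_px
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)
    _, idx = cKDTree(sample.centers).query(pts, k=1)
    return idx.reshape(h, w)


# ---------------------------------------------------------------------------
# dataset generation


def _regime_counts(n_images: int, regime_mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n_images across regimes."""
    fracs = {r: float(f) for r, f in regime_mix.items() if f > 0}
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError(f"regime fractions must sum to 1, got {sum(fracs.values())}")
    for r in fracs:
        if r not in DENSITY_REGIMES:
            raise ValueError(f"unknown regime {r!r}")
    raw = {r: n_images * f for r, f in fracs.items()}
    counts = {r: int(np.floor(v)) for r, v in raw.items()}
    short = n_images - sum(counts.values())
    order = sorted(fracs, key=lambda r: (-(raw[r] - counts[r]), r))
    for r in order[:short]:
        counts[r] += 1
    return counts


def generate_dataset(
    n_images: int,
    regime_mix: Mapping[str, float],
    base_seed: int,
    out_dir: str | Path,
    width_px: int = 128,
    height_px: int = 128,
    um_per_px: float = 2.0,
    overwrite: bool = False,
    spec_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> Path:
    """Write images, annotation CSVs and a manifest; return the manifest path.

    Per-image seeds are ``base_seed + index``; the manifest records the
    realized (placed-center) density as the true density.
    """
    if n_images <= 0:
        raise ValueError("n_images must be positive")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    counts = _regime_counts(n_images, regime_mix)
    rows = []
    index = 0
    for regime in DENSITY_REGIMES:
        for _ in range(counts.get(regime, 0)):
            seed = base_seed + index
            overrides = dict(
                width_px=width_px, height_px=height_px, um_per_px=um_per_px
            )
            if spec_overrides and regime in spec_overrides:
                overrides.update(spec_overrides[regime])
            spec = SceneSpec.for_regime(regime, seed=seed, **overrides)
            sample = generate_scene(spec)
            image_id = f"img_{index:05d}_{regime}"
            img_rel = f"images/{image_id}.png"
            ann_rel = f"annotations/{image_id}.csv"
            save_image(out_dir / img_rel, sample.image)
            save_annotations(sample.to_annotated(image_id), out_dir / ann_rel)
            rows.append(
                {
                    "image_id": image_id,
                    "path": img_rel,
                    "annotation_path": ann_rel,
                    "regime": regime,
                    "true_density_cells_per_mm2": len(sample.centers) / spec.field_area_mm2,
                    "seed": seed,
                }
            )
            index += 1
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path
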