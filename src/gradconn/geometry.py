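"""Toy ventral-pathway geometry: grid, strips, functional zones, node placement.

The synthetic anatomy lives on a 40 x 48 x 36 grid of 3-mm isotropic voxels
with an MNI-like axis convention (y negative = posterior).  It contains:

* two parallel "gyrus" strips running along the y-axis — a medial fusiform
  (FG) strip and a lateral inferior-temporal (ITG) strip — matched in their
  y and z extents and differing only in x.  Within each strip, per-condition
  response weights vary linearly (hence monotonically) with y, emulating the
  caudal perceptual -> rostral conceptual gradient, with a more posterior
  perceptual-to-conceptual tipping point and a stronger rostral semantic
  preference in the ITG strip;
* three disjoint occipital zones — a caudal *percept* zone, an intermediate
  *concept* zone, and a rostral *ppi* zone — with per-condition weights whose
  colour-vs-semantic effect is strong in the concept zone, intermediate in
  the ppi zone and weak in the percept zone;
* world-space coordinates for the five network nodes, two of which
  (occipital-percept, occipital-concept) sit inside the percept and ppi
  zones respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NODES

__all__ = [
    "GeometryError",
    "GeometrySpec",
    "default_geometry",
    "world_coordinates",
    "sphere_mask",
]


class GeometryError(ValueError):
    """Raised for out-of-grid coordinates or degenerate masks."""


def world_coordinates(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of every voxel centre, shape ``shape + (3,)``."""
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ijk1 = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return ijk1 @ affine.T[:, :3]


def sphere_mask(
    shape: tuple[int, int, int], affine: np.ndarray, centre_mm, radius_mm: float
) -> np.ndarray:
    """Boolean mask of voxels whose *centre* lies within radius of a point."""
    xyz = world_coordinates(shape, affine)
    d2 = np.sum((xyz - np.asarray(centre_mm, dtype=float)) ** 2, axis=-1)
    return d2 <= radius_mm**2 + 1e-9


@dataclass
class GeometrySpec:
    shape: tuple[int, int, int]
    affine: np.ndarray
    sectors: dict[str, np.ndarray]          # strip label -> boolean mask
    zones: dict[str, np.ndarray]            # zone label -> boolean mask
    node_coords: dict[str, np.ndarray]      # node label -> world mm
    # strip label -> condition -> (posterior weight, anterior weight);
    # the voxel weight interpolates linearly in y across the strip's extent
    strip_weights: dict[str, dict[str, tuple[float, float]]]
    zone_weights: dict[str, dict[str, float]]
    node_sigma_mm: float = 4.0

    def __post_init__(self) -> None:
        masks = list(self.sectors.values())
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise GeometryError("sector masks overlap")
        zmasks = list(self.zones.values())
        for i in range(len(zmasks)):
            for j in range(i + 1, len(zmasks)):
                if np.any(zmasks[i] & zmasks[j]):
                    raise GeometryError("zone masks overlap")
        for label, xyz in self.node_coords.items():
            ijk = np.linalg.inv(self.affine) @ np.append(np.asarray(xyz, float), 1.0)
            if np.any(ijk[:3] < -0.5) or np.any(ijk[:3] > np.array(self.shape) - 0.5):
                raise GeometryError(f"node {label} at {tuple(xyz)} falls outside the grid")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.affine[:3, :3] ** 2, axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world(self) -> np.ndarray:
        return world_coordinates(self.shape, self.affine)

    def strip_fraction(self, strip: str) -> np.ndarray:
        """Normalised y position (0 = posterior end, 1 = anterior end) of each
        voxel in a strip, returned for the strip's voxels in mask order."""
        y = self.world()[..., 1][self.sectors[strip]]
        lo, hi = y.min(), y.max()
        return (y - lo) / (hi - lo) if hi > lo else np.zeros_like(y)

    def node_blob(self, label: str, support_mm: float | None = None):
        """Gaussian blob weights around a node; returns (mask, weights)."""
        if support_mm is None:
            support_mm = 3.0 * self.node_sigma_mm
        xyz = self.world()
        d2 = np.sum((xyz - self.node_coords[label]) ** 2, axis=-1)
        mask = d2 <= support_mm**2
        w = np.exp(-d2[mask] / (2.0 * self.node_sigma_mm**2))
        return mask, w


def _box(shape, affine, x_mm, y_mm, z_mm) -> np.ndarray:
    xyz = world_coordinates(shape, affine)
    m = np.ones(shape, dtype=bool)
    for axis, (lo, hi) in enumerate((x_mm, y_mm, z_mm)):
        m &= (xyz[..., axis] >= lo - 1e-9) & (xyz[..., axis] <= hi + 1e-9)
    return m


# Strip curvature: like a real gyrus, each strip sways laterally (x) and
# vertically (z) along its course.  The sway lengthens the anchor-to-anchor
# path so that thirteen 3-mm spheres (five anchors, two intermediates per
# gap) fit without overlap — on a straight 81-mm strip the ~16-mm anchor
# gaps would place sphere centres less than 6 mm apart.
_SWAY_MM = 10.0


def _strip_mask(shape, affine, x0: float, y_range, z0: float, half_width_mm=4.5):
    xyz = world_coordinates(shape, affine)
    y = xyz[..., 1]
    frac = (y - y_range[0]) / (y_range[1] - y_range[0])
    xc = x0 + _SWAY_MM * np.sin(2.0 * np.pi * frac)
    zc = z0 + _SWAY_MM * np.cos(2.0 * np.pi * frac)
    m = (y >= y_range[0] - 1e-9) & (y <= y_range[1] + 1e-9)
    m &= np.abs(xyz[..., 0] - xc) <= half_width_mm
    m &= np.abs(xyz[..., 2] - zc) <= half_width_mm
    return m


def default_geometry() -> GeometrySpec:
    """The study layout on the default 40 x 48 x 36 grid at 3 mm isotropic."""
    shape = (40, 48, 36)
    affine = np.array(
        [
            [3.0, 0.0, 0.0, -60.0],
            [0.0, 3.0, 0.0, -90.0],
            [0.0, 0.0, 3.0, -54.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    strip_y = (-78.0, 3.0)
    strip_z0 = -27.0
    sectors = {
        "FG": _strip_mask(shape, affine, -30.0, strip_y, strip_z0),
        "ITG": _strip_mask(shape, affine, -48.0, strip_y, strip_z0),
    }
    zone_x = (-51.0, -24.0)
    zone_z = (-6.0, 3.0)
    zones = {
        "percept": _box(shape, affine, zone_x, (-90.0, -75.0), zone_z),
        "concept": _box(shape, affine, zone_x, (-72.0, -60.0), zone_z),
        "ppi": _box(shape, affine, zone_x, (-57.0, -45.0), zone_z),
    }
    # ATL nodes sit inferior to the strips so their blobs do not bleed into
    # the rostral ROI spheres of the gradient analysis
    node_coords = {
        "IFG": np.array([-45.0, 24.0, 6.0]),
        "vATL": np.array([-27.0, -9.0, -42.0]),
        "lATL": np.array([-54.0, -3.0, -42.0]),
        "OCC-C": np.array([-39.0, -51.0, 0.0]),    # inside the ppi zone
        "OCC-P": np.array([-30.0, -81.0, 0.0]),    # inside the percept zone
    }
    assert set(node_coords) == set(NODES)
    # (posterior, anterior) weights; gradients are linear in y within a strip
    strip_weights = {
        "FG": {
            "control": (1.0, 0.0),
            "colour": (0.1, 1.0),
            "semantic": (0.1, 1.0),
        },
        "ITG": {
            "control": (1.0, 0.0),
            "colour": (0.45, 1.0),
            "semantic": (0.2, 1.3),
        },
    }
    zone_weights = {
        "percept": {
            "colour": 0.55, "semantic": 0.40, "control": 0.50,
            "coloured": 1.0, "greyscale": 0.45,
        },
        "concept": {
            "colour": 1.00, "semantic": 0.25, "control": 0.25,
            "coloured": 0.55, "greyscale": 0.45,
        },
        "ppi": {
            "colour": 0.45, "semantic": 0.25, "control": 0.25,
            "coloured": 0.50, "greyscale": 0.45,
        },
    }
    for s in sectors.values():
        for z in zones.values():
            assert not np.any(s & z), "strips and zones must occupy disjoint voxels"
    return GeometrySpec(
        shape=shape,
        affine=affine,
        sectors=sectors,
        zones=zones,
        node_coords=node_coords,
        strip_weights=strip_weights,
        zone_weights=zone_weights,
    )
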