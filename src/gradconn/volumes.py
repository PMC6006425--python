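"""Lightweight volumetric containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume", "Run", "StatMap"]


@dataclass
class Volume:
    """A 3-D scalar field with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.affine[:3, :3] ** 2, axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class Run:
    """A 4-D BOLD run (x, y, z, time) with its affine and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Run data must be 4-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """Voxels flattened: shape (n_volumes, n_voxels), C order."""
        return self.data.reshape(-1, self.n_volumes).T

    def volume(self, t: int) -> Volume:
        return Volume(self.data[..., t], self.affine)


@dataclass
class StatMap(Volume):
    """A statistic volume (beta/t/z) tied to a contrast."""

    kind: str = "t"
    label: str = ""
    df: float | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.kind not in ("beta", "t", "z"):
            raise ValueError(f"unknown statistic kind {self.kind!r}")
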