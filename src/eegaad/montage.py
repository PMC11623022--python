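"""Electrode montages: 3-D unit-sphere positions and their 2-D projection.

Coordinate convention (right-handed): x toward the nasion, y toward the
left ear, z up through the vertex. The packaged BioSemi-layout montages in
``eegaad/data`` follow this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["ElectrodeMontage", "load_montage", "packaged_montage", "project_montage"]


@dataclass
class ElectrodeMontage:
    """Named electrode positions on the unit sphere.

    ``pos2d`` is populated by :func:`project_montage` and holds azimuthal
    equidistant plane coordinates (u, v); it is ``None`` until projected.
    """

    names: list[str]
    pos3d: np.ndarray  # (n, 3)
    pos2d: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if self.pos3d.shape != (len(self.names), 3):
            raise ValueError("pos3d must be (n_electrodes, 3)")
        norms = np.linalg.norm(self.pos3d, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-norm electrode position")
        self.pos3d = self.pos3d / norms[:, None]

    def __len__(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "ElectrodeMontage":
        """Return a montage restricted to ``names`` (in the given order)."""
        idx = [self.names.index(n) for n in names]
        sub = ElectrodeMontage(names=list(names), pos3d=self.pos3d[idx])
        if self.pos2d is not None:
            sub.pos2d = self.pos2d[idx]
        return sub

    @property
    def hemisphere(self) -> np.ndarray:
        """Per-electrode hemisphere sign: +1 left (y > 0), -1 right, 0 midline."""
        y = self.pos3d[:, 1]
        return np.sign(np.where(np.abs(y) < 1e-9, 0.0, y)).astype(int)


def load_montage(path: str | Path) -> ElectrodeMontage:
    """Read a montage from a ``name,x,y,z`` CSV file."""
    path = Path(path)
    names, rows = [], []
    with open(path) as f:
        header = f.readline().strip().lower().split(",")
        if header[:4] != ["name", "x", "y", "z"]:
            raise ValueError("montage CSV must have header name,x,y,z")
        for line in f:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return ElectrodeMontage(names=names, pos3d=np.array(rows))


def packaged_montage(n_channels: int = 64) -> ElectrodeMontage:
    """Load the packaged BioSemi-layout montage (64 or 32 channels)."""
    if n_channels not in (64, 32):
        raise ValueError("packaged montages exist for 64 and 32 channels only")
    ref = resources.files("eegaad.data") / f"montage_biosemi{n_channels}.csv"
    with resources.as_file(ref) as p:
        return load_montage(p)


def project_montage(montage: ElectrodeMontage) -> ElectrodeMontage:
    """Project electrodes onto a plane with the azimuthal equidistant map.

    The projection pole is the vertex (0, 0, 1). Each electrode maps to
    ``rho * (cos(theta), sin(theta))`` where ``rho`` is the great-circle
    angle to the pole and ``theta = atan2(y, x)``, so distances from the
    pole are preserved exactly and the map is injective on the open upper
    hemisphere.
    """
    xyz = montage.pos3d
    rho = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))
    theta = np.arctan2(xyz[:, 1], xyz[:, 0])
    # the pole itself has undefined azimuth; rho = 0 makes it moot
    pos2d = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    out = ElectrodeMontage(names=list(montage.names), pos3d=xyz.copy())
    out.pos2d = pos2d
    return out
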