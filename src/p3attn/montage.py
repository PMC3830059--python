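"""Schematic 91-channel scalp montage on the unit sphere.

Coordinate convention (head frame): +x right, +y anterior, +z superior,
all sensor positions unit-norm.  The layout is a deterministic golden-angle
(Fibonacci) lattice covering a spherical cap from the vertex down to just
below the equator, a schematic stand-in for the scalp portion of a
high-density geodesic net.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_CHANNELS_DEFAULT = 91

#: lowest z of the covered cap (slightly below the equator, as on a scalp net)
_CAP_Z_MIN = -0.15


@dataclass(frozen=True)
class Montage:
    """Named sensor positions on the unit sphere."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit-norm rows

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.names) != pos.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if not np.allclose(np.linalg.norm(pos, axis=1), 1.0, atol=1e-9):
            raise ValueError("positions must be unit-norm")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def nearest_channel(self, point) -> str:
        """Name of the sensor closest (by angle) to a unit-sphere point."""
        p = np.asarray(point, dtype=float)
        p = p / np.linalg.norm(p)
        return self.names[int(np.argmax(self.positions @ p))]

    def angles(self) -> np.ndarray:
        """Pairwise great-circle angles between sensors, in radians."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosang)

    def to_dict(self) -> dict:
        return {"names": list(self.names), "positions": self.positions.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(tuple(d["names"]), np.asarray(d["positions"], dtype=float))


def make_montage(n_channels: int = N_CHANNELS_DEFAULT) -> Montage:
    """Deterministic Fibonacci-lattice montage of ``n_channels`` sensors.

    Sensors are spread near-uniformly over the spherical cap
    ``z in [-0.15, 1]`` and named ``E01`` ... ``E91`` in order of descending
    ``z`` (vertex first).
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - _CAP_Z_MIN) * (i + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    # phase chosen so the lattice is roughly left/right symmetric on average
    x = r * np.sin(phi)
    y = r * np.cos(phi)
    pos = np.column_stack([x, y, z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    width = len(str(n_channels))
    names = tuple(f"E{k + 1:0{width}d}" for k in i)
    return Montage(names, pos)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: anchor directions for ERP component topographies (head frame, unit-norm)
FRONTOCENTRAL_ANCHOR = _unit((0.0, 0.55, 0.84))   # approx FCz
CENTROPARIETAL_ANCHOR = _unit((0.0, -0.45, 0.89))  # approx CPz/Pz
PARIETAL_ANCHOR = _unit((0.0, -0.70, 0.71))        # approx Pz/POz
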