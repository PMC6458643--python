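"""Core containers shared across the package.

Two objects travel through every stage of the analysis:

* :class:`Centreline` — an ordered 3D polyline through the aortic lumen with
  the maximal-inscribed-sphere radius attached to every point.  It is the
  geometric unit of the shape analysis.
* :class:`Waveform` — one cardiac cycle of a uniformly sampled periodic
  signal (volumetric flow, lumen area, pressure or velocity).  Samples live
  on the circular grid ``t = k*dt`` for ``k = 0..n-1`` with ``period = n*dt``;
  the sample at ``t = period`` is identified with the one at ``t = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Centreline", "Waveform"]


@dataclass
class Centreline:
    """Ordered centreline points (mm) with per-point lumen radius (mm).

    Parameters
    ----------
    points
        Array of shape ``(n, 3)``, ordered from the sinotubular junction to
        the diaphragm.
    radius
        Array of shape ``(n,)`` of maximal-inscribed-sphere radii, mm.
    landmarks
        Optional map from anatomical landmark name to point index.
    subject_id
        Identifier carried through the pipeline.
    """

    points: np.ndarray
    radius: np.ndarray
    landmarks: dict[str, int] = field(default_factory=dict)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        n = self.points.shape[0]
        if n < 2:
            raise ValueError("centreline needs at least 2 points")
        if self.radius.shape != (n,):
            raise ValueError("radius must have one value per point")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive centreline points must be distinct")
        if np.any(self.radius <= 0):
            raise ValueError("radius must be positive everywhere")
        for name, idx in self.landmarks.items():
            if not (0 <= int(idx) < n):
                raise ValueError(f"landmark {name!r} index {idx} out of range")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def arc_length(self) -> np.ndarray:
        """Cumulative arc length at each point, mm (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total arc length, mm."""
        return float(self.arc_length()[-1])

    def copy(self, **changes) -> "Centreline":
        out = replace(self, **changes)
        if "points" not in changes:
            out.points = self.points.copy()
        if "radius" not in changes:
            out.radius = self.radius.copy()
        if "landmarks" not in changes:
            out.landmarks = dict(self.landmarks)
        return out


@dataclass
class Waveform:
    """One cardiac cycle of a uniformly sampled periodic signal.

    ``values[k]`` is the sample at ``t = k*dt``; the grid is circular, so the
    cycle period is ``n*dt`` and ``t = period`` wraps to ``t = 0``.
    """

    values: np.ndarray
    dt: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size < 16:
            raise ValueError("need at least 16 samples per cycle")
        if not np.isfinite(self.values).all():
            raise ValueError("waveform contains non-finite samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def period(self) -> float:
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def mean(self) -> float:
        return float(self.values.mean())

    def max(self) -> float:
        return float(self.values.max())

    def min(self) -> float:
        return float(self.values.min())

    @property
    def pulse(self) -> float:
        """Peak-to-trough excursion (pulse pressure for a pressure wave)."""
        return float(self.values.max() - self.values.min())

    def increments(self) -> np.ndarray:
        """Successive circular differences ``values[k+1] - values[k]``.

        Length ``n``; the last entry closes the cycle back to sample 0, so
        the increments of a periodic signal sum to zero exactly.
        """
        return np.roll(self.values, -1) - self.values

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Waveform":
        return Waveform(np.asarray(values, dtype=float), self.dt,
                        self.units if units is None else units)
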