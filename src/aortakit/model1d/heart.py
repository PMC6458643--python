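"""Time-varying elastance heart for the 1D model's upstream boundary.

The left ventricle is a pressure source P_v(t) = E(t) (V_v - V0) with a
double-Hill normalised elastance shape (smooth rise to E_max at the end of
the activation ramp, rapid relaxation), filled from a constant-pressure
atrium through a linear mitral resistance and ejecting through an ideal
diode valve with a quadratic (Bernoulli) pressure loss.  During isovolumic
phases both valves are shut and the ventricular volume is constant, so
P_v = E(t)(V_v - V0) holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import MMHG

__all__ = ["HeartModel"]


@dataclass
class HeartModel:
    """Elastance-heart parameters (clinical units at the interface)."""

    e_max: float = 2.5          # mmHg/ml
    e_min: float = 0.08         # mmHg/ml
    period: float = 0.8         # s
    v0: float = 10.0            # ml, unstressed volume
    p_fill: float = 10.0        # mmHg, atrial filling pressure
    r_mv: float = 0.01          # mmHg·s/ml, mitral resistance
    valve_loss: float = 0.033   # dyn·s²/cm⁸, Bernoulli coefficient of the valve
    # double-Hill shape constants (fractions of the period)
    m1: float = 1.32
    m2: float = 27.4
    tau1_frac: float = 0.269
    tau2_frac: float = 0.452

    def __post_init__(self) -> None:
        if not (self.e_max > self.e_min > 0):
            raise ValueError("require E_max > E_min > 0")
        if self.period <= 0:
            raise ValueError("period must be positive")
        # normalisation of the double-Hill shape
        tt = np.linspace(0.0, self.period, 2001)
        self._norm = 1.0
        self._norm = float(np.max(self._shape(tt)))

    def _shape(self, t: np.ndarray | float) -> np.ndarray | float:
        tau = np.mod(t, self.period)
        g1 = (tau / (self.tau1_frac * self.period)) ** self.m1
        g2 = (tau / (self.tau2_frac * self.period)) ** self.m2
        return (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2)) / self._norm

    def elastance(self, t: float) -> float:
        """E(t) in mmHg/ml (periodic)."""
        return self.e_min + (self.e_max - self.e_min) * float(self._shape(t))

    def elastance_cgs(self, t: float) -> float:
        """E(t) in dyn/cm² per ml."""
        return self.elastance(t) * MMHG

    def ventricular_pressure(self, t: float, volume: float) -> float:
        """P_v in dyn/cm² for a given ventricular volume (ml)."""
        return self.elastance_cgs(t) * (volume - self.v0)

    @property
    def p_fill_cgs(self) -> float:
        return self.p_fill * MMHG

    @property
    def r_mv_cgs(self) -> float:
        return self.r_mv * MMHG

    def initial_volume(self) -> float:
        """Start filled to the atrial pressure at diastolic elastance."""
        return self.v0 + self.p_fill / self.e_min
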