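"""Conventional pressure–velocity wave intensity analysis for 1D model output.

The simulated waves are analysed with the classical P–U formulation: with
local wave speed c and density rho, the incremental separation is

    dI± = ±(dP ± rho c dU)² / (4 rho c),

satisfying dI₊ + dI₋ = dP·dU at every sample.  Wave areas use the same
dominant-window rule as the clinical flow–area analysis so the two routes
are directly comparable.
"""

from __future__ import annotations

import numpy as np

from ..core import Waveform
from ..hemodynamics import _window_area
from .tree import MMHG, RHO

__all__ = ["separate_waves_pu", "wia_pu"]


def separate_waves_pu(pressure: Waveform, velocity: Waveform, rho: float,
                      c: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward/backward intensity increments from P (mmHg) and U (cm/s).

    Returns (dI₊, dI₋, net) in CGS increment units (dyn/cm² · cm/s).
    """
    if c <= 0:
        raise ValueError("wave speed must be positive")
    if pressure.n != velocity.n or pressure.dt != velocity.dt:
        raise ValueError("pressure and velocity must share the same grid")
    dp = pressure.increments() * MMHG
    du = velocity.increments()
    zc = rho * c
    di_plus = (dp + zc * du) ** 2 / (4.0 * zc)
    di_minus = -((dp - zc * du) ** 2) / (4.0 * zc)
    return di_plus, di_minus, dp * du


def wia_pu(pressure: Waveform, velocity: Waveform, rho: float = RHO,
           c: float | None = None) -> dict:
    """Separated P–U wave intensity with FCW/BCW areas.

    If ``c`` is not given it is estimated from the early-systolic PU-loop
    slope (dP = rho c dU during reflection-free ejection).
    """
    if c is None:
        du = velocity.increments()
        dp = pressure.increments() * MMHG
        ipk = int(np.argmax(velocity.values))
        q = velocity.values
        height = q[ipk] - q.min()
        lo = q.min() + 0.05 * height
        hi = q.min() + 0.60 * height
        start = ipk
        while start > 0 and q[start - 1] >= lo:
            start -= 1
        end = start
        while end + 1 <= ipk and q[end + 1] <= hi:
            end += 1
        if end - start < 3:
            raise ValueError("PU-loop window too short to estimate wave speed")
        sl = np.polyfit(du[start:end + 1].cumsum(), dp[start:end + 1].cumsum(), 1)[0]
        c = float(sl / rho)
        if c <= 0:
            raise ValueError("non-positive PU-loop wave speed")
    di_plus, di_minus, net = separate_waves_pu(pressure, velocity, rho, c)
    fcw = _window_area(di_plus)
    bcw = _window_area(-di_minus)
    return {"di_plus": di_plus, "di_minus": di_minus, "net": net,
            "fcw_area": fcw, "bcw_area": bcw, "wave_speed": c}
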