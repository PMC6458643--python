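"""Non-invasive central haemodynamics from flow and area waveforms.

Three quantities are derived per subject from the ascending-aortic flow Q(t)
[ml/s] and lumen area A(t) [cm²] waveforms plus brachial cuff pressures:

* **central SBP** — the area waveform is mapped to pressure through the
  exponential wall model ``P = P_d exp(alpha (A/A_d − 1))``, anchored at the
  diastolic area/pressure pair and with the stiffness ``alpha`` tuned so the
  synthesised mean pressure matches the measured MBP (diastolic and mean
  pressure are conserved along the arterial tree; systolic is not, which is
  why c-SBP must be synthesised rather than taken from the cuff);
* **total arterial compliance (TAC)** — the measured flow drives a 2-element
  windkessel with resistance R = MBP/CO, and C is tuned so the model pulse
  pressure equals the measured central pulse pressure;
* **wave intensity** in the flow–area formulation: the wave speed c is the
  early-systolic slope of the QA loop, incremental wavefronts are separated
  into forward/backward components, and the forward (FCW) and backward (BCW)
  compression-wave magnitudes are the areas under the separated intensity
  curves.

Wave-intensity convention: by default intensities are per-sample increment
products (summed over the wave window), reported under the cohort's unit
label cm⁵; pass ``convention="timederiv"`` to use time-normalised
derivatives (units cm⁵/s³-equivalent, dI = (dQ/dt)(dA/dt)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import Waveform
from .synthetic import SubjectRecord, generate_wk2_pressure

__all__ = [
    "PressureCal",
    "HaemoSummary",
    "calibrate_pressure_from_area",
    "vascular_resistance",
    "fit_tac",
    "wave_speed_qa",
    "separate_waves_qa",
    "wave_areas",
    "default_qa_window",
    "subject_summary",
]


# ---------------------------------------------------------------------------
# central pressure from area distension


@dataclass
class PressureCal:
    """Result of the exponential pressure–area calibration."""

    alpha: float        # dimensionless wall stiffness
    p_d: float          # diastolic anchor pressure, mmHg
    a_d: float          # diastolic (minimum) area, cm²
    c_sbp: float        # peak of the synthesised central pressure, mmHg
    c_pp: float         # c_sbp - p_d, mmHg
    pressure: Waveform


def calibrate_pressure_from_area(area: Waveform, dbp: float,
                                 mbp: float) -> PressureCal:
    """Synthesise central pressure from the area waveform and cuff DBP/MBP.

    The diastolic anchor is ``A_d = min(area)`` at ``P_d = DBP``.  The mean of
    ``P_d exp(alpha x)`` with ``x = A/A_d − 1 ≥ 0`` is strictly increasing in
    alpha, so the stiffness solving mean(P) = MBP is found by bracketed
    root-finding to 1e−6 mmHg.
    """
    if not dbp < mbp:
        raise ValueError("require DBP < MBP")
    a = area.values
    a_d = float(a.min())
    if a_d <= 0:
        raise ValueError("area must be strictly positive")
    x = a / a_d - 1.0
    if x.max() <= 0:
        raise ValueError("pulseless area waveform: cannot reach MBP > DBP")

    def mean_minus_mbp(alpha: float) -> float:
        return dbp * float(np.mean(np.exp(alpha * x))) - mbp

    lo, hi = 1e-3, 1e3
    if mean_minus_mbp(lo) > 0 or mean_minus_mbp(hi) < 0:
        raise ValueError("stiffness alpha outside the [1e-3, 1e3] bracket")
    alpha = optimize.brentq(mean_minus_mbp, lo, hi, xtol=1e-12, rtol=1e-14)
    p = dbp * np.exp(alpha * x)
    pw = area.with_values(p, "mmHg")
    c_sbp = float(p.max())
    return PressureCal(alpha=float(alpha), p_d=dbp, a_d=a_d,
                       c_sbp=c_sbp, c_pp=c_sbp - dbp, pressure=pw)


# ---------------------------------------------------------------------------
# windkessel


def vascular_resistance(mbp: float, co: float) -> float:
    """Systemic vascular resistance MBP/CO, mmHg·s/ml (CO as mean flow in ml/s)."""
    if co <= 0:
        raise ValueError("cardiac output must be positive")
    return mbp / co


def fit_tac(flow: Waveform, r: float, target_cpp: float) -> float:
    """Total arterial compliance: tune WK2 C so model PP matches measured c-PP.

    The windkessel pulse pressure is strictly decreasing in C (more storage,
    less pulsation), so C is found by bracketed root-finding; the resistive
    limit C → 0 gives PP = R·(max Q − min Q), the largest attainable target.
    """
    if target_cpp <= 0:
        raise ValueError("target pulse pressure must be positive")

    def pp(c: float) -> float:
        return generate_wk2_pressure(flow, r, c).pulse

    lo, hi = 1e-6, 1e4
    if pp(lo) < target_cpp:
        raise ValueError("target pulse pressure exceeds the resistive (C->0) limit")
    if pp(hi) > target_cpp:
        raise ValueError("target pulse pressure unattainably small")
    return float(optimize.brentq(lambda c: pp(c) - target_cpp, lo, hi,
                                 xtol=1e-12, rtol=1e-14))


# ---------------------------------------------------------------------------
# wave intensity (flow–area formulation)


def default_qa_window(flow: Waveform) -> tuple[int, int]:
    """Early-systolic QA-loop window on the flow upstroke.

    From the upstroke onset (first sample exceeding 5% of the pulse height
    above the minimum) to the last sample below 60% of the pulse height
    before the peak.  Over this window the wave is assumed reflection-free.
    """
    q = flow.values
    ipk = int(np.argmax(q))
    qmin = q.min()
    height = q[ipk] - qmin
    lo_thr = qmin + 0.05 * height
    hi_thr = qmin + 0.60 * height
    start = ipk
    while start > 0 and q[start - 1] >= lo_thr:
        start -= 1
    end = start
    while end + 1 <= ipk and q[end + 1] <= hi_thr:
        end += 1
    return start, end


def wave_speed_qa(flow: Waveform, area: Waveform,
                  window: tuple[int, int] | None = None) -> float:
    """Wave speed as the QA-loop slope dQ/dA over the early-systolic window, cm/s.

    During reflection-free early ejection the incremental relation
    dQ = c·dA makes the QA loop linear with slope c.
    """
    if flow.n != area.n or flow.dt != area.dt:
        raise ValueError("flow and area must share the same grid")
    if window is None:
        window = default_qa_window(flow)
    i0, i1 = window
    if i1 - i0 + 1 < 4:
        raise ValueError("QA window needs at least 4 samples")
    q = flow.values[i0:i1 + 1]
    a = area.values[i0:i1 + 1]
    if np.ptp(a) <= 0 or np.var(a) < 1e-12 * max(1.0, np.var(q)):
        raise ValueError("area is flat over the QA window (vertical loop)")
    slope = stats.linregress(a, q).slope
    if slope <= 0:
        raise ValueError("non-positive QA slope: window is not an upstroke")
    return float(slope)


def separate_waves_qa(flow: Waveform, area: Waveform, c: float,
                      convention: str = "increments",
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separate wave intensity into forward/backward components.

    Per-sample circular increments dQ, dA give

        dI₊ = +(dQ + c·dA)² / (4c),   dI₋ = −(dQ − c·dA)² / (4c),

    which satisfy the separation identity dI₊ + dI₋ = dQ·dA exactly.
    Returns (dI₊, dI₋, net).
    """
    if c <= 0:
        raise ValueError("wave speed must be positive")
    if flow.n != area.n or flow.dt != area.dt:
        raise ValueError("flow and area must share the same grid")
    dq = flow.increments()
    da = area.increments()
    if convention == "timederiv":
        dq = dq / flow.dt
        da = da / flow.dt
    elif convention != "increments":
        raise ValueError("convention must be 'increments' or 'timederiv'")
    di_plus = (dq + c * da) ** 2 / (4.0 * c)
    di_minus = -((dq - c * da) ** 2) / (4.0 * c)
    return di_plus, di_minus, dq * da


def _window_area(di: np.ndarray, rel_floor: float = 1e-3) -> float:
    """Area of the dominant contiguous wave in a one-signed intensity series.

    The separated series is non-negative by construction (pass −dI₋ for the
    backward series), so the wave window is the contiguous run around the
    global maximum where the signal stays above ``rel_floor`` of that
    maximum; this is the deterministic stand-in for reading the window off
    the WIA plot.
    """
    peak = int(np.argmax(di))
    if di[peak] <= 0:
        return 0.0
    floor = rel_floor * di[peak]
    i0 = peak
    while i0 > 0 and di[i0 - 1] > floor:
        i0 -= 1
    i1 = peak
    while i1 < di.size - 1 and di[i1 + 1] > floor:
        i1 += 1
    return float(di[i0:i1 + 1].sum())


def wave_areas(di_plus: np.ndarray, di_minus: np.ndarray) -> tuple[float, float]:
    """FCW and BCW magnitudes: areas under the dominant separated waves.

    FCW is the systolic-ejection forward compression wave (dominant positive
    run of dI₊); BCW is the mid-systolic backward compression wave (dominant
    run of −dI₋).  Both are reported as magnitudes ≥ 0.
    """
    if np.all(di_plus <= 0):
        if np.all(di_minus == 0) and np.all(di_plus == 0):
            return 0.0, 0.0
        raise ValueError("no forward compression wave found (not an ejection beat)")
    fcw = _window_area(di_plus)
    bcw = _window_area(-di_minus)
    return fcw, bcw


# ---------------------------------------------------------------------------
# per-subject summary


@dataclass
class HaemoSummary:
    """Derived central haemodynamics for one subject."""

    subject_id: str
    co: float          # cardiac output = mean flow, ml/s
    r: float           # vascular resistance, mmHg·s/ml
    tac: float         # total arterial compliance, ml/mmHg
    taci: float        # TAC / BSA, ml/mmHg/m²
    wave_speed: float  # cm/s
    fcw_area: float    # cm⁵ (increment convention)
    bcw_area: float    # cm⁵
    c_sbp: float       # mmHg
    c_pp: float        # mmHg
    alpha: float       # wall stiffness from the pressure calibration


def subject_summary(record: SubjectRecord,
                    convention: str = "increments") -> HaemoSummary:
    """Run the full non-invasive haemodynamic chain for one subject."""
    cal = calibrate_pressure_from_area(record.area, record.dbp, record.mbp)
    co = record.flow.mean()
    r = vascular_resistance(record.mbp, co)
    tac = fit_tac(record.flow, r, cal.c_pp)
    c = wave_speed_qa(record.flow, record.area)
    di_p, di_m, _ = separate_waves_qa(record.flow, record.area, c, convention)
    fcw, bcw = wave_areas(di_p, di_m)
    return HaemoSummary(
        subject_id=record.subject_id, co=co, r=r, tac=tac,
        taci=tac / record.bsa, wave_speed=c, fcw_area=fcw, bcw_area=bcw,
        c_sbp=cal.c_sbp, c_pp=cal.c_pp, alpha=cal.alpha,
    )
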