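"""Synthetic cohorts with known ground truth.

The study population this package analyses (post-coarctation aortas with
paired flow/area waveforms and cuff pressures) is not publicly deposited, so
every analysis stage is exercised against synthetic data whose generating
parameters are known exactly:

* an aortic-arch-like centreline population built from a "candy-cane" base
  curve perturbed along mutually orthogonal curvature and radius modes
  (arch angulation, ascending dilation, transverse-arch hypoplasia, isthmus
  narrowing, ...), with weights drawn from known normal distributions;
* flow/area waveform pairs composed of a forward wave plus a delayed, scaled
  reflection under linear wave theory (``dQ_f = c dA_f``, ``dQ_b = -c dA_b``),
  so the forward/backward wave-intensity areas are known in closed form;
* pressure waveforms consistent with the exponential pressure–area wall model
  and with the 2-element windkessel, generated from known parameters so the
  corresponding calibration routines can be verified as exact inverses.

Weights, labels and covariates are drawn from a single seeded generator, so
an identical configuration and seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Centreline, Waveform
from .shape import geometry_indices

__all__ = [
    "ModeDef",
    "PopulationConfig",
    "WaveGenConfig",
    "CohortConfig",
    "SubjectRecord",
    "base_centreline",
    "make_mode_basis",
    "generate_centerline_population",
    "generate_waveforms",
    "generate_area_from_pressure",
    "generate_wk2_pressure",
    "generate_cohort",
    "default_population_config",
    "default_cohort_config",
]

DEFAULT_LANDMARKS = {
    "sinotubular": 0.0,
    "innominate_LCC_midpoint": 0.30,
    "isthmus": 0.45,
    "diaphragm": 1.0,
}


# ---------------------------------------------------------------------------
# base geometry


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def base_centreline(n_points: int = 100,
                    ascending_length: float = 55.0,
                    arch_width: float = 60.0,
                    arch_height: float = 30.0,
                    descending_length: float = 130.0,
                    descending_bow: float = 8.0,
                    landmark_fractions: dict[str, float] | None = None,
                    ) -> Centreline:
    """Analytic candy-cane arch: ascending limb, elliptical arch, descending limb.

    All dimensions in mm.  The curve starts at the sinotubular junction,
    rises by ``ascending_length``, turns through a half-ellipse of the given
    width and height, and descends with a gentle bow to the diaphragm.  The
    base radius tapers from 12.5 mm (ascending) to 9 mm (diaphragm).
    """
    # dense parameterisation, later resampled to equal arc length
    m = 2000
    za = np.linspace(0.0, ascending_length, m // 4)
    asc = np.column_stack([np.zeros_like(za), np.zeros_like(za), za])
    th = np.linspace(0.0, np.pi, m // 2)
    arch = np.column_stack([
        arch_width / 2.0 * (1.0 - np.cos(th)),
        np.zeros_like(th),
        ascending_length + arch_height * np.sin(th),
    ])
    zd = np.linspace(ascending_length, ascending_length - descending_length, m // 4)
    frac = (ascending_length - zd) / descending_length
    desc = np.column_stack([
        arch_width + descending_bow * np.sin(np.pi * frac),
        np.zeros_like(zd),
        zd,
    ])
    pts = np.vstack([asc, arch[1:], desc[1:]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, s[-1], n_points)
    pts = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])

    sf = np.linspace(0.0, 1.0, n_points)   # arc-length fraction
    radius = np.where(
        sf <= 0.18, 12.5,
        12.5 - 3.3 * _smoothstep((sf - 0.18) / 0.22))
    radius = np.where(sf > 0.40, 9.2 - 0.2 * (sf - 0.40) / 0.60, radius)

    fractions = dict(DEFAULT_LANDMARKS if landmark_fractions is None
                     else landmark_fractions)
    landmarks = {name: int(round(f * (n_points - 1)))
                 for name, f in fractions.items()}
    return Centreline(pts, radius, landmarks, "base")


# ---------------------------------------------------------------------------
# variation modes


def _gauss(s: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((s - mu) / sigma) ** 2)


def _raw_profile(name: str, kind: str, n_points: int) -> np.ndarray:
    """Unnormalised spatial profile of a named variation mode.

    Curvature modes are per-point 3D displacement fields flattened to a
    3*n vector; radius modes are per-point radius perturbations (n vector).
    """
    s = np.linspace(0.0, 1.0, n_points)
    if kind == "curvature":
        d = np.zeros((n_points, 3))
        if name == "ascending_length":
            # elongation of the ascending limb, carried through the arch
            d[:, 2] = _smoothstep(s / 0.35)
        elif name == "arch_angulation":
            # tall, narrow (gothic-like) peaking of the transverse arch
            d[:, 2] = _gauss(s, 0.28, 0.09)
            d[:, 0] = -0.35 * _gauss(s, 0.28, 0.09)
        elif name == "descending_bow":
            # out-of-plane bowing of the descending aorta
            d[:, 1] = _gauss(s, 0.72, 0.16)
        elif name == "arch_width":
            d[:, 0] = _gauss(s, 0.32, 0.12)
        else:
            raise KeyError(f"unknown curvature mode {name!r}")
        return d.ravel()
    if kind == "radius":
        if name == "ascending_dilation":
            return _gauss(s, 0.10, 0.07)
        if name == "transverse_arch":
            return _gauss(s, 0.32, 0.06)
        if name == "isthmus":
            return _gauss(s, 0.45, 0.04)
        if name == "descending_taper":
            return _smoothstep((s - 0.5) / 0.4)
        raise KeyError(f"unknown radius mode {name!r}")
    raise ValueError(f"unknown mode kind {kind!r}")


@dataclass
class ModeDef:
    """One generator variation mode: a named/explicit spatial profile + weight SD."""

    mode_id: str
    kind: str                      # "curvature" | "radius"
    sd: float                      # SD of the normal weight distribution, mm
    profile: np.ndarray | None = None   # explicit profile; None -> library lookup

    def __post_init__(self) -> None:
        if self.kind not in ("curvature", "radius"):
            raise ValueError(f"mode kind must be curvature|radius, got {self.kind!r}")
        if self.sd < 0:
            raise ValueError("mode SD must be >= 0")


def _pose_basis(n_points: int) -> np.ndarray:
    """Orthonormal basis of the similarity space at the base shape.

    Spans the 3 translations, the 3 infinitesimal rotations about the
    centroid, the uniform scaling and the arc-length gradient of the base
    candy-cane — the directions that rigid registration plus length
    normalisation remove or rescale.  Curvature modes are projected out of
    this space so that generated shape variation is orthogonal to pose and
    survives the normalisation pipeline intact.
    """
    base = base_centreline(n_points)
    centred = base.points - base.points.mean(axis=0)
    vecs = []
    for ax in range(3):                     # translations
        v = np.zeros((n_points, 3))
        v[:, ax] = 1.0
        vecs.append(v.ravel())
    for ax in range(3):                     # infinitesimal rotations
        omega = np.zeros(3)
        omega[ax] = 1.0
        vecs.append(np.cross(omega, centred).ravel())
    vecs.append(centred.ravel())            # uniform scaling
    # gradient of total arc length w.r.t. the point positions: a mode with a
    # component along it changes subject length, which the length scaling
    # would fold back into every coordinate
    seg = np.diff(base.points, axis=0)
    tang = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    grad = np.zeros((n_points, 3))
    grad[:-1] -= tang
    grad[1:] += tang
    vecs.append(grad.ravel())
    q, _ = np.linalg.qr(np.array(vecs).T)
    return q.T                              # (8, 3*n_points)


def make_mode_basis(defs: list[ModeDef], n_points: int = 100) -> dict[str, np.ndarray]:
    """Resolve mode profiles and orthonormalise them within each kind.

    Profiles are orthogonalised by modified Gram–Schmidt in the listed order
    and scaled to unit norm, so a weight of w mm moves the shape by w mm RMS
    along that mode and the modes are exactly orthogonal as vectors.
    Curvature modes are additionally projected out of the base shape's
    similarity (pose + scale) space, and radius modes are made zero-mean:
    pose and overall calibre are not shape — any such component of a mode
    would be silently removed (or, worse, smeared across modes) by the
    registration and scaling steps of the analysis pipeline.
    """
    pose = None
    out: dict[str, np.ndarray] = {}
    for kind in ("curvature", "radius"):
        sel = [d for d in defs if d.kind == kind]
        basis: list[np.ndarray] = []
        for d in sel:
            v = (_raw_profile(d.mode_id, kind, n_points) if d.profile is None
                 else np.asarray(d.profile, dtype=float).copy())
            if kind == "curvature":
                if pose is None:
                    pose = _pose_basis(n_points)
                v = v - pose.T @ (pose @ v)
            else:
                # overall calibre is normalised away (mean-radius scaling),
                # so radius modes carry relative-calibre variation only
                v = v - v.mean()
            for b in basis:
                v -= (v @ b) * b
            norm = np.linalg.norm(v)
            if norm < 1e-10:
                raise ValueError(f"mode {d.mode_id!r} is linearly dependent on "
                                 "earlier modes")
            v /= norm
            basis.append(v)
            out[d.mode_id] = v
    return out


# ---------------------------------------------------------------------------
# centreline population


@dataclass
class PopulationConfig:
    """Conditions of the synthetic shape cohort."""

    n_subjects: int = 60
    seed: int = 0
    mode_defs: list[ModeDef] = field(default_factory=list)
    noise_sd: float = 0.3          # iid point/radius jitter, mm
    landmark_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS))
    gothic_rule: tuple[str, float, float] | None = None   # (mode_id, slope, intercept)
    n_points: int = 100

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        fr = list(self.landmark_fractions.values())
        if not all(0.0 <= f <= 1.0 for f in fr):
            raise ValueError("landmark fractions must lie in [0, 1]")
        if not all(b > a for a, b in zip(fr, fr[1:])):
            raise ValueError("landmark fractions must be strictly increasing")


def _check_orthonormal(basis: dict[str, np.ndarray], defs: list[ModeDef],
                       kind: str) -> np.ndarray:
    ids = [d.mode_id for d in defs if d.kind == kind]
    if not ids:
        return np.zeros((0, 0))
    b = np.array([basis[i] for i in ids])
    gram = b @ b.T
    if not np.allclose(gram, np.eye(len(ids)), atol=1e-8):
        raise ValueError(f"{kind} mode profiles are not orthonormal")
    return b


def generate_centerline_population(
        cfg: PopulationConfig,
        rng: np.random.Generator | None = None,
) -> tuple[list[Centreline], pd.DataFrame]:
    """Draw a centreline cohort; returns the shapes and the truth table.

    Each subject is the base candy-cane shape perturbed by its normal mode
    weights plus iid jitter.  Subjects whose perturbed radius would go
    non-positive anywhere are rejected and redrawn (clipping would break the
    orthogonality of the realised modes); the redraw count is logged in the
    truth table.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = base_centreline(cfg.n_points, landmark_fractions=cfg.landmark_fractions)
    basis = make_mode_basis(cfg.mode_defs, cfg.n_points)
    _check_orthonormal(basis, cfg.mode_defs, "curvature")
    _check_orthonormal(basis, cfg.mode_defs, "radius")
    if cfg.gothic_rule is not None:
        gothic_mode = cfg.gothic_rule[0]
        if gothic_mode not in basis:
            raise ValueError(f"gothic rule refers to unknown mode {gothic_mode!r}")

    shapes: list[Centreline] = []
    rows = []
    for i in range(cfg.n_subjects):
        for attempt in range(1000):
            weights = {d.mode_id: rng.normal(0.0, d.sd) for d in cfg.mode_defs}
            pts = base.points.copy()
            rad = base.radius.copy()
            for d in cfg.mode_defs:
                w = weights[d.mode_id]
                if d.kind == "curvature":
                    pts = pts + w * basis[d.mode_id].reshape(-1, 3)
                else:
                    rad = rad + w * basis[d.mode_id]
            if cfg.noise_sd > 0:
                pts = pts + rng.normal(0.0, cfg.noise_sd, pts.shape)
                rad = rad + rng.normal(0.0, cfg.noise_sd, rad.shape)
            if rad.min() > 0.1:
                break
        else:
            raise RuntimeError("could not draw a subject with positive radius")
        sid = f"S{i:03d}"
        cl = Centreline(pts, rad, dict(base.landmarks), sid)
        row = {"id": sid, "redraws": attempt}
        row.update({f"w_{k}": v for k, v in weights.items()})
        if cfg.gothic_rule is not None:
            mode_id, slope, intercept = cfg.gothic_rule
            p = 1.0 / (1.0 + np.exp(-(intercept + slope * weights[mode_id])))
            row["gothic_p"] = p
            row["gothic"] = bool(rng.random() < p)
        gi = geometry_indices(cl)
        row["coarctation_index"] = gi.coarctation_index
        row["arch_index"] = gi.arch_index
        rows.append(row)
        shapes.append(cl)
    truth = pd.DataFrame(rows).set_index("id")
    return shapes, truth


# ---------------------------------------------------------------------------
# waveforms


@dataclass
class WaveGenConfig:
    """Forward wave + delayed scaled reflection under linear wave theory."""

    period: float = 0.96           # s
    dt: float = 0.0096             # s (temporal resolution of the acquisition)
    amplitude: float = 0.55        # cm², forward area pulse height
    onset: float = 0.02            # s
    width: float = 0.50            # s
    wave_speed: float = 400.0      # cm/s
    reflection_coeff: float = 0.2  # dimensionless, in [0, 1)
    reflection_delay: float = 0.16  # s
    baseline_area: float = 5.2     # cm²
    baseline_flow: float = 25.0    # ml/s
    pulse_power: float = 1.0       # exponent p in amp·sin(pi u)^p; higher = peakier

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.width < self.period:
            raise ValueError("pulse width must be shorter than the period")
        if self.reflection_delay < 0:
            raise ValueError("reflection delay must be >= 0")
        if self.baseline_area <= 0:
            raise ValueError("baseline area must be positive")
        if not 0.0 <= self.reflection_coeff < 1.0:
            raise ValueError("reflection coefficient must lie in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.period / self.dt))


def generate_waveforms(cfg: WaveGenConfig) -> tuple[Waveform, Waveform, dict]:
    """Flow/area pair with a known forward wave and reflection.

    The forward area component is a smooth compact pulse ``A_f``; the
    backward component is ``A_b(t) = Γ A_f(t − τ)``.  Incremental linear wave
    theory fixes the flow components: ``dQ_f = c dA_f`` and ``dQ_b = −c dA_b``.
    The truth dict carries the exact component-wise wave-intensity areas
    (FCW from the forward component, BCW from the backward one).
    """
    n = cfg.n_samples
    dt = cfg.period / n
    t = np.arange(n) * dt
    u = (t - cfg.onset) / cfg.width
    a_f = np.where((u >= 0) & (u <= 1),
                   cfg.amplitude * np.sin(np.pi * np.clip(u, 0, 1)) ** cfg.pulse_power,
                   0.0)
    shift = int(round(cfg.reflection_delay / dt))
    if cfg.onset + cfg.width + cfg.reflection_delay > cfg.period:
        warnings.warn("reflected pulse wraps around the cycle", stacklevel=2)
    a_b = cfg.reflection_coeff * np.roll(a_f, shift)
    c = cfg.wave_speed
    flow = Waveform(cfg.baseline_flow + c * a_f - c * a_b, dt, "ml/s")
    area = Waveform(cfg.baseline_area + a_f + a_b, dt, "cm2")
    da_f = np.roll(a_f, -1) - a_f
    da_b = np.roll(a_b, -1) - a_b
    fcw = float(c * np.sum(da_f ** 2))
    bcw = float(c * np.sum(da_b ** 2))
    truth = {
        "wave_speed": c,
        "reflection_coeff": cfg.reflection_coeff,
        "reflection_delay": shift * dt,
        "fcw_area": fcw,
        "bcw_area": bcw,
        "bcw_fcw_ratio": bcw / fcw if fcw > 0 else 0.0,
    }
    return flow, area, truth


def generate_area_from_pressure(pressure: Waveform, alpha: float,
                                a_d: float, p_d: float) -> Waveform:
    """Area from pressure under the exponential wall model (forward direction).

    The single-stiffness-parameter exponential model is
    ``P = P_d exp(alpha (A/A_d − 1))``; its exact inverse is
    ``A = A_d (1 + ln(P/P_d)/alpha)``, the relation used here.  The pressure
    must never fall below the diastolic anchor ``P_d``.
    """
    if alpha <= 0 or a_d <= 0 or p_d <= 0:
        raise ValueError("alpha, A_d and P_d must be positive")
    p = pressure.values
    if np.any(p < p_d * (1.0 - 1e-12)):
        raise ValueError("pressure falls below the diastolic anchor P_d")
    a = a_d * (1.0 + np.log(np.maximum(p, p_d) / p_d) / alpha)
    return pressure.with_values(a, "cm2")


def generate_wk2_pressure(flow: Waveform, r: float, c: float) -> Waveform:
    """Periodic steady-state pressure of the 2-element windkessel.

    Solves ``dP/dt = Q/C − P/(RC)`` exactly in the frequency domain (the
    discrete periodic solution): each flow harmonic is attenuated by the
    first-order filter ``R/(1 + iωRC)``.  The mean obeys ``mean(P) = R mean(Q)``.
    """
    if r <= 0 or c <= 0:
        raise ValueError("R and C must be positive")
    q = flow.values
    qh = np.fft.rfft(q)
    omega = 2.0 * np.pi * np.fft.rfftfreq(flow.n, flow.dt)
    ph = r * qh / (1.0 + 1j * omega * r * c)
    p = np.fft.irfft(ph, flow.n)
    return flow.with_values(p, "mmHg")


# ---------------------------------------------------------------------------
# full cohort (shapes + waveforms + covariates)


@dataclass
class SubjectRecord:
    """Everything the analysis consumes for one synthetic subject."""

    subject_id: str
    centreline: Centreline
    flow: Waveform
    area: Waveform
    p_sbp: float
    dbp: float
    mbp: float
    bsa: float
    lvmi: float
    lvef: float
    gothic: bool
    truth: dict

    def __post_init__(self) -> None:
        if not self.dbp < self.mbp < self.p_sbp:
            raise ValueError("require DBP < MBP < p-SBP")
        if self.bsa <= 0:
            raise ValueError("BSA must be positive")


@dataclass
class CohortConfig:
    """Conditions of the full synthetic study cohort."""

    population: PopulationConfig = field(default_factory=lambda: PopulationConfig())
    wave: WaveGenConfig = field(default_factory=WaveGenConfig)
    # reflection magnitude linked to radius-mode weights (per-mm coefficients):
    # calibre changes cause impedance mismatch, hence stronger reflection
    reflection_rule: dict[str, float] = field(default_factory=dict)
    gamma_noise_sd: float = 0.04


def default_population_config(n_subjects: int = 60, seed: int = 0) -> PopulationConfig:
    """Study-like defaults: 3 curvature + 3 radius modes, gothic label on arch angulation."""
    modes = [
        ModeDef("ascending_length", "curvature", 6.0),
        ModeDef("arch_angulation", "curvature", 2.5),
        ModeDef("descending_bow", "curvature", 1.5),
        ModeDef("ascending_dilation", "radius", 3.5),
        ModeDef("transverse_arch", "radius", 2.0),
        ModeDef("isthmus", "radius", 1.5),
    ]
    return PopulationConfig(
        n_subjects=n_subjects, seed=seed, mode_defs=modes, noise_sd=0.15,
        gothic_rule=("arch_angulation", 0.8, -1.4),
    )


def default_cohort_config(n_subjects: int = 60, seed: int = 0) -> CohortConfig:
    return CohortConfig(
        population=default_population_config(n_subjects, seed),
        wave=WaveGenConfig(),
        reflection_rule={
            "ascending_dilation": 0.015,  # larger root -> more reflection
            "transverse_arch": -0.02,     # arch hypoplasia -> more reflection
            "isthmus": -0.02,             # isthmus narrowing -> more reflection
        },
    )


def generate_cohort(cfg: CohortConfig) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate shapes, waveforms and covariates for a whole cohort.

    Per-subject wave parameters (speed, amplitude, baseline area, reflection
    delay) vary around the configured values; the reflection coefficient is
    tied to the radius-mode weights through ``reflection_rule`` so that
    calibre modes — and only calibre modes — drive the backward wave.
    """
    rng = np.random.default_rng(cfg.population.seed)
    shapes, truth = generate_centerline_population(cfg.population, rng)
    records: list[SubjectRecord] = []
    wave_rows = []
    for i, cl in enumerate(shapes):
        sid = cl.subject_id
        trow = truth.loc[sid]
        gamma = cfg.wave.reflection_coeff
        for mode_id, coef in cfg.reflection_rule.items():
            gamma += coef * trow[f"w_{mode_id}"]
        gamma += rng.normal(0.0, cfg.gamma_noise_sd)
        gamma = float(np.clip(gamma, 0.02, 0.85))
        wcfg = WaveGenConfig(
            period=cfg.wave.period, dt=cfg.wave.dt,
            amplitude=float(max(0.25, rng.normal(cfg.wave.amplitude, 0.08))),
            onset=cfg.wave.onset, width=cfg.wave.width,
            wave_speed=float(np.clip(rng.normal(cfg.wave.wave_speed, 35.0),
                                     300.0, 520.0)),
            reflection_coeff=gamma,
            reflection_delay=float(np.clip(rng.normal(cfg.wave.reflection_delay,
                                                      0.02), 0.12, 0.25)),
            baseline_area=float(max(3.0, rng.normal(cfg.wave.baseline_area, 0.7))),
            baseline_flow=cfg.wave.baseline_flow,
            pulse_power=cfg.wave.pulse_power,
        )
        flow, area, wtruth = generate_waveforms(wcfg)

        dbp = float(np.clip(rng.normal(70.0, 8.0), 52.0, 95.0))
        pp = float(np.clip(rng.normal(53.0, 10.0), 28.0, 85.0))
        p_sbp = dbp + pp
        mbp = float(np.clip(dbp + pp / 3.0 + rng.normal(0.0, 1.5),
                            dbp + 2.0, p_sbp - 2.0))
        bsa = float(np.clip(rng.normal(1.9, 0.2), 1.4, 2.5))
        lvmi = float(max(35.0, rng.normal(72.0, 14.0)))
        lvef = float(np.clip(rng.normal(66.0, 7.5), 45.0, 80.0))
        gothic = bool(trow["gothic"]) if "gothic" in trow else False

        records.append(SubjectRecord(
            subject_id=sid, centreline=cl, flow=flow, area=area,
            p_sbp=p_sbp, dbp=dbp, mbp=mbp, bsa=bsa, lvmi=lvmi, lvef=lvef,
            gothic=gothic, truth={**wtruth, "gamma": gamma},
        ))
        wave_rows.append({"id": sid, **wtruth})
    wave_truth = pd.DataFrame(wave_rows).set_index("id")
    truth = truth.join(wave_truth)
    return records, truth
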