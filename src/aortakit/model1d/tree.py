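"""Arterial tree description for the 1D pulse-wave model.

Vessels are tapered elastic tubes with the tube law

    P = P_ext + beta (sqrt(A) - sqrt(A0)) / A0,

whose linear wave speed is ``c0 = sqrt(beta sqrt(A0) / (2 rho A0))``.  A
segment is specified by its length, proximal/distal radius (linear taper)
and either the stiffness coefficient ``beta`` (dyn/cm³) or, more
conveniently, a reference wave speed ``c0`` (cm/s) from which a per-node
beta is computed.  Leaves close with a 3-element windkessel (characteristic
impedance Zc, peripheral resistance Rp, compliance Cp, CGS units), a
non-reflecting ("matched") condition, or a closed end.

Internal units are CGS (cm, g, s, dyn); pressures cross the API boundary in
mmHg (1 mmHg = 1333.22 dyn/cm²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MMHG = 1333.22          # dyn/cm² per mmHg
RHO = 1.06              # blood density, g/cm³
NU = 0.035              # kinematic viscosity, cm²/s

__all__ = ["MMHG", "RHO", "NU", "WindkesselRCR", "Segment", "ArterialTree",
           "build_tree", "default_tree_config", "default_segment_map",
           "apply_radius_profile"]


@dataclass
class WindkesselRCR:
    """RCR terminal closure (CGS: dyn·s/cm⁵ and cm⁵/dyn)."""

    z_c: float
    r_p: float
    c_p: float

    def __post_init__(self) -> None:
        if self.z_c < 0 or self.c_p < 0:
            raise ValueError("Zc and Cp must be >= 0")
        if self.r_p <= 0:
            raise ValueError("Rp must be positive")


@dataclass
class Segment:
    """One tapered vessel with its discretisation-ready geometry."""

    seg_id: str
    length: float                 # cm
    r_prox: float                 # cm
    r_dist: float                 # cm
    children: list[str] = field(default_factory=list)
    c0: float | None = None       # cm/s reference wave speed
    beta: float | None = None     # dyn/cm³ stiffness (constant along segment)
    terminal: WindkesselRCR | str | None = None   # RCR | "matched" | "closed"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.r_prox <= 0 or self.r_dist <= 0:
            raise ValueError(f"segment {self.seg_id}: length and radii must be > 0")
        if (self.c0 is None) == (self.beta is None):
            raise ValueError(f"segment {self.seg_id}: give exactly one of c0 or beta")
        if len(self.children) > 2:
            raise ValueError(f"segment {self.seg_id}: at most 2 children")
        if self.children and self.terminal is not None:
            raise ValueError(f"segment {self.seg_id}: terminal on a non-leaf")

    def discretise(self, dx: float, rho: float = RHO) -> dict:
        """Per-node reference geometry and stiffness on a uniform grid."""
        n = max(3, int(round(self.length / dx)) + 1)
        x = np.linspace(0.0, self.length, n)
        r = self.r_prox + (self.r_dist - self.r_prox) * x / self.length
        a0 = np.pi * r ** 2
        if self.beta is not None:
            beta = np.full(n, float(self.beta))
            c0 = np.sqrt(beta * np.sqrt(a0) / (2.0 * rho * a0))
        else:
            c0 = np.full(n, float(self.c0))
            beta = 2.0 * rho * c0 ** 2 * np.sqrt(a0)
        return {"x": x, "a0": a0, "beta": beta, "c0": c0,
                "dx": float(x[1] - x[0])}


@dataclass
class ArterialTree:
    """Validated, connected tree of segments (exactly one root, acyclic)."""

    segments: dict[str, Segment]
    root: str
    rho: float = RHO
    nu: float = NU

    @property
    def leaves(self) -> list[str]:
        return [s for s, seg in self.segments.items() if not seg.children]


def build_tree(config: dict) -> ArterialTree:
    """Build and validate an :class:`ArterialTree` from a plain config dict.

    The config mirrors the YAML schema: a ``segments`` list with
    ``id, length_cm, r_prox_cm, r_dist_cm, c0_cm_s | beta, children`` and an
    optional ``terminal`` (mapping with Zc/Rp/Cp, or the strings
    ``"matched"`` / ``"closed"``); optional ``rho``/``nu`` overrides.
    """
    segments: dict[str, Segment] = {}
    for sc in config["segments"]:
        term = sc.get("terminal")
        if isinstance(term, dict):
            term = WindkesselRCR(z_c=float(term["Zc"]), r_p=float(term["Rp"]),
                                 c_p=float(term.get("Cp", 0.0)))
        seg = Segment(
            seg_id=str(sc["id"]),
            length=float(sc["length_cm"]),
            r_prox=float(sc["r_prox_cm"]),
            r_dist=float(sc["r_dist_cm"]),
            children=[str(c) for c in sc.get("children", [])],
            c0=float(sc["c0_cm_s"]) if "c0_cm_s" in sc else None,
            beta=float(sc["beta"]) if "beta" in sc else None,
            terminal=term,
        )
        if seg.seg_id in segments:
            raise ValueError(f"duplicate segment id {seg.seg_id!r}")
        segments[seg.seg_id] = seg

    referenced: list[str] = []
    for seg in segments.values():
        for c in seg.children:
            if c not in segments:
                raise ValueError(f"segment {seg.seg_id} references unknown child {c!r}")
            referenced.append(c)
    if len(referenced) != len(set(referenced)):
        raise ValueError("a segment has more than one parent")
    roots = [s for s in segments if s not in referenced]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {roots}")
    root = roots[0]

    # reachability (orphans) and acyclicity: DFS from the root
    seen: set[str] = set()
    stack = [root]
    while stack:
        s = stack.pop()
        if s in seen:
            raise ValueError("tree contains a cycle")
        seen.add(s)
        stack.extend(segments[s].children)
    if seen != set(segments):
        raise ValueError(f"orphan segments: {sorted(set(segments) - seen)}")

    for leaf in (s for s in segments.values() if not s.children):
        if leaf.terminal is None:
            raise ValueError(f"leaf segment {leaf.seg_id} has no terminal")

    return ArterialTree(segments=segments, root=root,
                        rho=float(config.get("rho", RHO)),
                        nu=float(config.get("nu", NU)))


# ---------------------------------------------------------------------------
# default reduced systemic tree

# Aorta (sinotubular junction -> diaphragm) split into 10 segments so the
# 100-point radius profile is faithfully resolved: boundaries sit at the
# arch branch ostia and at the anatomically informative stations (ascending
# belly, transverse arch, isthmus).  Fractions are arc length along the
# profile.
_AORTA_CHAIN: tuple[tuple[str, float, float], ...] = (
    ("asc1", 0.000, 0.073),
    ("asc2", 0.073, 0.147),
    ("asc3", 0.147, 0.220),
    ("arch1", 0.220, 0.300),
    ("arch2", 0.300, 0.380),
    ("desc1", 0.380, 0.450),
    ("desc2", 0.450, 0.520),
    ("desc3", 0.520, 0.680),
    ("desc4", 0.680, 0.840),
    ("desc5", 0.840, 1.000),
)


def default_segment_map() -> dict[str, tuple[float, float]]:
    return {name: (f0, f1) for name, f0, f1 in _AORTA_CHAIN}


def default_tree_config(c0_aorta: float = 470.0, c0_branch: float = 580.0,
                        mbp_target_mmhg: float = 90.0,
                        co_target_ml_s: float = 83.0) -> dict:
    """Reduced systemic tree: 4 aortic segments + 3 arch branches, RCR leaves.

    Terminal resistances split the target cardiac output roughly 70% to the
    lower body and 10% to each arch branch, sized so the mean root pressure
    settles near ``mbp_target_mmhg`` at the target output.  Compliances are
    distributed in proportion to 1/R and sum to about 1.1 ml/mmHg.
    """
    rtot = mbp_target_mmhg * MMHG / co_target_ml_s    # dyn·s/cm⁵
    shares = {"desc": 0.70, "innominate": 0.11, "l_carotid": 0.08,
              "l_subclavian": 0.11}
    ctot = 1.1 / MMHG                                  # cm⁵/dyn
    leaf_radius = {"desc": 0.90, "innominate": 0.55, "l_carotid": 0.40,
                   "l_subclavian": 0.50}

    def rcr(leaf: str, c0: float) -> dict:
        a = np.pi * leaf_radius[leaf] ** 2
        zc = RHO * c0 / a
        r_total = rtot / shares[leaf]
        return {"Zc": zc, "Rp": max(r_total - zc, 0.1 * r_total),
                "Cp": ctot * shares[leaf]}

    # baseline aortic radius at an arc-length fraction (mirrors the mean
    # post-repair anatomy: 1.25 cm ascending tapering to 0.90 cm at the
    # diaphragm)
    def r_base(f: float) -> float:
        if f <= 0.18:
            return 1.25
        if f <= 0.40:
            u = (f - 0.18) / 0.22
            return 1.25 - 0.33 * u * u * (3.0 - 2.0 * u)
        return 0.92 - 0.02 * (f - 0.40) / 0.60

    aorta_len = 28.0
    branch_after = {"asc3": "innominate", "arch1": "l_carotid",
                    "arch2": "l_subclavian"}
    segments = []
    for i, (name, f0, f1) in enumerate(_AORTA_CHAIN):
        nxt = _AORTA_CHAIN[i + 1][0] if i + 1 < len(_AORTA_CHAIN) else None
        children = []
        if name in branch_after:
            children.append(branch_after[name])
        if nxt is not None:
            children.append(nxt)
        seg = {"id": name, "length_cm": aorta_len * (f1 - f0),
               "r_prox_cm": r_base(f0), "r_dist_cm": r_base(f1),
               "c0_cm_s": c0_aorta}
        if children:
            seg["children"] = children
        else:
            seg["terminal"] = rcr("desc", c0_aorta)
        segments.append(seg)
    segments += [
        {"id": "innominate", "length_cm": 3.5, "r_prox_cm": 0.60,
         "r_dist_cm": 0.55, "c0_cm_s": c0_branch,
         "terminal": rcr("innominate", c0_branch)},
        {"id": "l_carotid", "length_cm": 4.0, "r_prox_cm": 0.45,
         "r_dist_cm": 0.40, "c0_cm_s": c0_branch,
         "terminal": rcr("l_carotid", c0_branch)},
        {"id": "l_subclavian", "length_cm": 4.0, "r_prox_cm": 0.55,
         "r_dist_cm": 0.50, "c0_cm_s": c0_branch,
         "terminal": rcr("l_subclavian", c0_branch)},
    ]
    return {"rho": RHO, "nu": NU, "segments": segments}


def apply_radius_profile(config: dict, profile_cm: np.ndarray,
                         segment_map: dict[str, tuple[float, float]] | None = None,
                         ) -> dict:
    """Set aortic segment radii from a 100-point proto-aorta radius profile.

    ``segment_map`` assigns each aortic segment the arc-length fraction range
    of the profile it covers; proximal/distal radii are read off the profile
    at the range ends.  Non-aortic segments are untouched.
    """
    profile = np.asarray(profile_cm, dtype=float)
    if np.any(profile <= 0):
        raise ValueError("radius profile must be strictly positive")
    if segment_map is None:
        segment_map = default_segment_map()
    s = np.linspace(0.0, 1.0, profile.size)
    out = {k: v for k, v in config.items() if k != "segments"}
    out["segments"] = []
    for sc in config["segments"]:
        sc = dict(sc)
        if sc["id"] in segment_map:
            f0, f1 = segment_map[sc["id"]]
            sc["r_prox_cm"] = float(np.interp(f0, s, profile))
            sc["r_dist_cm"] = float(np.interp(f1, s, profile))
        out["segments"].append(sc)
    return out
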