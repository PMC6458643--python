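"""Statistical shape modelling of aortic centrelines.

The aorta's 3D shape is decomposed into two independent descriptors that are
analysed separately:

* *curvature* — the registered 3D coordinates of the centreline (the course
  of the vessel through space), and
* *radius* — the calibre profile along the centreline.

Centrelines are first resampled to a fixed number of equally spaced points
(arc-length correspondence), scaled to a common length, and rigidly
registered (rotation + translation only, no scaling, no reflection) to a
population reference built by generalised Procrustes alignment.  Principal
component analysis is then run separately on the coordinate data and on the
mean-scaled radius profiles; each subject is expressed as a weighted sum of
the leading components.  A reconstruction at a chosen weight along one
component is a "proto-aorta" that can be fed to the 1D pulse-wave model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Centreline

__all__ = [
    "ShapeModel",
    "GeometryIndices",
    "resample_centreline",
    "normalise_length",
    "normalise_radius",
    "rigid_register",
    "build_reference",
    "fit_shape_model",
    "project",
    "reconstruct",
    "geometry_indices",
]


# ---------------------------------------------------------------------------
# resampling and normalisation


def resample_centreline(cl: Centreline, n_points: int = 100) -> Centreline:
    """Resample to ``n_points`` equally spaced in arc length.

    Coordinates and radius are linearly interpolated at the uniform
    arc-length parameters; landmarks are mapped to the nearest new index.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    s = cl.arc_length()
    s_new = np.linspace(0.0, s[-1], n_points)
    pts = np.column_stack([np.interp(s_new, s, cl.points[:, k]) for k in range(3)])
    rad = np.interp(s_new, s, cl.radius)
    landmarks = {
        name: int(np.argmin(np.abs(s_new - s[idx])))
        for name, idx in cl.landmarks.items()
    }
    return Centreline(pts, rad, landmarks, cl.subject_id)


def normalise_length(cl: Centreline, target_length: float) -> Centreline:
    """Uniformly scale coordinates about the centroid to a target arc length.

    The radius profile is left untouched; radius scaling is a separate,
    independent normalisation (:func:`normalise_radius`).
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    length = cl.length
    if length == 0:
        raise ValueError("cannot scale a zero-length centreline")
    centroid = cl.points.mean(axis=0)
    pts = centroid + (cl.points - centroid) * (target_length / length)
    return Centreline(pts, cl.radius.copy(), dict(cl.landmarks), cl.subject_id)


def normalise_radius(cl: Centreline, target_mean_radius: float) -> Centreline:
    """Scale the radius profile so its mean equals the target; coordinates untouched."""
    if target_mean_radius <= 0:
        raise ValueError("target_mean_radius must be positive")
    rad = cl.radius * (target_mean_radius / cl.radius.mean())
    return Centreline(cl.points.copy(), rad, dict(cl.landmarks), cl.subject_id)


# ---------------------------------------------------------------------------
# rigid registration


def _kabsch(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation taking source onto target.

    Reflections are forbidden (det R = +1): anatomy has a fixed chirality, so
    a mirror image must register through the best proper rotation even if a
    reflection would fit better.
    """
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (source - mu_s).T @ (target - mu_t)
    u, sing, vt = np.linalg.svd(h)
    if sing[1] <= sing[0] * 1e-12:
        warnings.warn("near-collinear point set: registration may be non-unique",
                      stacklevel=3)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_s
    return rot, trans


def rigid_register(cl: Centreline, reference: Centreline) -> Centreline:
    """Rigidly register (rotation + translation, det(R) = +1) onto a reference.

    Point correspondence is by index, so both centrelines must be resampled
    to the same number of points.
    """
    if cl.n_points != reference.n_points:
        raise ValueError("centreline and reference must have equal point counts")
    rot, trans = _kabsch(cl.points, reference.points)
    pts = cl.points @ rot.T + trans
    return Centreline(pts, cl.radius.copy(), dict(cl.landmarks), cl.subject_id)


def _best_fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through the points."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[2]


def _canonical_orientation(points: np.ndarray) -> np.ndarray:
    """Rotate a centred shape into a deterministic pose.

    The principal axes of the point cloud are mapped onto x/y/z (x = largest
    in-plane spread, z = best-fit-plane normal).  Axis signs are fixed by the
    start-to-end chord and the circulation of the curve, so the pose is
    independent of the arbitrary rotation left over by Procrustes alignment.
    """
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v1, _, v3 = vt
    chord = centred[-1] - centred[0]
    if np.dot(v1, chord) < 0:
        v1 = -v1
    circulation = np.cross(centred[:-1], centred[1:]).sum(axis=0)
    if np.dot(v3, circulation) < 0:
        v3 = -v3
    v2 = np.cross(v3, v1)
    rot = np.vstack([v1, v2, v3])  # maps v1->ex, v2->ey, v3->ez
    return centred @ rot.T


def build_reference(population: list[Centreline], tol: float = 1e-10,
                    max_iter: int = 100,
                    return_n_iter: bool = False):
    """Generalised Procrustes alignment: the population mean shape.

    All centrelines are iteratively registered to the running mean until the
    mean stops moving.  The returned reference is centred at the origin and
    put in a canonical pose whose x-y plane is the best-fit plane of the mean
    shape (which, after alignment, coincides with the average best-fit plane
    of the population).
    """
    if len(population) < 2:
        raise ValueError("need at least 2 centrelines to build a reference")
    n = population[0].n_points
    if any(cl.n_points != n for cl in population):
        raise ValueError("all centrelines must be resampled to equal point counts")
    centred = [cl.points - cl.points.mean(axis=0) for cl in population]
    # start from the raw mean (the fixed point itself when the population is
    # already aligned); fall back to the first shape if poses are so spread
    # that the raw mean collapses toward zero
    ref = np.mean(centred, axis=0)
    if np.linalg.norm(ref) < 0.1 * np.linalg.norm(centred[0]):
        ref = centred[0]
    n_iter = max_iter
    for it in range(max_iter):
        registered = []
        for cl in population:
            rot, trans = _kabsch(cl.points, ref)
            registered.append(cl.points @ rot.T + trans)
        mean = np.mean(registered, axis=0)
        mean -= mean.mean(axis=0)
        change = np.sqrt(np.mean((mean - ref) ** 2))
        ref = mean
        if change < tol:
            n_iter = it + 1
            break
    else:
        raise RuntimeError("generalised Procrustes alignment did not converge")
    ref = _canonical_orientation(ref)
    mean_radius = np.mean([cl.radius for cl in population], axis=0)
    out = Centreline(ref, mean_radius, dict(population[0].landmarks), "reference")
    return (out, n_iter) if return_n_iter else out


# ---------------------------------------------------------------------------
# principal component analysis


@dataclass
class ShapeModel:
    """PCA model of one shape descriptor over a population.

    ``kind`` is ``"curvature"`` (features: concatenated x,y,z of the
    registered 100-point centreline, a 300-vector) or ``"radius"`` (features:
    the 100-point mean-scaled radius profile).  ``components`` are orthonormal
    rows; ``sd`` is the standard deviation of the population scores along each
    component, and ``subject_weights`` are per-subject scores in SD units
    (population SD of every column is 1 by construction).
    """

    kind: str
    mean_vector: np.ndarray
    components: np.ndarray        # (k, d), orthonormal rows
    variance_fraction: np.ndarray  # (k,)
    sd: np.ndarray                 # (k,) score SD in feature units
    subject_weights: np.ndarray    # (n_subjects, k), SD units
    n_points: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def _feature_vector(cl: Centreline, kind: str) -> np.ndarray:
    if kind == "curvature":
        return cl.points.ravel()
    if kind == "radius":
        return cl.radius.copy()
    raise ValueError(f"unknown shape kind {kind!r}")


def fit_shape_model(population: list[Centreline], kind: str,
                    n_components: int = 5) -> ShapeModel:
    """Mean-centred PCA (via SVD) of curvature or radius features.

    No per-feature variance scaling is applied — the components live in the
    original geometric units (mm), so a reconstruction is directly a shape.
    Components are sign-fixed so the loading of largest magnitude is positive.
    """
    if len(population) < n_components + 1:
        raise ValueError("need at least n_components + 1 subjects")
    x = np.array([_feature_vector(cl, kind) for cl in population])
    mean = x.mean(axis=0)
    xc = x - mean
    u, sing, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float((sing ** 2).sum())
    scale = max(1.0, float(np.linalg.norm(mean)))
    if sing[0] <= 1e-10 * scale:
        raise ValueError("population has zero shape variance")
    rank = int(np.sum(sing > sing[0] * 1e-12))
    k = n_components
    if k > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; "
                      "truncating", stacklevel=2)
        k = rank
    components = vt[:k].copy()
    scores = u[:, :k] * sing[:k]        # (n, k)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
            scores[:, i] = -scores[:, i]
    n = x.shape[0]
    var = sing[:k] ** 2 / (n - 1)
    sd = np.sqrt(var)
    return ShapeModel(
        kind=kind,
        mean_vector=mean,
        components=components,
        variance_fraction=sing[:k] ** 2 / total_var,
        sd=sd,
        subject_weights=scores / sd,
        n_points=population[0].n_points,
    )


def project(model: ShapeModel, cl: Centreline | np.ndarray) -> np.ndarray:
    """Score a shape against the model, in SD units per component."""
    x = cl if isinstance(cl, np.ndarray) else _feature_vector(cl, model.kind)
    if x.shape != model.mean_vector.shape:
        raise ValueError(
            f"feature vector length {x.shape} does not match model "
            f"{model.mean_vector.shape}")
    return (x - model.mean_vector) @ model.components.T / model.sd


def reconstruct(model: ShapeModel, weights: np.ndarray) -> np.ndarray:
    """Reconstruct a proto-shape at the given display weights.

    Display weight ±1 maps to ±2 population SD along each component, matching
    the convention used to visualise the extremes of each mode.
    """
    w = np.asarray(weights, dtype=float)
    if w.size > model.n_components:
        raise ValueError("more weights than model components")
    k = w.size
    return model.mean_vector + (w * 2.0 * model.sd[:k]) @ model.components[:k]


# ---------------------------------------------------------------------------
# clinical geometry indices


@dataclass
class GeometryIndices:
    """Diameter-ratio indices of residual narrowing and arch hypoplasia."""

    coarctation_index: float   # isthmus diameter / descending (diaphragm) diameter
    arch_index: float          # transverse arch diameter / descending diameter


_INDEX_LANDMARKS = ("innominate_LCC_midpoint", "isthmus", "diaphragm")


def geometry_indices(cl: Centreline) -> GeometryIndices:
    """Coarctation and arch indices from landmark diameters (2 x inscribed radius)."""
    for name in _INDEX_LANDMARKS:
        if name not in cl.landmarks:
            raise KeyError(f"missing landmark {name!r}")
    d = {name: 2.0 * cl.radius[cl.landmarks[name]] for name in _INDEX_LANDMARKS}
    return GeometryIndices(
        coarctation_index=d["isthmus"] / d["diaphragm"],
        arch_index=d["innominate_LCC_midpoint"] / d["diaphragm"],
    )
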