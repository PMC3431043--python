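"""Landmark-based spatial transforms: rigid, affine and thin-plate spline.

These are the computational core of the registration scheme: hemisphere
stacks are rigidly aligned into the reference frame (no scaling — size and
shape are preserved when building the average brain), while regions and
neuron morphologies are registered non-rigidly with a thin-plate spline
(TPS) interpolating at least four named landmarks.

The 3D TPS uses the biharmonic kernel ``U(r) = r`` (the correct Green's
function in three dimensions; the 2D ``r^2 log r`` kernel does not apply).
With regularisation ``lam = 0`` the spline interpolates the landmarks
exactly; ``lam > 0`` trades exactness for smoothness.

Image resampling uses inverse mapping.  Rigid and affine transforms invert
analytically; a TPS has no closed-form inverse, so the inverse is fitted by
exchanging the roles of source and destination landmarks (the same landmark
file drives both directions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import ndimage

from .formats import ImageStack, LandmarkSet, Morphology

__all__ = [
    "DegenerateFitError",
    "RigidTransform",
    "AffineTransform",
    "TPSTransform",
    "IdentityTransform",
    "fit_rigid",
    "fit_affine",
    "fit_tps",
    "apply_points",
    "apply_morphology",
    "resample_image",
    "mirror",
]


class DegenerateFitError(ValueError):
    """The landmark configuration cannot determine the requested transform."""


def _matched_coords(src: LandmarkSet, dst: LandmarkSet) -> tuple[np.ndarray, np.ndarray]:
    names = src.common_names(dst)
    return src.coords(names), dst.coords(names)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LandmarkSet):
        return obj.coords()
    return np.atleast_2d(np.asarray(obj, dtype=float))


# ---------------------------------------------------------------------------
# Transform classes
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Rotation (proper, det = +1) plus translation; preserves distances."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflection is not a rigid transform here; use mirror()")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return _as_points(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """self(inner(x))."""
        return RigidTransform(self.rotation @ inner.rotation,
                              self.rotation @ inner.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AffineTransform:
    """General invertible linear map plus translation."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is numerically singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return _as_points(points) @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TPSTransform:
    """3D thin-plate spline ``f(x) = A [1; x] + sum_i w_i U(|x - s_i|)``.

    ``affine`` is 3x4 (translation column first), ``warp`` is (n, 3).  The
    source and destination landmarks are retained so the inverse spline can
    be fitted by swapping their roles.
    """

    source: np.ndarray
    destination: np.ndarray
    affine: np.ndarray
    warp: np.ndarray
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.destination = np.asarray(self.destination, dtype=float).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float).reshape(3, 4)
        self.warp = np.asarray(self.warp, dtype=float).reshape(-1, 3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _as_points(points)
        # kernel U(r) = r, evaluated point-vs-landmark
        r = np.linalg.norm(pts[:, None, :] - self.source[None, :, :], axis=2)
        poly = np.concatenate([np.ones((len(pts), 1)), pts], axis=1)
        return poly @ self.affine.T + r @ self.warp

    def inverse(self) -> "TPSTransform":
        """Approximate inverse: the TPS fitted with landmarks swapped."""
        return _fit_tps_points(self.destination, self.source, self.lam)

    def warp_norm(self) -> float:
        return float(np.linalg.norm(self.warp))


class IdentityTransform:
    """No-op transform (useful as a default and in tests)."""

    def apply(self, points: np.ndarray) -> np.ndarray:
        return _as_points(points).copy()

    def inverse(self) -> "IdentityTransform":
        return self


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_rigid(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Least-squares rotation + translation (orthogonal Procrustes, no scaling).

    Landmarks are paired by name.  Reflections are excluded: the recovered
    rotation always has determinant +1, so hemispheres can never be flipped
    silently.  Requires >= 3 non-collinear pairs.
    """
    s, d = _matched_coords(src, dst)
    if len(s) < 3:
        raise DegenerateFitError(
            f"rigid fit needs >= 3 shared landmarks, got {len(s)}")
    sc, dc = s - s.mean(axis=0), d - d.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError("landmarks are collinear; rotation undetermined")
    u, _, vt = np.linalg.svd(sc.T @ dc)
    sign = np.sign(np.linalg.det(u @ vt)) or 1.0
    rot = (u @ np.diag([1.0, 1.0, sign]) @ vt).T
    t = d.mean(axis=0) - rot @ s.mean(axis=0)
    return RigidTransform(rot, t)


def fit_affine(src: LandmarkSet, dst: LandmarkSet) -> AffineTransform:
    """Least-squares 12-parameter affine fit from >= 4 non-coplanar pairs."""
    s, d = _matched_coords(src, dst)
    _check_affine_geometry(s)
    design = np.concatenate([s, np.ones((len(s), 1))], axis=1)
    sol, *_ = np.linalg.lstsq(design, d, rcond=None)
    return AffineTransform(sol[:3].T, sol[3])


def _check_affine_geometry(s: np.ndarray, what: str = "affine") -> None:
    if len(s) < 4:
        raise DegenerateFitError(
            f"{what} fit needs >= 4 shared landmarks, got {len(s)}")
    sv = np.linalg.svd(s - s.mean(axis=0), compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateFitError(
            f"{what} fit: landmarks are coplanar; add out-of-plane points")


def _fit_tps_points(s: np.ndarray, d: np.ndarray, lam: float) -> TPSTransform:
    _check_affine_geometry(s, what="thin-plate-spline")
    n = len(s)
    r = np.linalg.norm(s[:, None, :] - s[None, :, :], axis=2)
    K = r + lam * np.eye(n)
    P = np.concatenate([np.ones((n, 1)), s], axis=1)
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = d
    try:
        sol = scipy.linalg.solve(L, rhs)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateFitError(
            f"singular thin-plate-spline system for this landmark geometry: {exc}"
        ) from exc
    return TPSTransform(s, d, sol[n:].T, sol[:n], lam)


def fit_tps(src: LandmarkSet, dst: LandmarkSet, lam: float = 0.0) -> TPSTransform:
    """Fit a 3D thin-plate spline from name-matched landmark pairs.

    With ``lam = 0`` the spline maps each source landmark exactly onto its
    destination; the warp coefficients satisfy the usual side conditions
    (zero sum, orthogonal to the source coordinates).  At least four
    non-coplanar pairs are required.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    s, d = _matched_coords(src, dst)
    return _fit_tps_points(s, d, lam)


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def apply_points(transform, points: np.ndarray) -> np.ndarray:
    """Map an (n, 3) um point array through any transform."""
    return transform.apply(points)


def _jacobian_scale(transform, xyz: np.ndarray, h: float = 0.5) -> np.ndarray:
    """|det J|^(1/3) at each point, J estimated by central differences (h um)."""
    n = len(xyz)
    J = np.empty((n, 3, 3))
    for axis in range(3):
        step = np.zeros(3)
        step[axis] = h
        J[:, :, axis] = (transform.apply(xyz + step)
                         - transform.apply(xyz - step)) / (2 * h)
    return np.abs(np.linalg.det(J)) ** (1.0 / 3.0)


def apply_morphology(transform, m: Morphology,
                     radius_policy: str = "fixed") -> Morphology:
    """Map a morphology's coordinates; topology and ids are untouched.

    ``radius_policy``:

    * ``"fixed"`` (default) — radii unchanged; the registration workflow
      transforms SWC geometry only.
    * ``"local_scale"`` — each radius multiplied by the local isotropic
      volume scale ``|det J|^(1/3)`` of the transform.
    """
    if radius_policy not in ("fixed", "local_scale"):
        raise ValueError(f"unknown radius_policy {radius_policy!r}")
    out = m.copy()
    out.xyz = transform.apply(m.xyz)
    if not np.all(np.isfinite(out.xyz)):
        raise ValueError("transform mapped morphology nodes to non-finite coordinates")
    if radius_policy == "local_scale":
        out.radii = m.radii * _jacobian_scale(transform, m.xyz)
    out.validate()
    return out


def resample_image(transform, stack: ImageStack,
                   out_geometry: ImageStack | None = None,
                   *, order: int = 1, cval: float = 0.0) -> ImageStack:
    """Resample ``stack`` through ``transform`` into a reference geometry.

    ``transform`` maps *input-stack* physical coordinates to *reference*
    physical coordinates; resampling walks the other way (inverse mapping
    with trilinear interpolation), so each output voxel looks up where it
    came from.  Output geometry (shape, spacing, origin) is taken from
    ``out_geometry`` (default: the input's own geometry).  Out-of-field
    voxels are ``cval`` (0).
    """
    ref = out_geometry if out_geometry is not None else stack
    inv = transform.inverse()
    nz, ny, nx = ref.shape
    out = np.empty(ref.shape, dtype=np.float64)
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    flat_j, flat_i = jj.ravel(), ii.ravel()
    vol = stack.voxels.astype(np.float64, copy=False)
    for k in range(nz):  # slab-wise to bound memory
        kji = np.stack([np.full(flat_j.shape, k), flat_j, flat_i], axis=1)
        pts_ref = ref.index_to_physical(kji)
        pts_src = inv.apply(pts_ref)
        idx = stack.physical_to_index(pts_src)
        out[k] = ndimage.map_coordinates(
            vol, idx.T, order=order, mode="constant", cval=cval
        ).reshape(ny, nx)
    if np.issubdtype(stack.voxels.dtype, np.integer):
        info = np.iinfo(stack.voxels.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return ImageStack(out.astype(stack.voxels.dtype), ref.spacing, ref.origin)


# ---------------------------------------------------------------------------
# Mirroring (explicit reflection; bilateral-symmetry workflow)
# ---------------------------------------------------------------------------

_AXIS_TO_COL = {"x": 0, "y": 1, "z": 2}


def mirror(obj, axis: str = "x", extent: tuple[float, float] | float | None = None):
    """Reflect a stack, morphology or landmark set about a volume midplane.

    The average-brain scheme treats hemispheres as independent samples under
    a bilateral-symmetry assumption, so left hemispheres are mirrored before
    alignment.  Reflection is deliberately separate from rigid fitting
    (which forbids reflections).

    For an :class:`ImageStack` the midplane is the stack's own midplane and
    ``extent`` is ignored.  For point-based objects ``extent`` gives the
    field along ``axis`` as ``(lo, hi)`` um (a bare number means ``(0, w)``),
    and each coordinate ``c`` maps to ``lo + hi - c``.
    """
    if axis not in _AXIS_TO_COL:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}")
    col = _AXIS_TO_COL[axis]
    if isinstance(obj, ImageStack):
        arr_axis = 2 - col  # (z, y, x) storage
        return obj.with_voxels(np.flip(obj.voxels, axis=arr_axis).copy())
    if extent is None:
        raise ValueError("mirroring points requires an extent along the axis")
    if np.isscalar(extent):
        lo, hi = 0.0, float(extent)  # type: ignore[arg-type]
    else:
        lo, hi = (float(v) for v in extent)  # type: ignore[misc]
    if isinstance(obj, Morphology):
        out = obj.copy()
        out.xyz[:, col] = lo + hi - out.xyz[:, col]
        return out
    if isinstance(obj, LandmarkSet):
        pts = obj.coords()
        pts[:, col] = lo + hi - pts[:, col]
        return LandmarkSet(dict(zip(obj.names, pts)))
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")


def swap_lr_names(lm: LandmarkSet) -> LandmarkSet:
    """Exchange left/right landmark labels (RMC <-> LMC etc.) after mirroring.

    A name starting with ``L``/``R`` whose counterpart (same suffix, other
    prefix) exists in the set is relabelled; all other names pass through.
    """
    names = {n.lower() for n in lm.names}
    out: dict[str, np.ndarray] = {}
    for n in lm.names:
        if n[:1].upper() in ("L", "R") and len(n) > 1:
            other = ("R" if n[:1].upper() == "L" else "L") + n[1:]
            if other.lower() in names:
                out[other] = lm[n]
                continue
        out[n] = lm[n]
    return LandmarkSet(out)
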