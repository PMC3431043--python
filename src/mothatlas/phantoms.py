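"""Synthetic cylinder-tree neuron phantoms with exact SWC ground truth.

The tracing benchmark evaluates extraction methods on computer-generated
arborised objects: a random branched tree of tapering cylinders (frusta)
rendered into a confocal-like 3D stack, under four image conditions —

* ``raw`` — the neuron alone on a dark background,
* ``biased_background`` — a large smooth bright object covering the neuron,
* ``noise`` — additive white (Gaussian) noise,
* ``object`` — a bright cylindrical distractor overlapping the neuron.

Every phantom is fully determined by its integer seed (bit-reproducible),
and the generating tree is kept as exact ground truth, so miss/false
consistency, diameter discrepancy and passive-model response error can be
scored against a known answer.

What these phantoms emulate — tubular fluorescent structures, background
offset, detector noise, occluding objects — and what they do not (real
confocal optics: depth attenuation, anisotropic PSF, multi-neuron clutter)
bounds what benchmark scores say about real image data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .formats import ImageStack, Morphology

__all__ = [
    "PhantomSpec",
    "BenchmarkItem",
    "CONDITIONS",
    "generate_tree",
    "render_morphology",
    "rasterize_frusta",
    "corrupt",
    "make_phantom",
    "make_benchmark",
]

CONDITIONS = ("raw", "biased_background", "noise", "object")


@dataclass
class PhantomSpec:
    """Parameters of one phantom; the seed pins every random choice.

    Geometry defaults emulate a modest confocal field: 256 x 256 x 128
    voxels at (1, 1, 2) um for (x, y, z), i.e. 2 um optical sections.
    Intensities are 8-bit: foreground 200 on background 20.  The tree has a
    trunk plus 2–4 binary branching generations (>= 3 bifurcations), 20–60 um
    segments, 20–70 degree branch angles, 2 um root radius tapering by 0.8
    per generation.  Corruption strengths: noise sigma 30 (below half the
    foreground-background gap, so signal is never drowned), bias amplitude
    100, distractor cylinder radius 8 um.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (128, 256, 256)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)  # (dz, dy, dx) um
    generations: tuple[int, int] = (2, 4)
    segment_length: tuple[float, float] = (20.0, 60.0)
    branch_angle: tuple[float, float] = (20.0, 70.0)  # degrees
    root_radius: float = 2.0
    taper: float = 0.8
    fg: int = 200
    bg: int = 20
    condition: str = "raw"
    noise_sigma: float = 30.0
    bias_amplitude: float = 100.0
    distractor_radius: float = 8.0
    psf_sigma: float = 0.0  # um; optional Gaussian blur after rendering
    margin: float = 6.0  # um kept clear of the volume faces

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fg <= self.bg:
            raise ValueError("foreground intensity must exceed background")

    def field_size(self) -> np.ndarray:
        """(x, y, z) physical extent in um."""
        return (np.asarray(self.shape) * np.asarray(self.spacing))[::-1]


@dataclass
class BenchmarkItem:
    stack: ImageStack
    truth: Morphology
    condition: str
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def generate_tree(spec: PhantomSpec) -> Morphology:
    """Grow a random binary cylinder tree inside the phantom volume.

    Structure: a non-tapering trunk, then ``G`` generations of binary
    branching; a generation-``g`` segment tapers from ``r0 * taper^(g-1)`` to
    ``r0 * taper^g``, so tip radius is ``r0 * taper^G``.  Segment directions
    are re-drawn (up to 100 attempts each) until the endpoint stays inside
    the volume margin; a spec that cannot fit raises.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.field_size()
    lo = np.full(3, spec.margin)
    hi = size - spec.margin
    G = int(rng.integers(spec.generations[0], spec.generations[1] + 1))

    ids = [1]
    types = [1]
    xyz = [size / 2 + rng.uniform(-10, 10, size=3)]
    radii = [spec.root_radius]
    parents = [-1]

    def endpoint(start: np.ndarray, direction: np.ndarray, length: float) -> np.ndarray:
        return start + direction * length

    def grow_segment(start: np.ndarray, base_dir: np.ndarray,
                     bent: bool) -> tuple[np.ndarray, np.ndarray]:
        """Pick a direction (optionally bent off base_dir) and a valid endpoint."""
        for attempt in range(100):
            length = rng.uniform(*spec.segment_length)
            if not bent or attempt >= 60:
                # late attempts fall back to any direction so a branch stuck
                # against a volume face can still turn back inside
                d = _random_unit(rng)
            else:
                perp = np.cross(base_dir, _random_unit(rng))
                nrm = np.linalg.norm(perp)
                if nrm < 1e-6:
                    continue
                d = _rotate_about(base_dir, perp / nrm, bend_angle())
            end = endpoint(start, d, length)
            if np.all(end > lo) and np.all(end < hi):
                return d, end
        raise RuntimeError(
            "phantom tree does not fit the volume after 100 attempts; "
            "reduce segment lengths or enlarge the volume")

    def bend_angle() -> float:
        return np.deg2rad(rng.uniform(*spec.branch_angle))

    next_id = 2

    def add_node(pos: np.ndarray, radius: float, parent: int) -> int:
        nonlocal next_id
        ids.append(next_id)
        types.append(3)
        xyz.append(pos)
        radii.append(radius)
        parents.append(parent)
        next_id += 1
        return next_id - 1

    # trunk (no taper)
    d, end = grow_segment(xyz[0], _random_unit(rng), False)
    trunk_end = add_node(end, spec.root_radius, 1)

    # binary generations
    frontier = [(trunk_end, end, d, 1)]  # (node id, pos, direction, generation)
    while frontier:
        node, pos, pdir, gen = frontier.pop(0)
        if gen > G:
            continue
        r_end = spec.root_radius * spec.taper ** gen
        for _ in range(2):
            cd, cend = grow_segment(pos, pdir, True)
            child = add_node(cend, r_end, node)
            if gen < G:
                frontier.append((child, cend, cd, gen + 1))

    return Morphology.from_arrays(ids, types, xyz, radii, parents)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def rasterize_frusta(
    m: Morphology,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    *,
    radius_pad: float = 0.0,
) -> np.ndarray:
    """Boolean mask of all voxels inside the morphology's tapered segments.

    Each edge is a frustum: a voxel is inside when its distance to the
    segment axis is at most the linearly interpolated radius (plus
    ``radius_pad``).  Isolated nodes (roots without edges) are rendered as
    balls.  Works per-segment on a local bounding box, so cost scales with
    cable volume rather than stack volume.
    """
    mask = np.zeros(shape, dtype=bool)
    sp = np.asarray(spacing)  # (dz, dy, dx)
    org = np.asarray(origin)
    pidx = m.parent_index()
    has_child = np.zeros(m.n_nodes, dtype=bool)
    for p in pidx:
        if p >= 0:
            has_child[p] = True

    def paint(p0: np.ndarray, p1: np.ndarray, r0: float, r1: float) -> None:
        rmax = max(r0, r1) + radius_pad
        zyx0, zyx1 = p0[::-1], p1[::-1]
        lo_i = np.floor((np.minimum(zyx0, zyx1) - rmax - org) / sp).astype(int)
        hi_i = np.ceil((np.maximum(zyx0, zyx1) + rmax - org) / sp).astype(int) + 1
        lo_i = np.maximum(lo_i, 0)
        hi_i = np.minimum(hi_i, np.asarray(shape))
        if np.any(lo_i >= hi_i):
            return
        kk, jj, ii = np.meshgrid(*[np.arange(lo_i[a], hi_i[a]) for a in range(3)],
                                 indexing="ij")
        centers = (np.stack([kk, jj, ii], axis=-1) * sp + org)[..., ::-1]  # (x,y,z)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 < 1e-18:
            dist = np.linalg.norm(centers - p0, axis=-1)
            inside = dist <= r0 + radius_pad
        else:
            t = np.clip(((centers - p0) @ d) / L2, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            dist = np.linalg.norm(centers - closest, axis=-1)
            rloc = r0 + (r1 - r0) * t + radius_pad
            inside = dist <= rloc
        sub = mask[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]]
        sub |= inside

    for child, parent in m.edges():
        paint(m.xyz[parent], m.xyz[child], float(m.radii[parent]),
              float(m.radii[child]))
    for row in range(m.n_nodes):  # lone nodes (single-node morphologies)
        if pidx[row] == -1 and not has_child[row]:
            paint(m.xyz[row], m.xyz[row], float(m.radii[row]), float(m.radii[row]))
    return mask


def render_morphology(
    m: Morphology,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    fg: float = 200,
    bg: float = 20,
    psf_sigma: float = 0.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    dtype=np.uint8,
) -> ImageStack:
    """Render a morphology as a grayscale stack: fg inside frusta, bg outside.

    ``psf_sigma`` (um) applies an isotropic Gaussian blur emulating the
    point-spread function; 0 disables it.
    """
    if m.n_nodes == 0:
        vol = np.full(shape, bg, dtype=np.float64)
    else:
        mask = rasterize_frusta(m, shape, spacing, origin)
        vol = np.where(mask, float(fg), float(bg))
    if psf_sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=psf_sigma / np.asarray(spacing))
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        vol = np.clip(np.rint(vol), info.min, info.max)
    return ImageStack(vol.astype(dtype), spacing, origin)


# ---------------------------------------------------------------------------
# Corruption conditions
# ---------------------------------------------------------------------------

def _clip_to_dtype(vol: np.ndarray, dtype) -> np.ndarray:
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        vol = np.clip(np.rint(vol), info.min, info.max)
    return vol.astype(dtype)


def corrupt(stack: ImageStack, condition: str, spec: PhantomSpec,
            seed: int | None = None) -> ImageStack:
    """Apply one corruption condition; seeded and reproducible.

    * ``biased_background`` — adds a large smooth bright ellipsoidal ramp
      (amplitude ``bias_amplitude`` at its centre) covering the middle of
      the field, i.e. the neuron.
    * ``noise`` — adds i.i.d. Gaussian noise of ``noise_sigma``, clipped to
      the dtype range.
    * ``object`` — paints one bright cylinder (radius ``distractor_radius``)
      crossing the centre of the field at full foreground intensity.
    """
    if condition == "raw":
        return stack.copy()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    vol = stack.voxels.astype(np.float64)
    dtype = stack.voxels.dtype
    size = np.asarray(stack.shape) * np.asarray(stack.spacing)  # (z, y, x) um

    if condition == "noise":
        if spec.noise_sigma > 0:
            vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    elif condition == "biased_background":
        center = size / 2 + rng.uniform(-0.1, 0.1, size=3) * size
        half_axes = size * rng.uniform(0.35, 0.5, size=3)
        grids = np.meshgrid(*[(np.arange(n) * s) for n, s in
                              zip(stack.shape, stack.spacing)], indexing="ij")
        rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, half_axes))
        vol = vol + spec.bias_amplitude * np.clip(1.0 - rho2, 0.0, None)
    elif condition == "object":
        # cylinder through the field centre along a random direction
        axis_dir = _random_unit(rng)
        axis_dir[0] *= 0.3  # mostly in-plane, like a stray fibre
        axis_dir /= np.linalg.norm(axis_dir)
        p0 = size / 2 + rng.uniform(-0.05, 0.05, size=3) * size
        grids = np.meshgrid(*[(np.arange(n) * s) for n, s in
                              zip(stack.shape, stack.spacing)], indexing="ij")
        rel = np.stack([g - c for g, c in zip(grids, p0)], axis=-1)
        t = rel @ axis_dir
        dist2 = (rel ** 2).sum(axis=-1) - t ** 2
        inside = dist2 <= spec.distractor_radius ** 2
        vol = np.where(inside, np.maximum(vol, float(spec.fg)), vol)
    return ImageStack(_clip_to_dtype(vol, dtype), stack.spacing, stack.origin)


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> BenchmarkItem:
    """Generate one phantom: tree, rendering and the spec's corruption."""
    truth = generate_tree(spec)
    clean = render_morphology(truth, spec.shape, spec.spacing,
                              fg=spec.fg, bg=spec.bg, psf_sigma=spec.psf_sigma)
    stack = corrupt(clean, spec.condition, spec, seed=spec.seed + 1)
    return BenchmarkItem(stack, truth, spec.condition, spec)


def make_benchmark(n_per_condition: int = 3, base_seed: int = 0,
                   **spec_overrides) -> list[BenchmarkItem]:
    """The 4-condition benchmark: ``n_per_condition`` phantoms per condition.

    The default of 3 per condition gives the 12-stack suite.  Child seeds are
    derived deterministically from ``base_seed``; identical base seeds yield
    bit-identical benchmarks.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    seeds = ss.generate_state(len(CONDITIONS) * n_per_condition) % (2 ** 31)
    items = []
    k = 0
    for condition in CONDITIONS:
        for _ in range(n_per_condition):
            spec = PhantomSpec(seed=int(seeds[k]), condition=condition,
                               **spec_overrides)
            items.append(make_phantom(spec))
            k += 1
    return items
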