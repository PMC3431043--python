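"""File formats and core containers for the atlas toolkit.

Everything downstream (registration, tracing, atlas construction) works on
four containers defined here:

* :class:`Morphology` — an SWC-style rooted tree of 3D nodes with radii,
  coordinates in physical micrometres.
* :class:`ImageStack` — a 3D grayscale (or binary) voxel volume with
  anisotropic voxel spacing, the in-memory form of a multi-page TIFF of
  confocal optical sections.
* :class:`LandmarkSet` — named reference points (e.g. CCB, RMC, LMC) in
  physical coordinates, the anchors of landmark-based registration.
* :class:`SurfaceMesh` — a triangle mesh (Wavefront OBJ on disk).

Conventions: SWC and landmark coordinates are physical micrometres; voxel
indices are 0-based ``(k, j, i)`` for ``(z, y, x)``; the physical position of
a voxel is ``origin + index * spacing``.  Voxel spacing is never trusted from
TIFF metadata — it is an explicit parameter or a JSON sidecar, because
microscope exports are unreliable and mixed-magnification stacks must be
registered together.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FormatError",
    "StructureError",
    "Morphology",
    "ImageStack",
    "LandmarkSet",
    "SurfaceMesh",
    "read_swc",
    "write_swc",
    "read_stack",
    "write_stack",
    "read_obj",
    "write_obj",
    "mesh_volume",
    "read_landmarks",
    "write_landmarks",
]

#: default optical-section geometry: 2 um z-step, 1 um in-plane pixels
DEFAULT_SPACING = (2.0, 1.0, 1.0)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class StructureError(ValueError):
    """A parsed object violates a structural invariant (cycles, bad refs...)."""


# ---------------------------------------------------------------------------
# Morphology (SWC)
# ---------------------------------------------------------------------------

@dataclass
class Morphology:
    """Rooted forest of 3D nodes with radii (SWC semantics).

    ``ids`` are the SWC sample numbers (arbitrary positive integers, unique),
    ``parent_ids`` refer to ``ids`` with ``-1`` marking a root.  Nodes are
    kept topologically sorted: every parent precedes its children.  ``xyz``
    is ``(n, 3)`` in micrometres, ``radii`` strictly positive micrometres.
    ``type_codes`` are carried verbatim and never interpreted.
    """

    ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parent_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.type_codes = np.asarray(self.type_codes, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        ids: Iterable[int],
        type_codes: Iterable[int],
        xyz: Iterable[Sequence[float]],
        radii: Iterable[float],
        parent_ids: Iterable[int],
        *,
        sort: bool = True,
    ) -> "Morphology":
        """Build and validate a morphology; topologically sort unless told not to."""
        m = cls(np.asarray(list(ids)), np.asarray(list(type_codes)),
                np.asarray(list(xyz), dtype=float).reshape(-1, 3),
                np.asarray(list(radii), dtype=float), np.asarray(list(parent_ids)))
        m.validate()
        return m.toposorted() if sort else m

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        """Map node id -> row index."""
        return {int(i): k for k, i in enumerate(self.ids)}

    def parent_index(self) -> np.ndarray:
        """Row index of each node's parent (-1 for roots)."""
        idx = self.index_of()
        return np.array(
            [idx[int(p)] if p != -1 else -1 for p in self.parent_ids],
            dtype=np.int64,
        )

    def validate(self) -> None:
        """Raise :class:`StructureError` on any invariant violation."""
        n = self.n_nodes
        if n == 0:
            return
        if len(set(self.ids.tolist())) != n:
            raise StructureError("duplicate node ids")
        if np.any(self.ids <= 0):
            raise StructureError("node ids must be positive integers")
        if not np.all(np.isfinite(self.xyz)):
            raise StructureError("non-finite coordinates")
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise StructureError("radii must be strictly positive and finite")
        known = set(self.ids.tolist())
        for nid, pid in zip(self.ids.tolist(), self.parent_ids.tolist()):
            if pid == -1:
                continue
            if pid not in known:
                raise StructureError(f"node {nid}: parent id {pid} does not exist")
            if pid == nid:
                raise StructureError(f"node {nid} is its own parent")
        if not np.any(self.parent_ids == -1):
            raise StructureError("no root node (parent_id == -1) present")
        # forest check: walking parent pointers must terminate at a root
        pidx = {int(i): int(p) for i, p in zip(self.ids, self.parent_ids)}
        state: dict[int, int] = {}  # 0 visiting, 1 done
        for start in pidx:
            chain = []
            cur = start
            while cur != -1 and state.get(cur) != 1:
                if state.get(cur) == 0:
                    raise StructureError(f"cycle detected through node {cur}")
                state[cur] = 0
                chain.append(cur)
                cur = pidx[cur]
            for c in chain:
                state[c] = 1

    def toposorted(self) -> "Morphology":
        """Return a copy with parents listed before children (stable order)."""
        pidx = {int(i): int(p) for i, p in zip(self.ids, self.parent_ids)}
        order: list[int] = []
        placed: set[int] = set()

        def place(nid: int) -> None:
            stack = []
            cur = nid
            while cur != -1 and cur not in placed:
                stack.append(cur)
                cur = pidx[cur]
            for c in reversed(stack):
                placed.add(c)
                order.append(c)

        for nid in self.ids.tolist():
            place(int(nid))
        idx = self.index_of()
        rows = np.array([idx[i] for i in order], dtype=np.int64)
        return Morphology(self.ids[rows], self.type_codes[rows],
                          self.xyz[rows], self.radii[rows], self.parent_ids[rows])

    # -- topology helpers ----------------------------------------------------

    def roots(self) -> np.ndarray:
        return self.ids[self.parent_ids == -1]

    def n_children(self) -> np.ndarray:
        """Number of children per node (aligned with rows)."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        pidx = self.parent_index()
        for p in pidx:
            if p >= 0:
                counts[p] += 1
        return counts

    def tips(self) -> np.ndarray:
        """Ids of leaf nodes (no children)."""
        return self.ids[self.n_children() == 0]

    def bifurcations(self, *, count_degree2_root: bool = False) -> np.ndarray:
        """Ids of branching nodes (>= 2 children).

        A root with exactly two children lies on a path passing through it
        (a seed placed mid-neurite); by default such a root is not counted
        as a bifurcation.
        """
        nc = self.n_children()
        mask = nc >= 2
        if not count_degree2_root:
            is_root = self.parent_ids == -1
            mask &= ~(is_root & (nc == 2))
        return self.ids[mask]

    def edges(self) -> np.ndarray:
        """(m, 2) array of (child_row, parent_row) indices."""
        pidx = self.parent_index()
        child = np.nonzero(pidx >= 0)[0]
        return np.stack([child, pidx[child]], axis=1)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        if len(e) == 0:
            return np.zeros(0)
        return np.linalg.norm(self.xyz[e[:, 0]] - self.xyz[e[:, 1]], axis=1)

    def total_length(self) -> float:
        """Total cable length in micrometres."""
        return float(self.edge_lengths().sum())

    def copy(self) -> "Morphology":
        return Morphology(self.ids.copy(), self.type_codes.copy(),
                          self.xyz.copy(), self.radii.copy(), self.parent_ids.copy())


def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file.

    Lines beginning with ``#`` and blank lines are ignored.  Forward parent
    references are tolerated and fixed by topological re-sorting; multiple
    roots are allowed (fragmented fills) but flagged with a warning.
    """
    path = Path(path)
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 7 fields, got {len(fields)}")
            try:
                nid = int(fields[0])
                tc = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
            ids.append(nid); types.append(tc)
            xyz.append((x, y, z)); radii.append(r); parents.append(pid)
    if not ids:
        raise FormatError(f"{path.name}: no SWC data lines")
    m = Morphology(np.array(ids), np.array(types), np.array(xyz),
                   np.array(radii), np.array(parents))
    m.validate()
    if len(m.roots()) > 1:
        warnings.warn(f"{path.name}: {len(m.roots())} roots (fragmented morphology)",
                      stacklevel=2)
    return m.toposorted()


def write_swc(m: Morphology, path: str | Path, *, comment: str = "") -> None:
    """Write a validated morphology as 7-column SWC (parents precede children)."""
    m.validate()
    m = m.toposorted()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# SWC written by mothatlas\n")
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# id type x y z radius parent\n")
        for nid, tc, (x, y, z), r, pid in zip(
                m.ids, m.type_codes, m.xyz, m.radii, m.parent_ids):
            fh.write(f"{nid} {tc} {x:.17g} {y:.17g} {z:.17g} {r:.17g} {pid}\n")


# ---------------------------------------------------------------------------
# ImageStack (multi-page TIFF)
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """3D voxel volume with physical geometry.

    ``voxels`` is ``(z, y, x)``; ``spacing`` and ``origin`` are
    ``(dz, dy, dx)`` / ``(z0, y0, x0)`` in micrometres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"stack must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageStack", *, atol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    def index_to_physical(self, kji: np.ndarray) -> np.ndarray:
        """Voxel indices ``(k, j, i)`` -> physical points ``(x, y, z)`` um."""
        kji = np.atleast_2d(np.asarray(kji, dtype=float))
        zyx = np.asarray(self.origin) + kji * np.asarray(self.spacing)
        return zyx[:, ::-1]

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Physical points ``(x, y, z)`` um -> fractional indices ``(k, j, i)``."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        zyx = xyz[:, ::-1]
        return (zyx - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_extent(self) -> np.ndarray:
        """(3, 2) min/max physical coordinates of voxel centers, (x, y, z) rows."""
        lo = self.index_to_physical(np.zeros(3))[0]
        hi = self.index_to_physical(np.asarray(self.shape, dtype=float) - 1)[0]
        return np.stack([np.minimum(lo, hi), np.maximum(lo, hi)], axis=1)

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.spacing, self.origin)

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.spacing, self.origin)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] | None = None,
    origin: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a single-channel multi-page TIFF.

    Geometry comes from the explicit arguments, else a ``<file>.json``
    sidecar, else the 2 um optical-section default.  TIFF resolution tags are
    deliberately ignored.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"{path.name}: not a readable TIFF ({exc})") from exc
    if arr is None or arr.size == 0:
        raise FormatError(f"{path.name}: empty TIFF")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path.name}: only single-channel grayscale stacks are supported "
            f"(got shape {arr.shape})")
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]) // 4:
        raise FormatError(f"{path.name}: looks like RGB(A) data; unsupported")
    side = _sidecar_path(path)
    meta = {}
    if side.exists():
        meta = json.loads(side.read_text())
    if spacing is None:
        spacing = tuple(meta.get("spacing", DEFAULT_SPACING))
    if origin is None:
        origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    return ImageStack(arr, spacing, origin)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-page TIFF plus a JSON sidecar holding the geometry."""
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps(
        {"spacing": list(stack.spacing), "origin": list(stack.origin)}))


# ---------------------------------------------------------------------------
# SurfaceMesh (Wavefront OBJ)
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangle mesh; vertices in um, faces as 0-based vertex index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise StructureError("face references a missing vertex")

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if len(self.faces) == 0:
            return False
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume by the divergence theorem (sum of signed tetrahedra)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def write_obj(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write Wavefront OBJ: ``v x y z`` lines then ``f i j k`` (1-based)."""
    if len(mesh.faces) and mesh.faces.max() >= len(mesh.vertices):
        raise StructureError("face references a missing vertex")
    path = Path(path)
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for i, j, k in mesh.faces + 1:
            fh.write(f"f {i} {j} {k}\n")


def read_obj(path: str | Path) -> SurfaceMesh:
    """Read the v/f subset of Wavefront OBJ written by :func:`write_obj`."""
    verts, faces = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise FormatError(f"line {lineno}: only triangle faces supported")
                faces.append(idx)
    return SurfaceMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# LandmarkSet (CSV)
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named 3D points in physical micrometres.

    Names are unique; matching between landmark sets is by name,
    case-insensitively (the register-by-named-landmarks workflow), never by
    row order.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        lowered: set[str] = set()
        for name, p in self.entries.items():
            if not name:
                raise FormatError("empty landmark name")
            if name.lower() in lowered:
                raise FormatError(f"duplicate landmark name {name!r}")
            lowered.add(name.lower())
            p = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(p)):
                raise FormatError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = p
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name.lower() in (n.lower() for n in self.entries)

    def __getitem__(self, name: str) -> np.ndarray:
        for n, p in self.entries.items():
            if n.lower() == name.lower():
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        if names is None:
            names = self.names
        return np.stack([self[n] for n in names]) if names else np.zeros((0, 3))

    def common_names(self, other: "LandmarkSet") -> list[str]:
        """Names present in both sets (case-insensitive, this set's spelling)."""
        theirs = {n.lower() for n in other.names}
        return [n for n in self.names if n.lower() in theirs]

    def transformed(self, fn) -> "LandmarkSet":
        """Apply a point-mapping callable to every landmark."""
        pts = fn(self.coords())
        return LandmarkSet(dict(zip(self.names, np.atleast_2d(pts))))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "LandmarkSet":
        return cls(dict((k, np.asarray(v, dtype=float)) for k, v in mapping.items()))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with columns name,x,y,z (um)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path.name}: empty landmark file") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {sorted(missing)}")
    if len(df) < 1:
        raise FormatError(f"{path.name}: no landmark rows")
    entries: dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        name = str(row["name"]).strip()
        try:
            p = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path.name}: non-numeric coordinate for {name!r}") from exc
        if name.lower() in (k.lower() for k in entries):
            raise FormatError(f"{path.name}: duplicate landmark name {name!r}")
        entries[name] = p
    return LandmarkSet(entries)


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(n, *lm[n]) for n in lm.names], columns=["name", "x", "y", "z"])
    df.to_csv(path, index=False)
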