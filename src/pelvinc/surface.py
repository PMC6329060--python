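"""Surface reconstruction from binary masks and minimal mesh utilities.

Meshes live in the same physical (mm) frame as their source volume.
Reconstruction is level-0.5 marching cubes on the binary grid; smoothing is
a Taubin lambda/mu pass that never changes topology (no simplification).
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from skimage import measure

from .segmentation import BinaryMask


@dataclass
class SurfaceMesh:
    """Triangle mesh: (n, 3) float vertices in mm, (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray
    _vertex_normals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        """Unnormalized face normals (cross products; magnitude = 2*area)."""
        v = self.vertices
        f = self.faces
        return np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals (cached)."""
        if self._vertex_normals is None:
            fn = self.face_normals()
            vn = np.zeros_like(self.vertices)
            for c in range(3):
                np.add.at(vn, self.faces[:, c], fn)
            norms = np.linalg.norm(vn, axis=1)
            norms[norms == 0] = 1.0
            self._vertex_normals = vn / norms[:, None]
        return self._vertex_normals

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency from shared edges (boolean CSR)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        n = self.n_vertices
        A = sparse.coo_matrix(
            (np.ones(len(e), dtype=np.int8), (e[:, 0], e[:, 1])), shape=(n, n)
        ).tocsr()
        A = A + A.T
        A.data = np.ones_like(A.data)
        return A

    def transformed(self, R, t) -> "SurfaceMesh":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        return SurfaceMesh(self.vertices @ R.T + t, self.faces.copy())

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


def extract_isosurface(mask: BinaryMask) -> SurfaceMesh:
    """Marching cubes at level 0.5 on a binary mask, vertices in physical mm.

    Normals are oriented outward (from true voxels toward false voxels).
    """
    if not mask.voxels.any():
        raise ValueError("cannot extract an isosurface from an empty mask")
    padded = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=0.5, gradient_direction="descent"
    )
    verts = verts - 1.0  # undo padding
    phys = (verts * mask.spacing) @ mask.orientation.T + mask.origin
    mesh = SurfaceMesh(phys, faces)
    _orient_outward(mesh)
    return mesh


def marching_cubes_field(
    values: np.ndarray, level: float, spacing, origin, orientation=None
) -> SurfaceMesh:
    """Marching cubes on a continuous scalar field (e.g. a signed distance).

    Normals point toward increasing field values (outward for an SDF that is
    negative inside).
    """
    verts, faces, _, _ = measure.marching_cubes(
        values.astype(np.float32), level=level, gradient_direction="ascent"
    )
    orientation = np.eye(3) if orientation is None else np.asarray(orientation)
    phys = (verts * np.asarray(spacing, dtype=float)) @ orientation.T + np.asarray(
        origin, dtype=float
    )
    mesh = SurfaceMesh(phys, faces)
    _orient_outward(mesh)
    return mesh


def _orient_outward(mesh: SurfaceMesh) -> None:
    """Flip all faces if the signed volume indicates inward orientation."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    f = mesh.faces
    signed6 = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    if signed6.sum() < 0:
        mesh.faces = mesh.faces[:, [0, 2, 1]]
        mesh._vertex_normals = None


def smooth_mesh(mesh: SurfaceMesh, iterations: int = 10,
                lam: float = 0.5, mu: float = -0.53) -> SurfaceMesh:
    """Taubin lambda/mu smoothing; topology (vertex/face counts) is untouched.

    ``iterations=0`` returns an identical copy. The inflate step (mu < -lam)
    counteracts the shrinkage of plain Laplacian smoothing, keeping the pass
    close to volume-preserving.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    verts = mesh.vertices.copy()
    if iterations == 0 or mesh.n_faces == 0:
        return SurfaceMesh(verts, mesh.faces.copy())
    A = mesh.vertex_adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv_deg = (1.0 / deg)[:, None]
    for _ in range(iterations):
        verts += lam * (inv_deg * (A @ verts) - verts)
        verts += mu * (inv_deg * (A @ verts) - verts)
    return SurfaceMesh(verts, mesh.faces.copy())


# ---------------------------------------------------------------------------
# PLY / STL I/O


def write_mesh(mesh: SurfaceMesh, path: str, binary: bool = True) -> None:
    low = str(path).lower()
    if low.endswith(".ply"):
        _write_ply(mesh, path, binary)
    elif low.endswith(".stl"):
        _write_stl(mesh, path, binary)
    else:
        raise ValueError(f"unsupported mesh format {os.path.splitext(low)[1]!r}")


def read_mesh(path: str) -> SurfaceMesh:
    low = str(path).lower()
    if low.endswith(".ply"):
        return _read_ply(path)
    if low.endswith(".stl"):
        return _read_stl(path)
    raise ValueError(f"unsupported mesh format {os.path.splitext(low)[1]!r}")


def _write_ply(mesh: SurfaceMesh, path: str, binary: bool) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            face_rec = np.empty(mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", 3)])
            face_rec["n"] = 3
            face_rec["idx"] = mesh.faces
            fh.write(face_rec.tobytes())
        else:
            lines = ["%.17g %.17g %.17g" % tuple(v) for v in mesh.vertices]
            lines += ["3 %d %d %d" % tuple(f) for f in mesh.faces]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def _read_ply(path: str) -> SurfaceMesh:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path} is not a PLY file")
        fmt = None
        counts = {}
        order = []
        while True:
            line = fh.readline().decode("ascii").strip()
            if line == "end_header":
                break
            parts = line.split()
            if parts[0] == "format":
                fmt = parts[1]
            elif parts[0] == "element":
                counts[parts[1]] = int(parts[2])
                order.append(parts[1])
        nv, nf = counts.get("vertex", 0), counts.get("face", 0)
        if fmt == "ascii":
            verts = np.array(
                [[float(x) for x in fh.readline().split()[:3]] for _ in range(nv)]
            )
            faces = np.array(
                [[int(x) for x in fh.readline().split()[1:4]] for _ in range(nf)]
            )
        elif fmt == "binary_little_endian":
            verts = np.frombuffer(fh.read(nv * 24), dtype="<f8").reshape(nv, 3).copy()
            rec = np.frombuffer(
                fh.read(nf * 13), dtype=[("n", "u1"), ("idx", "<i4", 3)]
            )
            faces = rec["idx"].astype(np.int64)
        else:
            raise ValueError(f"unsupported PLY format {fmt!r}")
    return SurfaceMesh(verts, faces)


def _write_stl(mesh: SurfaceMesh, path: str, binary: bool) -> None:
    fn = mesh.face_normals()
    norms = np.linalg.norm(fn, axis=1)
    norms[norms == 0] = 1.0
    fn = fn / norms[:, None]
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    if binary:
        rec = np.zeros(
            mesh.n_faces,
            dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
        rec["normal"] = fn
        rec["v"] = tri
        with open(path, "wb") as fh:
            fh.write(b"\x00" * 80 + struct.pack("<I", mesh.n_faces) + rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid pelvinc\n")
            for n, t in zip(fn, tri):
                fh.write("facet normal %.9g %.9g %.9g\n outer loop\n" % tuple(n))
                for v in t:
                    fh.write("  vertex %.9g %.9g %.9g\n" % tuple(v))
                fh.write(" endloop\nendfacet\n")
            fh.write("endsolid pelvinc\n")


def _read_stl(path: str) -> SurfaceMesh:
    with open(path, "rb") as fh:
        head = fh.read(80)
        rest = fh.read()
    if head.lstrip().startswith(b"solid") and b"facet" in rest[:2000]:
        tokens = rest.decode("ascii", errors="replace").split()
        coords = []
        i = 0
        while i < len(tokens):
            if tokens[i] == "vertex":
                coords.append([float(tokens[i + 1]), float(tokens[i + 2]), float(tokens[i + 3])])
                i += 4
            else:
                i += 1
        tri = np.array(coords).reshape(-1, 3, 3)
    else:
        (nf,) = struct.unpack("<I", rest[:4])
        rec = np.frombuffer(
            rest[4 : 4 + nf * 50],
            dtype=[("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
        )
        tri = rec["v"].astype(float)
    # weld duplicate vertices so faces index a shared vertex table
    flat = tri.reshape(-1, 3)
    uniq, inverse = np.unique(flat.round(decimals=6), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(uniq, faces)
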