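"""Supertoroidal and toroidal glyph meshes with the three color encodings.

A supertoroid is a genus-1 generalization of the superquadric glyph: the
central opening marks the principal diffusion direction regardless of viewing
angle, and the surface blends from an ordinary torus (isotropy) to a tube or
sharp-edged ring (anisotropy).  With shape metrics (CL, CP, CS) the surface is

    CS >= CP:  x = cos^e1(t) {(CL+CP) + CS cos^e2(p)}
               y = sin^e1(t) {(CL+CP) + CS cos^e2(p)}
               z = sin^e2(p)
    CS <  CP:  ring and tube amplitudes swapped,

with e1 = (1-CP)^g1, e2 = (1-CP)^g2 (defaults g1=4, g2=0.5) and cos^e/sin^e
the sign-preserving superquadric powers.  In the isotropic corner (0,0,1) the
ring amplitude vanishes and the glyph closes into a genus-0 blob — no hole.

Local glyph frame convention: the rotational axis is local +z and is mapped to
the principal eigenvector e1 on placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .invariants import toroid_params
from .tensor_model import CONFIG_COLORS, ConfigClass, EigenSystem, ShapeMetrics

ETA_FLOOR = 0.05          # avoid numerically flat exponents as CP -> 1
WELD_TOL = 1e-9
DEGENERATE_EPS = 1e-6     # amplitude below which a glyph is a ring/point
BRIGHTNESS_FLOOR = 0.2


@dataclass
class GlyphParams:
    """Supertoroid display parameters.

    gamma1 sharpens the shape in the medium/minor diffusion directions;
    gamma2 shapes it along the rotational (principal) axis.
    """

    gamma1: float = 4.0
    gamma2: float = 0.5
    n_theta: int = 64
    n_phi: int = 64

    def __post_init__(self) -> None:
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("gamma exponents must be positive")
        if self.n_theta < 8 or self.n_phi < 8:
            raise ValueError("tessellation resolution must be >= 8")


@dataclass
class GlyphMesh:
    """Triangulated glyph surface with optional per-vertex color and placement."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_colors: np.ndarray | None = None
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))
    degenerate: bool = False

    @property
    def trimesh(self) -> trimesh.Trimesh:
        tm = trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )
        if self.vertex_colors is not None:
            tm.visual.vertex_colors = (
                np.clip(self.vertex_colors, 0, 1) * 255
            ).astype(np.uint8)
        return tm

    def placed(self) -> "GlyphMesh":
        """Apply the 4x4 transform to the vertices (colors/faces unchanged)."""
        v = self.vertices @ self.transform[:3, :3].T + self.transform[:3, 3]
        return GlyphMesh(v, self.faces.copy(), self.vertex_colors, np.eye(4), self.degenerate)


def signed_power(x, eta: float):
    """sign(x) * |x|**eta — the superquadric power, odd and continuous in x."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** eta


def _param_grid(n_theta: int, n_phi: int) -> tuple[np.ndarray, np.ndarray]:
    # closed grids: endpoint 2*pi duplicates the seam, welded later
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta + 1)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi + 1)
    return np.meshgrid(theta, phi, indexing="ij")


def supertoroid_surface(
    metrics: ShapeMetrics | tuple[float, float, float],
    params: GlyphParams | None = None,
) -> np.ndarray:
    """Evaluate the supertoroid point grid, shape (n_theta+1, n_phi+1, 3)."""
    params = params or GlyphParams()
    if isinstance(metrics, ShapeMetrics):
        cl, cp, cs = float(metrics.CL), float(metrics.CP), float(metrics.CS)
    else:
        cl, cp, cs = map(float, metrics)
    if not np.all(np.isfinite([cl, cp, cs])):
        raise ValueError("non-finite shape metrics")
    eta1 = max((1.0 - cp) ** params.gamma1, ETA_FLOOR)
    eta2 = max((1.0 - cp) ** params.gamma2, ETA_FLOOR)
    ring, tube = (cl + cp, cs) if cs >= cp else (cs, cl + cp)
    if ring < 1e-12:
        # no central opening: the full polar range would double-cover the
        # genus-0 blob, so sample a single cover with poles at phi = +/-pi/2
        theta = np.linspace(0.0, 2.0 * np.pi, params.n_theta + 1)
        phi = np.linspace(-0.5 * np.pi, 0.5 * np.pi, params.n_phi + 1)
        th, ph = np.meshgrid(theta, phi, indexing="ij")
    else:
        th, ph = _param_grid(params.n_theta, params.n_phi)
    radial = ring + tube * signed_power(np.cos(ph), eta2)
    return np.stack(
        [
            signed_power(np.cos(th), eta1) * radial,
            signed_power(np.sin(th), eta1) * radial,
            signed_power(np.sin(ph), eta2),
        ],
        axis=-1,
    )


def toroid_surface(
    eigs: EigenSystem | np.ndarray, n_theta: int = 64, n_phi: int = 64
) -> np.ndarray:
    """Evaluate the plain toroidal surface for one eigenvalue triple.

    z-extent is l1, the central-opening diameter 2(a-b) equals l2, and the
    tube thickness is l3/2.
    """
    p = toroid_params(eigs)
    a, b, g = float(p.alpha), float(p.beta), float(p.gamma)
    th, ph = _param_grid(n_theta, n_phi)
    r = a + b * np.cos(ph)
    return np.stack([np.cos(th) * r, np.sin(th) * r, g * np.sin(ph)], axis=-1)


def tessellate(grid: np.ndarray) -> GlyphMesh:
    """Triangulate a closed parametric grid and weld duplicate seam vertices.

    Quads are split into two triangles; vertices closer than WELD_TOL are
    merged so topological checks (Euler characteristic) are meaningful.
    Degenerate (zero-area) surfaces yield a flagged placeholder mesh instead
    of an error, so whole-slice export never aborts.
    """
    nt, np_, _ = grid.shape
    verts = grid.reshape(-1, 3)
    if not np.all(np.isfinite(verts)):
        raise ValueError("non-finite vertices in parametric grid")
    idx = np.arange(nt * np_).reshape(nt, np_)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([a, c, d], axis=1)], axis=0
    )

    # weld: quantize coordinates to the tolerance, unify identical vertices
    key = np.round(verts / WELD_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    wverts = verts[np.sort(first)]
    order = np.argsort(first)
    remap = np.empty(len(first), dtype=np.int64)
    remap[order] = np.arange(len(first))
    wfaces = remap[inverse][faces]
    # drop triangles that collapsed onto a welded vertex
    good = (
        (wfaces[:, 0] != wfaces[:, 1])
        & (wfaces[:, 1] != wfaces[:, 2])
        & (wfaces[:, 0] != wfaces[:, 2])
    )
    wfaces = wfaces[good]

    extent = verts.ptp(axis=0) if hasattr(verts, "ptp") else np.ptp(verts, axis=0)
    degenerate = bool(np.min(extent) < DEGENERATE_EPS) or len(wfaces) == 0

    # orient outward: positive enclosed volume under the divergence theorem
    if len(wfaces):
        v = wverts
        tri = v[wfaces]
        vol6 = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()
        if vol6 < 0:
            wfaces = wfaces[:, ::-1]
    return GlyphMesh(vertices=wverts, faces=wfaces, degenerate=degenerate)


def euler_characteristic(mesh: GlyphMesh) -> int:
    """V - E + F of the welded mesh (2 for a sphere-like blob, 0 for a torus)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    return int(tm.euler_number)


def place_glyph(
    mesh: GlyphMesh,
    eigs: EigenSystem | np.ndarray,
    voxel_center: np.ndarray,
    scale: float = 1.0,
) -> GlyphMesh:
    """Orient and position a glyph: local z (rotational axis) -> e1, x -> e2, y -> e3.

    The rotation is forced right-handed (det = +1) by flipping the local
    y-image if necessary; translation goes to the voxel center in world
    coordinates, with a uniform display scale.
    """
    if isinstance(eigs, EigenSystem):
        V = np.asarray(eigs.vectors, dtype=float)
        e1, e2, e3 = V[..., :, 0], V[..., :, 1], V[..., :, 2]
    else:
        e1, e2, e3 = (np.asarray(v, dtype=float) for v in eigs)
    frame = np.stack([e2, e3, e1], axis=-1)  # columns: images of local x, y, z
    if not np.allclose(frame.T @ frame, np.eye(3), atol=1e-8):
        raise ValueError("eigenframe is not orthonormal")
    if np.linalg.det(frame) < 0:
        frame[:, 1] = -frame[:, 1]
    T = np.eye(4)
    T[:3, :3] = frame * scale
    T[:3, 3] = np.asarray(voxel_center, dtype=float)
    return GlyphMesh(
        vertices=mesh.vertices,
        faces=mesh.faces,
        vertex_colors=mesh.vertex_colors,
        transform=T,
        degenerate=mesh.degenerate,
    )


def color_by_orientation(e1: np.ndarray, fa: float | np.ndarray | None = None) -> np.ndarray:
    """RGB = (|e1x|, |e1y|, |e1z|), the standard DTI direction encoding,
    optionally weighted by FA."""
    rgb = np.abs(np.asarray(e1, dtype=float))
    if fa is not None:
        rgb = rgb * np.clip(np.asarray(fa, dtype=float), 0.0, 1.0)[..., None] if rgb.ndim > 1 else rgb * float(np.clip(fa, 0.0, 1.0))
    return np.clip(rgb, 0.0, 1.0)


def color_by_configuration(cls: ConfigClass, tv_norm: float) -> np.ndarray:
    """Configuration base color with its brightness modulated by normalized TV.

    The value channel scales between BRIGHTNESS_FLOOR and 1 so zero-TV voxels
    stay visible; tv_norm outside [0,1] is clipped.
    """
    tv = float(np.clip(tv_norm, 0.0, 1.0))
    base = np.array(CONFIG_COLORS[cls], dtype=float)
    return base * (BRIGHTNESS_FLOOR + (1.0 - BRIGHTNESS_FLOOR) * tv)


def glyph_field(
    field,
    z: int,
    mode: str = "supertoroid",
    color: str = "orientation",
    params: GlyphParams | None = None,
    scale_fraction: float = 0.45,
) -> GlyphMesh:
    """Build one combined mesh of glyphs for an axial slice of a tensor field.

    mode: "supertoroid" (Eq-style shape blend) or "toroid" (plain toroidal
    surface, scaled by 1/l1 so glyphs share a display size).
    color: "orientation" (|e1| RGB weighted by FA), "config" (eigenvalue
    configuration with TV brightness), or "tv" (normalized TV, hot-to-cold).
    Glyphs are scaled to scale_fraction of the voxel size so neighbors do not
    overlap, and placed at world-space voxel centers.
    """
    from .invariants import compute_map, normalize_map
    from .tensor_model import classify_configuration, eigendecompose, shape_metrics

    params = params or GlyphParams(n_theta=16, n_phi=16)
    eigs = eigendecompose(field)
    sm = shape_metrics(eigs)
    fa = None
    tvn = None
    cfg = None
    if color == "orientation":
        fa = compute_map(eigs, "FA", affine=field.affine).values
    elif color in ("config", "tv"):
        tvn = normalize_map(compute_map(eigs, "TV", affine=field.affine)).values
        if color == "config":
            cfg = classify_configuration(eigs)
    else:
        raise ValueError(f"unknown color mode {color!r}")

    voxel_size = float(np.min(np.linalg.norm(field.affine[:3, :3], axis=0)))
    scale = scale_fraction * voxel_size
    verts, faces, colors = [], [], []
    offset = 0
    nx, ny, _ = field.grid_shape
    for i in range(nx):
        for j in range(ny):
            if not eigs.mask[i, j, z]:
                continue
            lam = eigs.lambdas[i, j, z]
            if lam[0] <= 0:
                continue
            if mode == "supertoroid":
                grid = supertoroid_surface(
                    (sm.CL[i, j, z], sm.CP[i, j, z], sm.CS[i, j, z]), params
                )
            elif mode == "toroid":
                grid = toroid_surface(lam / lam[0], params.n_theta, params.n_phi)
            else:
                raise ValueError(f"unknown glyph mode {mode!r}")
            mesh = tessellate(grid)
            center = (field.affine @ np.array([i, j, z, 1.0]))[:3]
            placed = place_glyph(mesh, eigs.vectors[i, j, z], center, scale).placed()
            if color == "orientation":
                rgb = color_by_orientation(eigs.vectors[i, j, z, :, 0], fa[i, j, z])
            elif color == "config":
                rgb = color_by_configuration(cfg[i, j, z], tvn[i, j, z])
            else:
                rgb = hot_to_cold(tvn[i, j, z])
            verts.append(placed.vertices)
            faces.append(placed.faces + offset)
            colors.append(np.tile(rgb, (len(placed.vertices), 1)))
            offset += len(placed.vertices)
    if not verts:
        raise ValueError(f"no fittable voxels in slice z={z}")
    return GlyphMesh(
        vertices=np.concatenate(verts),
        faces=np.concatenate(faces),
        vertex_colors=np.concatenate(colors),
    )


def hot_to_cold(v: float | np.ndarray) -> np.ndarray:
    """Blue -> cyan -> green -> yellow -> red piecewise-linear ramp on [0, 1]."""
    v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
    r = np.clip(4.0 * v - 2.0, 0.0, 1.0)
    g = np.minimum(np.clip(4.0 * v, 0.0, 1.0), np.clip(4.0 - 4.0 * v, 0.0, 1.0))
    b = np.clip(2.0 - 4.0 * v, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)
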