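"""Brain-like synthetic tensor fields, DWI signals, ROIs, and cohorts.

The phantom emulates the regional structure a glioblastoma analysis assumes:
an isotropic high-diffusivity tumor (necrotic) core, an intermediate
peritumoral edema shell, anisotropic white-matter tracts (one straight bundle
and one 90-degree arc, so orientation encodings are exercised), and a
near-isotropic gray-matter background, all inside an ellipsoidal brain mask.

Default eigenvalues (mm^2/s) are literature-typical values producing the
qualitative orderings seen in GBM DTI — MD/TV: tumor > edema > parenchyma;
FA/TC: WM > GM — not values reported by any specific study:

    tumor (1.8, 1.7, 1.6)e-3    edema (1.3, 1.1, 1.0)e-3
    GM    (0.9, 0.8, 0.75)e-3   WM    (1.7, 0.4, 0.3)e-3

Signals follow S_i = S0 exp(-b_i g^T D g) with Rician noise (the magnitude-MRI
standard): sqrt((S + n1)^2 + n2^2) with n1, n2 ~ N(0, (sigma S0)^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .tensor_model import DWIVolume, TensorField

log = logging.getLogger(__name__)

ROI_LABELS = {"background": 0, "tumor": 1, "edema": 2, "GM": 3, "WM": 4}
ROI_NAMES = {v: k for k, v in ROI_LABELS.items()}
REGION_ORDER = ("tumor", "edema", "GM", "WM")  # fixed (T, E, GM, WM) output order

DEFAULT_EIGENVALUES = {
    "tumor": (1.8e-3, 1.7e-3, 1.6e-3),
    "edema": (1.3e-3, 1.1e-3, 1.0e-3),
    "GM": (0.9e-3, 0.8e-3, 0.75e-3),
    "WM": (1.7e-3, 0.4e-3, 0.3e-3),
}


@dataclass
class PhantomSpec:
    """Geometry, tissue eigenvalues, and noise settings of the phantom.

    Geometry is in voxel units on ``shape``; the affine carries the voxel
    size (default 2.5 x 2.5 x 3.3 mm).  ``jitter_sd`` is the fractional
    standard deviation of the multiplicative lognormal inter-subject
    eigenvalue perturbation; ``noise_sigma`` the Rician scale as a fraction
    of S0.
    """

    shape: tuple[int, int, int] = (48, 48, 12)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.3)
    core_center: tuple[float, float, float] | None = None  # defaults near (0.3,0.35)*xy
    core_radius: float = 5.0
    edema_thickness: float = 4.0
    wm_halfwidth: float = 3.0
    eigenvalues: dict = field(default_factory=lambda: dict(DEFAULT_EIGENVALUES))
    jitter_sd: float = 0.05
    noise_sigma: float = 0.02
    equal_volume: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lam in self.eigenvalues.items():
            lam = tuple(float(x) for x in lam)
            if list(lam) != sorted(lam, reverse=True) or lam[-1] < 0:
                raise ValueError(f"{name} eigenvalues must be sorted nonincreasing >= 0")
            self.eigenvalues[name] = lam
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.voxel_size
        return A


@dataclass
class ROISet:
    """Integer label volume: 0 background, 1 tumor, 2 edema, 3 GM, 4 WM."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI labels must be integer")
        bad = set(np.unique(self.labels)) - set(ROI_LABELS.values())
        if bad:
            raise ValueError(f"unexpected ROI labels {sorted(bad)}")

    def voxels(self, label: int) -> np.ndarray:
        return self.labels == label


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices via QR of Gaussian matrices."""
    A = rng.standard_normal((n, 3, 3))
    Q, R = np.linalg.qr(A)
    sgn = np.sign(np.einsum("nii->ni", R))
    sgn[sgn == 0] = 1.0
    Q = Q * sgn[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 2] *= -1.0
    return Q


def _tract_frame(direction: np.ndarray) -> np.ndarray:
    """Orthonormal frame whose first column is ``direction`` (WM eigenframe)."""
    d = direction / np.linalg.norm(direction)
    up = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(up, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.stack([d, u, v], axis=1)  # columns: e1, e2, e3


def _equalize(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Trim every nonzero ROI to the smallest ROI's voxel count (seeded choice)."""
    counts = {lb: int(np.sum(labels == lb)) for lb in range(1, 5)}
    target = min(counts.values())
    out = labels.copy()
    for lb, n in counts.items():
        if n > target:
            idx = np.flatnonzero(labels.ravel() == lb)
            drop = rng.choice(idx, size=n - target, replace=False)
            out.ravel()[drop] = 0
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[TensorField, ROISet]:
    """Build one subject: per-voxel tensors R diag(lambda) R^T plus ROI labels.

    Region precedence where geometries overlap: core > edema > WM > GM
    (overlaps are logged).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    brain = ((ii - cx) / (0.48 * nx)) ** 2 + ((jj - cy) / (0.48 * ny)) ** 2 + (
        (kk - cz) / (0.52 * nz)
    ) ** 2 <= 1.0

    core_c = spec.core_center or (0.30 * nx, 0.35 * ny, cz)
    r = np.sqrt(
        (ii - core_c[0]) ** 2 + (jj - core_c[1]) ** 2 + (kk - core_c[2]) ** 2
    )
    core = brain & (r <= spec.core_radius)
    edema = brain & (r > spec.core_radius) & (r <= spec.core_radius + spec.edema_thickness)

    # straight bundle along +y in the contralateral hemisphere
    straight = brain & (np.abs(ii - 0.72 * nx) <= spec.wm_halfwidth) & (
        np.abs(kk - cz) <= max(1.0, spec.wm_halfwidth / 2)
    )
    # 90-degree arc in the axial plane, centered on the posterior midline
    arc_c = (0.50 * nx, 0.82 * ny)
    ar = np.sqrt((ii - arc_c[0]) ** 2 + (jj - arc_c[1]) ** 2)
    arc_r = 0.22 * nx
    ang = np.arctan2(jj - arc_c[1], ii - arc_c[0])
    arc = (
        brain
        & (np.abs(ar - arc_r) <= spec.wm_halfwidth)
        & (ang >= -np.pi)
        & (ang <= -np.pi / 2)
        & (np.abs(kk - cz) <= max(1.0, spec.wm_halfwidth / 2))
    )
    wm = (straight | arc) & ~core & ~edema
    n_overlap = int(np.sum((straight | arc) & (core | edema)))
    if n_overlap:
        log.info("resolved %d WM/tumor overlapping voxels by precedence", n_overlap)
    gm = brain & ~core & ~edema & ~wm

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[gm] = ROI_LABELS["GM"]
    labels[wm] = ROI_LABELS["WM"]
    labels[edema] = ROI_LABELS["edema"]
    labels[core] = ROI_LABELS["tumor"]

    lam = {k: np.array(v) for k, v in spec.eigenvalues.items()}
    D = np.zeros(spec.shape + (3, 3))
    for name, region in (("tumor", core), ("edema", edema), ("GM", gm)):
        n = int(region.sum())
        if n == 0:
            continue
        R = _random_rotations(n, rng)
        D[region] = np.einsum("nij,j,nkj->nik", R, lam[name], R)

    # WM: e1 along the local tract direction
    for region, direction in (
        (wm & straight, None),
        (wm & arc & ~straight, "arc"),
    ):
        n = int(region.sum())
        if n == 0:
            continue
        if direction is None:
            dirs = np.tile(np.array([0.0, 1.0, 0.0]), (n, 1))
        else:
            pts = np.stack([ii[region], jj[region]], axis=1).astype(float)
            rad = pts - np.array(arc_c)
            tang = np.stack([-rad[:, 1], rad[:, 0]], axis=1)
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            dirs = np.concatenate([tang, np.zeros((n, 1))], axis=1)
        Rm = np.stack([_tract_frame(d) for d in dirs])
        D[region] = np.einsum("nij,j,nkj->nik", Rm, lam["WM"], Rm)

    if spec.equal_volume:
        labels = _equalize(labels, rng)

    fld = TensorField.from_matrices(D, mask=brain, affine=spec.affine)
    return fld, ROISet(labels=labels, affine=spec.affine)


def default_gradient_table(n_directions: int = 32, b: float = 800.0, seed: int = 42):
    """One b=0 volume plus ``n_directions`` unit vectors at b (s/mm^2).

    Directions are electrostatically spread on the sphere (repulsion descent
    from a seeded start) so the design is well-conditioned; deterministic.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_directions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(200):
        # antipodally-symmetrized Coulomb repulsion step
        diff = v[:, None, :] - v[None, :, :]
        anti = v[:, None, :] + v[None, :, :]
        for d in (diff, anti):
            r2 = np.sum(d**2, axis=-1) + np.eye(n_directions)
            f = d / r2[..., None] ** 1.5
            f[np.arange(n_directions), np.arange(n_directions)] = 0.0
            v = v + 0.01 * f.sum(axis=1)
            v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, b)])
    bvecs = np.concatenate([np.zeros((1, 3)), v], axis=0)
    return bvals, bvecs


def synthesize_dwi(
    fld: TensorField,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    S0: float = 1000.0,
    sigma: float = 0.0,
    seed: int = 0,
    *,
    noise_model: str = "rician",
    TE: float = 76.0,
) -> DWIVolume:
    """Forward-simulate DWI signals from a tensor field.

    sigma is the noise scale as a fraction of S0; sigma=0 is exactly
    noiseless.  noise_model "rician" (default) or "gaussian" (debugging).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    from .tensor_model import design_matrix

    B = design_matrix(bvals, bvecs)  # (ngrad, 6)
    exponent = np.einsum("xyzc,gc->xyzg", fld.D, B)
    S = S0 * np.exp(-exponent)
    S[~fld.mask] = 0.0
    if sigma > 0:
        rng = np.random.default_rng(seed)
        s = sigma * S0
        if noise_model == "rician":
            n1 = rng.normal(0.0, s, S.shape)
            n2 = rng.normal(0.0, s, S.shape)
            S = np.sqrt((S + n1) ** 2 + n2**2)
        elif noise_model == "gaussian":
            S = np.maximum(S + rng.normal(0.0, s, S.shape), 0.0)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return DWIVolume(signal=S, bvals=bvals, bvecs=bvecs, affine=fld.affine, TE=TE)


def generate_cohort(
    n_subjects: int, spec: PhantomSpec | None = None, seed: int = 0
) -> list[tuple[TensorField, ROISet]]:
    """Simulate a cohort: per-subject lognormal eigenvalue jitter, derived seeds.

    Each subject/region draws one lognormal scale factor (sd = jitter_sd,
    shared by all three eigenvalues — overall diffusivity variation) and three
    independent lognormal shape factors (sd = jitter_sd/2 — eigenvalue-ratio
    variation), so the cross-subject CV of region-mean MD is close to the
    nominal jitter_sd.  Subject s draws with seed ``seed + 1000*(s+1)`` while
    phantom geometry keeps the spec's own seed, so jitter_sd = 0 reproduces
    identical subjects and the full cohort is reproducible from the master
    seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec = spec or PhantomSpec()
    out = []
    for s in range(n_subjects):
        sub_seed = int(seed) + 1000 * (s + 1)
        rng = np.random.default_rng(sub_seed)
        eig = {}
        for name, lam in spec.eigenvalues.items():
            if spec.jitter_sd > 0:
                scale = rng.lognormal(mean=0.0, sigma=spec.jitter_sd)
                shape = rng.lognormal(mean=0.0, sigma=spec.jitter_sd / 2.0, size=3)
                f = scale * shape
            else:
                f = np.ones(3)
            jl = np.sort(np.array(lam) * f)[::-1]
            eig[name] = tuple(jl)
        sub_spec = replace(spec, eigenvalues=eig, seed=spec.seed)
        out.append(generate_phantom(sub_spec))
    return out
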