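"""Diffusion tensor estimation, eigendecomposition, and shape classification.

The diffusion tensor D is a symmetric positive semi-definite 3x3 matrix per
voxel (units mm^2/s) modeling Gaussian water displacement.  Signals follow the
monoexponential Stejskal-Tanner model

    S_i = S0 * exp(-b_i * g_i^T D g_i),

so ln(S_i/S0) is linear in the six unique tensor components and D is
recovered by log-linear least squares.  Downstream shape analysis uses the
sorted eigensystem and the Westin barycentric shape metrics

    CL = (l1-l2)/tr,  CP = 2(l2-l3)/tr,  CS = 3*l3/tr,   CL+CP+CS = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

log = logging.getLogger(__name__)

# in-memory unique-component order (row-major upper triangle)
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_UT_I = np.array([0, 0, 0, 1, 1, 2])
_UT_J = np.array([0, 1, 2, 1, 2, 2])

SIGNAL_FLOOR_FRACTION = 1e-6  # of S0, applied before the log


class UnfittableDesignError(ValueError):
    """Raised when the gradient scheme cannot determine six tensor components."""


@dataclass
class DWIVolume:
    """4D diffusion-weighted acquisition with its gradient table.

    signal: (x, y, z, n_gradients) nonnegative array.
    bvals:  (n_gradients,) b-values in s/mm^2; at least one zero entry.
    bvecs:  (n_gradients, 3) unit direction per nonzero-b gradient
            (zero rows allowed for b=0 volumes).
    affine: 4x4 voxel-to-world (RAS) transform.
    TE:     echo time in ms, metadata only.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    TE: float | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {self.signal.shape}")
        n = self.signal.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table mismatch: {n} volumes, {len(self.bvals)} bvals, "
                f"{self.bvecs.shape[0]} bvecs"
            )
        if not np.any(self.bvals == 0):
            raise ValueError("need at least one b=0 (T2-weighted) volume")
        nz = self.bvals > 0
        if nz.sum() < 6:
            raise UnfittableDesignError(
                f"need >=6 diffusion-weighted gradients, got {int(nz.sum())}"
            )
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if np.any(norms == 0):
            raise ValueError("zero gradient vector with nonzero b-value")
        self.bvecs = self.bvecs.copy()
        self.bvecs[nz] /= norms[:, None]

    @property
    def n_gradients(self) -> int:
        return self.signal.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor on a 3D grid.

    D: (x, y, z, 6) array in TENSOR_COMPONENTS order, mm^2/s.
    mask: (x, y, z) boolean; masked-out voxels hold ``fill`` and are excluded
    from every statistic computed downstream.
    """

    D: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    fill: float = 0.0

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 4 or self.D.shape[3] != 6:
            raise ValueError(f"D must have shape (x,y,z,6), got {self.D.shape}")
        if self.mask is None:
            self.mask = np.ones(self.D.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.D.shape[:3]:
            raise ValueError("mask shape does not match grid")
        self.affine = np.asarray(self.affine, dtype=float)
        self.D[~self.mask] = self.fill

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.D.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand the 6 components to full (x,y,z,3,3) symmetric matrices."""
        M = np.empty(self.grid_shape + (3, 3))
        M[..., _UT_I, _UT_J] = self.D
        M[..., _UT_J, _UT_I] = self.D
        return M

    @classmethod
    def from_matrices(cls, M: np.ndarray, **kw) -> "TensorField":
        return cls(D=np.asarray(M)[..., _UT_I, _UT_J], **kw)


@dataclass
class EigenSystem:
    """Sorted eigensystem of a tensor field: l1 >= l2 >= l3, unit eigenvectors.

    lambdas: (..., 3) descending eigenvalues, mm^2/s (clamped nonnegative).
    vectors: (..., 3, 3) with vectors[..., :, k] the eigenvector of lambdas[..., k],
    expressed in the world (RAS) frame, sign-fixed so the largest-magnitude
    component of each vector is positive.
    """

    lambdas: np.ndarray
    vectors: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.lambdas.shape[:-1], dtype=bool)

    @property
    def l1(self) -> np.ndarray:
        return self.lambdas[..., 0]

    @property
    def l2(self) -> np.ndarray:
        return self.lambdas[..., 1]

    @property
    def l3(self) -> np.ndarray:
        return self.lambdas[..., 2]

    @property
    def e1(self) -> np.ndarray:
        return self.vectors[..., :, 0]


@dataclass
class ShapeMetrics:
    """Westin barycentric shape coordinates, each in [0,1], summing to 1."""

    CL: np.ndarray
    CP: np.ndarray
    CS: np.ndarray


class ConfigClass(Enum):
    """Eigenvalue degeneracy pattern with its display color."""

    ORTHOTROPIC = 0  # l1 > l2 > l3, purple
    PROLATE = 1      # l1 > l2 = l3, orange
    OBLATE = 2       # l1 = l2 > l3, green
    ISOTROPIC = 3    # l1 = l2 = l3, gray


CONFIG_COLORS = {
    ConfigClass.ORTHOTROPIC: (0.5, 0.0, 0.5),
    ConfigClass.PROLATE: (1.0, 0.55, 0.0),
    ConfigClass.OBLATE: (0.0, 0.6, 0.0),
    ConfigClass.ISOTROPIC: (0.5, 0.5, 0.5),
}


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows b * (gx^2, 2 gx gy, 2 gx gz, gy^2, 2 gy gz, gz^2) so that
    B @ d = b g^T D g for d in TENSOR_COMPONENTS order."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)[:, None]
    return b * np.stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ],
        axis=1,
    )


def fit_tensor(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    *,
    weighted: bool = False,
) -> TensorField:
    """Estimate the tensor field by (weighted) log-linear least squares.

    S0 is the mean of the b=0 volumes.  Non-positive signals are clipped to
    1e-6*S0 before the log (occurrences counted and logged).  Voxels whose
    signal is identically zero are masked out.

    weighted: one-pass WLLS with weights equal to the measured signals
    (variance-stabilizing first-order approximation); default is plain LLS.
    """
    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool) & np.all(np.isfinite(dwi.signal), axis=3)

    b0 = dwi.bvals == 0
    nz = ~b0
    if design_rank(dwi.bvecs[nz]) < 6:
        raise UnfittableDesignError("gradient directions do not span 6 tensor DOF")

    S0 = dwi.signal[..., b0].mean(axis=3)
    dead = mask & (S0 <= 0)
    if dead.any():
        log.warning("masking %d voxels with non-positive S0", int(dead.sum()))
        mask = mask & ~dead

    S = dwi.signal[..., nz]
    allzero = mask & np.all(S <= 0, axis=3)
    if allzero.any():
        log.warning("masking %d all-zero-signal voxels", int(allzero.sum()))
        mask = mask & ~allzero

    B = design_matrix(dwi.bvals[nz], dwi.bvecs[nz])
    D = np.zeros(shape + (6,))
    idx = np.nonzero(mask)
    if idx[0].size:
        Sv = S[idx]                       # (nvox, ngrad)
        S0v = S0[idx][:, None]
        floor = SIGNAL_FLOOR_FRACTION * S0v
        nclip = int(np.sum(Sv < floor))
        if nclip:
            log.info("clipped %d non-positive/low signal samples to 1e-6*S0", nclip)
        y = -np.log(np.maximum(Sv, floor) / S0v)  # (nvox, ngrad)
        if weighted:
            w = np.maximum(Sv, floor)
            # per-voxel weighted normal equations, vectorized over voxels
            A = np.einsum("gi,vg,gj->vij", B, w * w, B)
            rhs = np.einsum("gi,vg->vi", B, w * w * y)
            D[idx] = np.linalg.solve(A, rhs)
        else:
            Bpinv = np.linalg.pinv(B)             # (6, ngrad)
            D[idx] = y @ Bpinv.T
    return TensorField(D=D, mask=mask, affine=dwi.affine)


def design_rank(bvecs: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(design_matrix(np.ones(len(bvecs)), bvecs)))


def eigendecompose(fld: TensorField) -> EigenSystem:
    """Per-voxel sorted eigensystem of a tensor field.

    Eigenvalues sorted descending; negatives (noise) clamped to zero with a
    logged count; non-finite tensors masked out, never propagated.  Eigenvector
    signs fixed so the largest-magnitude component is positive.
    """
    M = fld.as_matrices()
    finite = np.all(np.isfinite(fld.D), axis=3)
    bad = fld.mask & ~finite
    if bad.any():
        log.warning("masking %d voxels with non-finite tensor components", int(bad.sum()))
    mask = fld.mask & finite
    M[~mask] = 0.0

    w, V = np.linalg.eigh(M)           # ascending
    w = w[..., ::-1]
    V = V[..., ::-1]

    nneg = int(np.sum(w[mask] < 0))
    if nneg:
        log.info("clamped %d negative eigenvalues to 0", nneg)
    w = np.maximum(w, 0.0)

    # deterministic sign: largest-|component| entry of each eigenvector positive
    comp = np.argmax(np.abs(V), axis=-2, keepdims=True)
    sgn = np.sign(np.take_along_axis(V, comp, axis=-2))
    sgn[sgn == 0] = 1.0
    V = V * sgn
    return EigenSystem(lambdas=w, vectors=V, mask=mask)


def shape_metrics(eigs: EigenSystem | np.ndarray) -> ShapeMetrics:
    """Westin CL/CP/CS from sorted nonnegative eigenvalues.

    Degenerate all-zero triples map to (0, 0, 1) — the isotropic corner — with
    a warning, so downstream barycentric logic never sees NaN.
    """
    lam = eigs.lambdas if isinstance(eigs, EigenSystem) else np.asarray(eigs, dtype=float)
    tr = lam.sum(axis=-1)
    zero = tr <= 0
    if np.any(zero):
        log.warning("%d zero-trace voxels mapped to CS=1", int(np.sum(zero)))
    safe = np.where(zero, 1.0, tr)
    CL = np.where(zero, 0.0, (lam[..., 0] - lam[..., 1]) / safe)
    CP = np.where(zero, 0.0, 2.0 * (lam[..., 1] - lam[..., 2]) / safe)
    CS = np.where(zero, 1.0, 3.0 * lam[..., 2] / safe)
    return ShapeMetrics(CL=CL, CP=CP, CS=CS)


def classify_configuration(
    eigs: EigenSystem | np.ndarray, rel_tol: float = 0.05
) -> np.ndarray:
    """Four-way eigenvalue-configuration labels.

    Equality lambda_i = lambda_j is declared when (lambda_i - lambda_j)/lambda_1
    <= rel_tol; the relative form makes the labels invariant to uniform scaling.
    lambda_1 = 0 is ISOTROPIC by convention.  Returns an array of ConfigClass
    values (dtype=object for arrays; a scalar ConfigClass for a single triple).
    """
    lam = eigs.lambdas if isinstance(eigs, EigenSystem) else np.asarray(eigs, dtype=float)
    scalar = lam.ndim == 1
    lam = np.atleast_2d(lam)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    safe = np.where(l1 > 0, l1, 1.0)
    eq12 = (l1 - l2) / safe <= rel_tol
    eq23 = (l2 - l3) / safe <= rel_tol
    zero = l1 <= 0

    out = np.empty(lam.shape[:-1], dtype=object)
    out[...] = ConfigClass.ORTHOTROPIC
    out[eq23 & ~eq12] = ConfigClass.PROLATE
    out[eq12 & ~eq23] = ConfigClass.OBLATE
    out[(eq12 & eq23) | zero] = ConfigClass.ISOTROPIC
    return out[0] if scalar and out.shape == (1,) else (out.item() if scalar else out)
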