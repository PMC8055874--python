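"""Quasi-static linear-elastic tissue mechanics coupled to tumor growth.

An expanding tumor pushes on surrounding tissue.  At each time the
displacement field u solves the isotropic linear-elastic equilibrium
equation forced by the tumor-fraction gradient:

    div(G grad u) + grad[ G/(1-2 nu) (div u) ] - lambda2 grad(phi) = 0

with u = 0 on (and outside) the brain-mask boundary — the skull is rigid.
The von Mises stress sigma_vm summarizes the resulting deviatoric stress
and exponentially damps tumor cell diffusion:

    D = D0 * exp(-lambda1 * sigma_vm).

Discretization is second-order central differences on the (anisotropic)
image grid with harmonic averaging of the shear modulus at tissue
interfaces.  The operator depends only on the tissue labels, so it is
assembled and factorized once (sparse LU) and reused for every time step
and every calibration iteration; the residual of each solve is checked
against a configurable tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .core import TISSUE_CSF, TISSUE_GRAY, TISSUE_WHITE, ImageGrid
from .errors import InvalidParameterError, SolverError


@dataclass(frozen=True)
class ElasticityParams:
    """Tissue elastic properties (kPa) and the forcing coupling constant.

    Literature values: white matter G = 2.7 kPa, gray matter G = 3.1 kPa,
    Poisson ratio 0.45 (nearly incompressible).  CSF bears negligible shear;
    a small positive modulus keeps the discrete system well posed.
    """

    g_white: float = 2.7
    g_gray: float = 3.1
    g_csf: float = 0.1
    nu: float = 0.45
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        for name, g in (("g_white", self.g_white), ("g_gray", self.g_gray),
                        ("g_csf", self.g_csf)):
            if g <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {g}")
        if not (0 < self.nu < 0.5):
            raise InvalidParameterError(f"Poisson ratio must be in (0, 0.5), got {self.nu}")


def shear_modulus_field(tissue_labels: np.ndarray, params: ElasticityParams) -> np.ndarray:
    """Per-voxel shear modulus from the tissue label map (kPa)."""
    g = np.zeros(tissue_labels.shape, dtype=float)
    g[tissue_labels == TISSUE_WHITE] = params.g_white
    g[tissue_labels == TISSUE_GRAY] = params.g_gray
    g[tissue_labels == TISSUE_CSF] = params.g_csf
    return g


def central_gradient(f: np.ndarray, spacing, axis: int) -> np.ndarray:
    """Central difference with zero padding beyond the grid edges."""
    out = np.zeros_like(f, dtype=float)
    h = spacing[axis]
    sl_c = [slice(None)] * 3
    sl_p = [slice(None)] * 3
    sl_m = [slice(None)] * 3
    sl_c[axis] = slice(1, -1)
    sl_p[axis] = slice(2, None)
    sl_m[axis] = slice(None, -2)
    out[tuple(sl_c)] = (f[tuple(sl_p)] - f[tuple(sl_m)]) / (2 * h)
    # Edge planes: neighbor outside the grid is zero.
    first = [slice(None)] * 3
    second = [slice(None)] * 3
    first[axis] = 0
    second[axis] = 1
    out[tuple(first)] = f[tuple(second)] / (2 * h)
    last = [slice(None)] * 3
    penult = [slice(None)] * 3
    last[axis] = -1
    penult[axis] = -2
    out[tuple(last)] = -f[tuple(penult)] / (2 * h)
    return out


class ElasticSolver:
    """Assembles and factorizes the elastic operator for one tissue geometry.

    Reuse one instance across time steps and calibration iterations: only
    the right-hand side (the tumor-fraction gradient) changes.
    """

    def __init__(
        self,
        tissue_labels: np.ndarray,
        brain_mask: np.ndarray,
        grid: ImageGrid,
        params: ElasticityParams | None = None,
        tol: float = 1e-8,
    ) -> None:
        self.params = params or ElasticityParams()
        self.grid = grid
        self.mask = np.asarray(brain_mask, dtype=bool)
        self.tol = tol
        self.g_field = shear_modulus_field(tissue_labels, self.params)
        self.kappa_field = self.g_field / (1 - 2 * self.params.nu)
        self.n_vox = int(self.mask.sum())
        if self.n_vox == 0:
            raise InvalidParameterError("brain mask is empty")
        self._idx3 = -np.ones(grid.shape, dtype=np.int64)
        self._idx3[self.mask] = np.arange(self.n_vox)
        self._coords = np.argwhere(self.mask)
        # Nearest in-mask voxel for every voxel: used to extend phi beyond
        # the brain before differencing, so a spatially constant phi has
        # zero forcing (the skull feels no spurious edge gradient).
        from scipy import ndimage

        _, idx = ndimage.distance_transform_edt(
            ~self.mask, sampling=grid.spacing, return_indices=True
        )
        self._nearest_inside = tuple(idx)
        self.operator = self._assemble()
        try:
            self._lu = splu(self.operator)
        except RuntimeError as exc:  # pragma: no cover - singular geometry
            raise SolverError(f"elastic operator factorization failed: {exc}") from exc

    # -- assembly -----------------------------------------------------------

    def _neighbor_ids(self, offset: np.ndarray) -> np.ndarray:
        """Unknown-voxel index of each in-mask voxel's neighbor (-1 if none)."""
        q = self._coords + offset
        shape = np.asarray(self.grid.shape)
        inb = np.all((q >= 0) & (q < shape), axis=1)
        nid = np.full(self.n_vox, -1, dtype=np.int64)
        nid[inb] = self._idx3[q[inb, 0], q[inb, 1], q[inb, 2]]
        return nid

    def _assemble(self) -> csc_matrix:
        h = self.grid.spacing
        n = self.n_vox
        gc = self.g_field[self.mask]
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        p_ids = np.arange(n)

        def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # div(G grad u_i): flux form, harmonic face modulus; a missing
        # neighbor is a rigid wall (u = 0) with the local modulus.
        for a in range(3):
            h2 = h[a] ** 2
            for s in (1, -1):
                off = np.zeros(3, dtype=int)
                off[a] = s
                nid = self._neighbor_ids(off)
                has = nid >= 0
                gq = np.where(
                    has,
                    self.g_field[tuple((self._coords + off).clip(0, np.asarray(self.grid.shape) - 1).T)],
                    gc,
                )
                gf = np.where(has & (gc + gq > 0), 2 * gc * gq / np.maximum(gc + gq, 1e-300), gc)
                for i in range(3):
                    add(3 * p_ids + i, 3 * p_ids + i, -gf / h2)
                    ok = has
                    add(3 * p_ids[ok] + i, 3 * nid[ok] + i, gf[ok] / h2)

        # grad_i [ kappa (div u) ]: wide central stencil; the kappa*div term
        # is dropped at voxels outside the mask (u vanishes there anyway).
        shape_arr = np.asarray(self.grid.shape)
        for i in range(3):
            for s in (1, -1):
                off_i = np.zeros(3, dtype=int)
                off_i[i] = s
                nid_q = self._neighbor_ids(off_i)
                has_q = nid_q >= 0
                q_coords = (self._coords + off_i).clip(0, shape_arr - 1)
                kq = np.where(has_q, self.kappa_field[tuple(q_coords.T)], 0.0)
                for j in range(3):
                    for s2 in (1, -1):
                        off_j = np.zeros(3, dtype=int)
                        off_j[j] = s2
                        rid = self._neighbor_ids(off_i + off_j)
                        ok = has_q & (rid >= 0)
                        coef = s * s2 * kq[ok] / (4 * h[i] * h[j])
                        add(3 * p_ids[ok] + i, 3 * rid[ok] + j, coef)

        mat = coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * n, 3 * n),
        )
        return mat.tocsc()

    # -- solves -------------------------------------------------------------

    def rhs_from_phi(self, phi: np.ndarray) -> np.ndarray:
        """Right-hand side lambda2 * grad(phi) restricted to in-mask voxels.

        phi is extended beyond the brain mask by nearest neighbor first, so
        the gradient at the boundary reflects only in-brain variation.
        """
        phi_ext = np.asarray(phi, dtype=float)[self._nearest_inside]
        b = np.empty(3 * self.n_vox)
        for i in range(3):
            if self.grid.shape[i] > 1:
                gi = np.gradient(phi_ext, self.grid.spacing[i], axis=i)
            else:
                gi = np.zeros_like(phi_ext)
            b[i::3] = self.params.lambda2 * gi[self.mask]
        return b

    def solve_rhs(self, b: np.ndarray) -> np.ndarray:
        """Solve A x = b; returns the packed unknown vector."""
        x = self._lu.solve(b)
        bnorm = float(np.linalg.norm(b))
        if bnorm > 0:
            res = float(np.linalg.norm(self.operator @ x - b)) / bnorm
            if not np.isfinite(res) or res > max(self.tol, 1e-10) * 100:
                raise SolverError(f"elastic solve residual {res:.3e} exceeds tolerance")
        return x

    def unpack(self, x: np.ndarray) -> np.ndarray:
        """Packed vector -> displacement array of shape (3, *grid.shape)."""
        u = np.zeros((3,) + self.grid.shape)
        for i in range(3):
            u[i][self.mask] = x[i::3]
        return u

    def pack(self, u: np.ndarray) -> np.ndarray:
        x = np.empty(3 * self.n_vox)
        for i in range(3):
            x[i::3] = u[i][self.mask]
        return x

    def displacement(self, phi: np.ndarray) -> np.ndarray:
        """Displacement field (mm) driven by the tumor-fraction gradient."""
        b = self.rhs_from_phi(phi)
        if not np.any(b):
            return np.zeros((3,) + self.grid.shape)
        return self.unpack(self.solve_rhs(b))

    def von_mises(self, u: np.ndarray) -> np.ndarray:
        return von_mises(u, self.g_field, self.grid, self.params, mask=self.mask)


# Factorizations are expensive and depend only on (labels, mask, grid,
# elastic parameters); a tiny FIFO cache shares them across phantom
# synthesis, calibration problems and repeated experiments.
_SOLVER_CACHE: dict[tuple, "ElasticSolver"] = {}
_SOLVER_CACHE_MAX = 4


def get_elastic_solver(
    tissue_labels: np.ndarray,
    brain_mask: np.ndarray,
    grid: ImageGrid,
    params: ElasticityParams | None = None,
    tol: float = 1e-8,
) -> ElasticSolver:
    """Cached :class:`ElasticSolver` keyed on the geometry content."""
    import hashlib

    params = params or ElasticityParams()
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(tissue_labels).tobytes())
    h.update(np.ascontiguousarray(brain_mask).tobytes())
    key = (h.hexdigest(), grid.shape, grid.spacing,
           params.g_white, params.g_gray, params.g_csf, params.nu, params.lambda2,
           tol)
    solver = _SOLVER_CACHE.get(key)
    if solver is None:
        solver = ElasticSolver(tissue_labels, brain_mask, grid, params, tol=tol)
        if len(_SOLVER_CACHE) >= _SOLVER_CACHE_MAX:
            _SOLVER_CACHE.pop(next(iter(_SOLVER_CACHE)))
        _SOLVER_CACHE[key] = solver
    return solver


def solve_displacement(
    phi: np.ndarray,
    tissue_labels: np.ndarray,
    params: ElasticityParams,
    brain_mask: np.ndarray,
    grid: ImageGrid,
    tol: float = 1e-8,
) -> np.ndarray:
    """One-shot displacement solve (assembles the operator each call).

    Prefer :class:`ElasticSolver` when solving repeatedly on one geometry.
    """
    return ElasticSolver(tissue_labels, brain_mask, grid, params, tol=tol).displacement(phi)


def von_mises(
    u: np.ndarray,
    g_field: np.ndarray,
    grid: ImageGrid,
    params: ElasticityParams,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Von Mises stress (kPa) of a displacement field.

    Uses the isotropic linear-elastic constitutive law; being built from the
    deviatoric stress, sigma_vm vanishes for purely hydrostatic states and
    equals |s| for a uniaxial stress of magnitude s.
    """
    h = grid.spacing
    # Strain tensor from central differences of u.
    grad = np.empty((3, 3) + tuple(grid.shape))
    for i in range(3):
        for j in range(3):
            grad[i, j] = central_gradient(u[i], h, j)
    eps = 0.5 * (grad + grad.transpose(1, 0, 2, 3, 4))
    lam = 2 * g_field * params.nu / (1 - 2 * params.nu)
    tr_eps = eps[0, 0] + eps[1, 1] + eps[2, 2]
    sigma = 2 * g_field * eps
    for k in range(3):
        sigma[k, k] += lam * tr_eps
    mean_sigma = (sigma[0, 0] + sigma[1, 1] + sigma[2, 2]) / 3.0
    dev = sigma.copy()
    for k in range(3):
        dev[k, k] -= mean_sigma
    vm = np.sqrt(np.maximum(1.5 * np.einsum("ij...,ij...->...", dev, dev), 0.0))
    if mask is not None:
        vm = np.where(np.asarray(mask, dtype=bool), vm, 0.0)
    return vm


def damp_diffusion(d0: np.ndarray, sigma_vm: np.ndarray, lambda1: float) -> np.ndarray:
    """Exponential stress damping of diffusion: D = D0 * exp(-lambda1 * sigma_vm)."""
    if lambda1 < 0:
        raise InvalidParameterError(f"lambda1 must be >= 0, got {lambda1}")
    return np.asarray(d0, dtype=float) * np.exp(-lambda1 * np.asarray(sigma_vm, dtype=float))
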