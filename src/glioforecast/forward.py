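"""Explicit 3-D finite-difference integration of the growth models.

Single species:

    d(phi_T)/dt = div(D_T grad phi_T) + k_pT phi_T (1 - phi_T/theta_T)

Two species (enhancing E and non-enhancing N, competing for space):

    d(phi_E)/dt = div(D_E grad phi_E)
                  + k_pE phi_E (1 - (phi_E + beta_NE phi_N)/theta_E)
    d(phi_N)/dt = div(D_N grad phi_N)
                  + k_pN phi_N (1 - (phi_N + beta_EN phi_E)/theta_N)

Diffusion is tissue-wise (one coefficient for white matter, one for gray),
exponentially damped by the von Mises stress (mechanics module), zero in
CSF and outside the brain (tumor cells do not invade CSF), with no-flux
behavior at the brain boundary arising from the conservative flux-form
stencil.  Time stepping is forward Euler with the standard explicit
stability bound; treatments are instantaneous multiplicative events
(therapy module) applied at the first step at or after each scheduled day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    TISSUE_GRAY,
    TISSUE_WHITE,
    ImageGrid,
    TumorState,
)
from .errors import InstabilityError, InvalidParameterError
from .mechanics import ElasticityParams, ElasticSolver
from .therapy import (
    ModelSpec,
    TherapyParams,
    TreatmentSchedule,
    apply_treatment,
    surviving_fraction,
)


@dataclass(frozen=True)
class GrowthParams:
    """Growth-model parameters (rates in 1/day, diffusion in mm^2/day).

    Single-species runs use ``d_t_w``, ``d_t_g``, ``k_p_t``, ``theta_t``;
    two-species runs use the E/N fields.  Proliferation rates may be scalars
    or per-voxel fields (arrays on the image grid).  ``lambda1`` (1/kPa) is
    the stress-diffusion coupling shared by both bases; the competition
    weights ``beta_ne``/``beta_en`` and ``theta_n`` are fixed by convention
    (4, 1 and 0.16).
    """

    # single species
    d_t_w: float = 0.0
    d_t_g: float = 0.0
    k_p_t: float | np.ndarray = 0.0
    theta_t: float = 1.0
    # two species
    d_e_w: float = 0.0
    d_e_g: float = 0.0
    d_n_w: float = 0.0
    d_n_g: float = 0.0
    k_p_e: float | np.ndarray = 0.0
    k_p_n: float = 0.0
    theta_e: float = 1.0
    theta_n: float = 0.16
    beta_ne: float = 4.0
    beta_en: float = 1.0
    # shared
    lambda1: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_t_w", "d_t_g", "d_e_w", "d_e_g", "d_n_w", "d_n_g"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("theta_t", "theta_e", "theta_n"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")
        if self.beta_ne < 0 or self.beta_en < 0:
            raise InvalidParameterError("competition terms must be >= 0")
        if self.lambda1 < 0:
            raise InvalidParameterError("lambda1 must be >= 0")

    def max_diffusion(self, base: str) -> float:
        if base == "single":
            return max(self.d_t_w, self.d_t_g)
        return max(self.d_e_w, self.d_e_g, self.d_n_w, self.d_n_g)


@dataclass(frozen=True)
class SimulationSettings:
    """Time-integration controls.

    ``dt`` (days) is the nominal step; if omitted it defaults to the
    explicit stability bound with the given safety factor.  Whatever is
    requested, the step actually used never exceeds the stability bound.
    ``mechanics_stride`` re-solves the elasticity problem every k steps
    (1 = every step).
    """

    dt: float | None = None
    safety: float = 0.9
    mechanics_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt is not None and self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if not (0 < self.safety <= 1):
            raise InvalidParameterError(f"safety must be in (0, 1], got {self.safety}")
        if self.mechanics_stride < 1:
            raise InvalidParameterError("mechanics_stride must be >= 1")


@dataclass
class DomainContext:
    """Static per-patient geometry shared by all simulations.

    Carries the grid, brain mask, tissue labels, the enhancement-ratio
    field (held fixed at the most recent measured visit; the model does not
    evolve vasculature), and a lazily-built cached elastic solver.
    """

    grid: ImageGrid
    brain_mask: np.ndarray
    tissue_labels: np.ndarray
    er_field: np.ndarray | None = None
    elasticity: ElasticityParams = field(default_factory=ElasticityParams)
    mechanics_tol: float = 1e-8
    _solver: ElasticSolver | None = field(default=None, repr=False, compare=False)

    def elastic_solver(self) -> ElasticSolver:
        if self._solver is None:
            from .mechanics import get_elastic_solver

            self._solver = get_elastic_solver(
                self.tissue_labels, self.brain_mask, self.grid,
                self.elasticity, tol=self.mechanics_tol,
            )
        return self._solver

    def diffusion_base_field(self, d_white: float, d_gray: float) -> np.ndarray:
        """Uninhibited tissue-wise diffusion map (zero in CSF/background)."""
        d0 = np.zeros(self.grid.shape)
        d0[self.tissue_labels == TISSUE_WHITE] = d_white
        d0[self.tissue_labels == TISSUE_GRAY] = d_gray
        d0[~self.brain_mask.astype(bool)] = 0.0
        return d0


def stable_dt(d_max: float, grid: ImageGrid, safety: float = 0.9) -> float:
    """Explicit-scheme stability bound: safety * 0.5 / (D_max sum(1/h_i^2))."""
    if d_max < 0:
        raise InvalidParameterError(f"d_max must be >= 0, got {d_max}")
    if d_max == 0:
        return math.inf
    s = sum(1.0 / h**2 for h in grid.spacing)
    return safety * 0.5 / (d_max * s)


def _face_conductances(d_field: np.ndarray, spacing) -> list[np.ndarray | None]:
    """Harmonic-mean face coefficients divided by h^2, one array per axis.

    A zero face coefficient (CSF, background, grid edge) gives zero flux,
    so the brain boundary is no-flux by construction and total mass is
    conserved exactly when the reaction term vanishes.  Recomputed only
    when the damped diffusion field changes (i.e. at mechanics updates).
    """
    faces: list[np.ndarray | None] = []
    for a in range(3):
        if d_field.shape[a] == 1:
            faces.append(None)
            continue
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        d1 = d_field[tuple(lo)]
        d2 = d_field[tuple(hi)]
        s = d1 + d2
        faces.append(
            np.where(s > 0, 2 * d1 * d2 / np.where(s > 0, s, 1.0), 0.0) / spacing[a] ** 2
        )
    return faces


def _divergence_from_faces(phi: np.ndarray, faces) -> np.ndarray:
    out = np.zeros_like(phi, dtype=float)
    for a in range(3):
        c = faces[a]
        if c is None:
            continue
        flux = c * np.diff(phi, axis=a)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        out[tuple(lo)] += flux
        out[tuple(hi)] -= flux
    return out


def _diffusion_divergence(phi: np.ndarray, d_field: np.ndarray, spacing) -> np.ndarray:
    """Conservative flux-form div(D grad phi) with harmonic face averaging."""
    return _divergence_from_faces(phi, _face_conductances(d_field, spacing))


def _check_finite(phi: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(phi)):
        mx = np.nanmax(np.abs(phi))
        raise InstabilityError(
            f"non-finite tumor fraction at step {step} (max|phi|={mx:.3e}); "
            "reduce dt or diffusion"
        )


def step_single_species(
    phi: np.ndarray,
    d_field: np.ndarray,
    k_p: float | np.ndarray,
    theta: float,
    dt: float,
    grid: ImageGrid,
    step_index: int = 0,
) -> np.ndarray:
    """One forward-Euler step of the single-species model, clamped to [0, theta]."""
    growth = k_p * phi * (1.0 - phi / theta)
    new = phi + dt * (_diffusion_divergence(phi, d_field, grid.spacing) + growth)
    _check_finite(new, step_index)
    return np.clip(new, 0.0, theta)


def step_two_species(
    phi_e: np.ndarray,
    phi_n: np.ndarray,
    d_e_field: np.ndarray,
    d_n_field: np.ndarray,
    params: GrowthParams,
    dt: float,
    grid: ImageGrid,
    step_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward-Euler step of the coupled two-species model."""
    growth_e = params.k_p_e * phi_e * (
        1.0 - (phi_e + params.beta_ne * phi_n) / params.theta_e
    )
    growth_n = params.k_p_n * phi_n * (
        1.0 - (phi_n + params.beta_en * phi_e) / params.theta_n
    )
    new_e = phi_e + dt * (_diffusion_divergence(phi_e, d_e_field, grid.spacing) + growth_e)
    new_n = phi_n + dt * (_diffusion_divergence(phi_n, d_n_field, grid.spacing) + growth_n)
    _check_finite(new_e, step_index)
    _check_finite(new_n, step_index)
    return (
        np.clip(new_e, 0.0, params.theta_e),
        np.clip(new_n, 0.0, params.theta_n),
    )


def extend_field_nearest(
    values: np.ndarray, support: np.ndarray, grid: ImageGrid
) -> np.ndarray:
    """Extend a field defined on ``support`` to the whole grid by nearest voxel.

    Used for voxel-wise proliferation maps: voxels the tumor invades later
    inherit the nearest calibrated rate.
    """
    support = np.asarray(support, dtype=bool)
    if not support.any():
        return np.zeros(grid.shape)
    _, idx = ndimage.distance_transform_edt(
        ~support, sampling=grid.spacing, return_indices=True
    )
    return values[tuple(idx)]


def _event_steps(
    schedule: TreatmentSchedule | None, t0: float, dt: float, n_steps: int
) -> dict[int, int]:
    """Map step index -> number of events due (first step at/after each day)."""
    due: dict[int, int] = {}
    if schedule is None:
        return due
    for day in schedule.days:
        if day < t0 - 1e-9:
            continue
        k = max(0, math.ceil((day - t0) / dt - 1e-9))
        if k > n_steps:
            continue
        due[k] = due.get(k, 0) + 1
    return due


def _survival_fields(
    spec: ModelSpec,
    therapy: TherapyParams,
    state: TumorState,
    growth: GrowthParams,
    ctx: DomainContext,
    n_rt: int,
    n_ct: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Combined SF_RT^n_rt and SF_CT^n_ct fields from the current state."""
    total = state.total()
    support = total > 0
    theta = growth.theta_t if spec.base == "single" else growth.theta_e
    kwargs = dict(phi=total, theta=theta, er=ctx.er_field, support=support)
    ones = np.ones(ctx.grid.shape)
    sf_rt = ones
    sf_ct = ones
    if n_rt:
        sf = surviving_fraction(spec.coupling.rt_approach, therapy.sf_rt_min, **kwargs)
        sf_rt = sf**n_rt
    if n_ct:
        sf = surviving_fraction(spec.coupling.ct_approach, therapy.sf_ct_min, **kwargs)
        sf_ct = sf**n_ct
    return sf_rt, sf_ct


def simulate(
    spec: ModelSpec,
    growth: GrowthParams,
    therapy: TherapyParams,
    initial: TumorState,
    rt_schedule: TreatmentSchedule | None,
    ct_schedule: TreatmentSchedule | None,
    record_times: Sequence[float],
    ctx: DomainContext,
    settings: SimulationSettings | None = None,
) -> list[TumorState]:
    """Run one model forward and sample it at the requested times.

    Each step interleaves (i) the mechanics solve and stress damping of the
    diffusion fields (every ``mechanics_stride`` steps, skipped entirely
    when lambda1 = 0), (ii) due treatment events, and (iii) one explicit
    reaction-diffusion step.  States are recorded at the step nearest each
    record time (after any treatment due at that step).
    """
    settings = settings or SimulationSettings()
    record_times = sorted(float(t) for t in record_times)
    t0 = initial.time
    if record_times and record_times[0] < t0 - 1e-9:
        raise InvalidParameterError(
            f"record time {record_times[0]} precedes the initial state at t={t0}"
        )
    t_end = record_times[-1] if record_times else t0
    bound = stable_dt(growth.max_diffusion(spec.base), ctx.grid, settings.safety)
    dt = min(settings.dt, bound) if settings.dt is not None else bound
    if not math.isfinite(dt):
        dt = max(t_end - t0, 1.0)  # proliferation-only: any step is stable
    n_steps = max(0, math.ceil((t_end - t0) / dt - 1e-9))

    record_map: dict[int, list[float]] = {}
    for t in record_times:
        k = int(round((t - t0) / dt))
        record_map.setdefault(min(k, n_steps), []).append(t)

    rt_due = _event_steps(rt_schedule, t0, dt, n_steps)
    ct_due = _event_steps(ct_schedule, t0, dt, n_steps)

    two = spec.base == "two_species"
    if two:
        d0_e = ctx.diffusion_base_field(growth.d_e_w, growth.d_e_g)
        d0_n = ctx.diffusion_base_field(growth.d_n_w, growth.d_n_g)
    else:
        d0_t = ctx.diffusion_base_field(growth.d_t_w, growth.d_t_g)

    state = initial.copy()
    use_mechanics = growth.lambda1 > 0 and ctx.elasticity.lambda2 != 0
    sigma_vm = np.zeros(ctx.grid.shape)
    recorded: list[TumorState] = []
    spacing = ctx.grid.spacing
    faces_e = faces_n = faces_t = None
    if not use_mechanics:
        if two:
            faces_e = _face_conductances(d0_e, spacing)
            faces_n = _face_conductances(d0_n, spacing)
        else:
            faces_t = _face_conductances(d0_t, spacing)

    for k in range(n_steps + 1):
        n_rt = rt_due.get(k, 0)
        n_ct = ct_due.get(k, 0)
        if n_rt or n_ct:
            sf_rt, sf_ct = _survival_fields(spec, therapy, state, growth, ctx, n_rt, n_ct)
            state = apply_treatment(state, sf_rt, sf_ct)
        if k in record_map:
            for t_rec in record_map[k]:
                snap = state.copy()
                snap.time = t_rec
                recorded.append(snap)
        if k == n_steps:
            break
        if use_mechanics and k % settings.mechanics_stride == 0:
            solver = ctx.elastic_solver()
            u = solver.displacement(state.total())
            sigma_vm = solver.von_mises(u)
            damp = np.exp(-growth.lambda1 * sigma_vm)
            if two:
                faces_e = _face_conductances(d0_e * damp, spacing)
                faces_n = _face_conductances(d0_n * damp, spacing)
            else:
                faces_t = _face_conductances(d0_t * damp, spacing)
        if two:
            phi_e, phi_n = state.phi_E, state.phi_N
            growth_e = growth.k_p_e * phi_e * (
                1.0 - (phi_e + growth.beta_ne * phi_n) / growth.theta_e
            )
            growth_n = growth.k_p_n * phi_n * (
                1.0 - (phi_n + growth.beta_en * phi_e) / growth.theta_n
            )
            new_e = phi_e + dt * (_divergence_from_faces(phi_e, faces_e) + growth_e)
            new_n = phi_n + dt * (_divergence_from_faces(phi_n, faces_n) + growth_n)
            _check_finite(new_e, k)
            _check_finite(new_n, k)
            state = TumorState(
                "two_species", t0 + (k + 1) * dt,
                phi_E=np.clip(new_e, 0.0, growth.theta_e),
                phi_N=np.clip(new_n, 0.0, growth.theta_n),
            )
        else:
            phi_t = state.phi_T
            g = growth.k_p_t * phi_t * (1.0 - phi_t / growth.theta_t)
            new_t = phi_t + dt * (_divergence_from_faces(phi_t, faces_t) + g)
            _check_finite(new_t, k)
            state = TumorState(
                "single", t0 + (k + 1) * dt,
                phi_T=np.clip(new_t, 0.0, growth.theta_t),
            )

    return recorded
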