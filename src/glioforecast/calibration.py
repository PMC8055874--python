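"""Per-patient parameter estimation, forecasting, and noise robustness.

Free parameters (proliferation rates, carrying capacities, tissue-wise
diffusion coefficients, the stress-diffusion coupling and the minimum
surviving fractions) are estimated by bounded damped least squares —
scipy's trust-region-reflective solver, the bound-honoring equivalent of
Levenberg-Marquardt — against voxel-wise cell-fraction measurements at
the calibration visits.  Three scenarios are supported:

  1  calibrate on every follow-up visit (fit assessment; nothing held out)
  2  calibrate on the 1-month visit, forecast the rest
  3  calibrate on the 1-month and 3-month visits, forecast the rest

The baseline visit is always the initial condition and never a residual
target.  Residuals compare the simulated total cell fraction against the
DWI-derived fraction at every brain-mask voxel of every calibration
visit; for the two-species model, species identity is pinned down by the
species-specific baseline initial condition and the fixed asymmetric
competition couplings rather than by extra residual blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    CellularityParams,
    ImageGrid,
    PatientDataset,
    TumorState,
    assign_initial_state,
    compute_enhancement_ratio,
    dwi_cellularity,
)
from .errors import InsufficientDataError, InvalidParameterError, SolverError
from .forward import (
    DomainContext,
    GrowthParams,
    SimulationSettings,
    extend_field_nearest,
    simulate,
)
from .mechanics import ElasticityParams
from .therapy import ModelSpec, TherapyParams

# Default bounds and initial guesses per parameter class (units as in
# GrowthParams/TherapyParams).  All configurable per call.
DEFAULT_PARAM_SPECS: dict[str, tuple[float, float, float]] = {
    # name-class: (lower, upper, init)
    "diffusion": (0.0, 1.0, 0.05),
    "proliferation": (0.0, 0.5, 0.05),
    "theta": (0.5, 1.0, 1.0),
    "lambda1": (0.0, 10.0, 0.1),
    "sf": (0.01, 1.0, 0.8),
}


@dataclass
class Param:
    name: str
    value: float
    lower: float
    upper: float
    free: bool = True

    @property
    def scale(self) -> float:
        return max(abs(self.value), 0.05 * (self.upper - self.lower), 1e-6)


@dataclass
class FieldProliferationMap:
    """Voxel-wise proliferation parameterization on the baseline tumor mask.

    One free value per lattice cell (``downsample`` voxels per axis, 1 =
    full voxel resolution) intersecting the baseline tumor; the assembled
    field is extended to the rest of the brain by nearest neighbor so that
    voxels invaded later inherit the closest calibrated rate.
    """

    grid: ImageGrid
    support: np.ndarray
    downsample: int = 1
    cell_index: np.ndarray = field(init=False)
    n_cells: int = field(init=False)

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=bool)
        if not sup.any():
            raise InvalidParameterError("field proliferation needs a nonempty tumor mask")
        ds = int(self.downsample)
        if ds < 1:
            raise InvalidParameterError("downsample must be >= 1")
        idx = np.indices(self.grid.shape)
        lattice = tuple(idx[a] // ds for a in range(3))
        flat = np.ravel_multi_index(
            lattice, tuple(-(-n // ds) for n in self.grid.shape)
        )
        cells = np.unique(flat[sup])
        remap = -np.ones(flat.max() + 1, dtype=np.int64)
        remap[cells] = np.arange(len(cells))
        ci = remap[flat]
        ci[~sup] = -1
        self.cell_index = ci
        self.n_cells = int(len(cells))

    def field_from_values(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.grid.shape)
        inside = self.cell_index >= 0
        out[inside] = np.asarray(values)[self.cell_index[inside]]
        return extend_field_nearest(out, inside, self.grid)


@dataclass
class ParameterSet:
    """Named free/fixed parameters of one model spec, with bounds.

    Fixed constants (beta_NE=4, beta_EN=1, lambda2=1, nu=0.45, theta_N=0.16
    and the literature shear moduli) live in the GrowthParams /
    ElasticityParams defaults and are never part of the free vector.
    """

    spec: ModelSpec
    params: list[Param]
    field_map: FieldProliferationMap | None = None

    def __getitem__(self, name: str) -> Param:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def free_params(self) -> list[Param]:
        return [p for p in self.params if p.free]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def free_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.free_params])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.lower for p in self.free_params])
        hi = np.array([p.upper for p in self.free_params])
        return lo, hi

    def scales(self) -> np.ndarray:
        return np.array([p.scale for p in self.free_params])

    def with_free_vector(self, x: np.ndarray) -> "ParameterSet":
        out = ParameterSet(
            spec=self.spec,
            params=[replace(p) for p in self.params],
            field_map=self.field_map,
        )
        it = iter(np.asarray(x, dtype=float))
        for p in out.params:
            if p.free:
                p.value = float(next(it))
        return out

    def with_values(self, values: Mapping[str, float]) -> "ParameterSet":
        out = ParameterSet(
            spec=self.spec,
            params=[replace(p) for p in self.params],
            field_map=self.field_map,
        )
        for name, v in values.items():
            out[name].value = float(v)
        return out

    def scalar_values(self) -> dict[str, float]:
        """Values of the scalar (non-field) parameters."""
        return {p.name: p.value for p in self.params if "[" not in p.name}

    # -- conversion to model parameter objects ------------------------------

    def _field_values(self, prefix: str) -> np.ndarray:
        vals = [p.value for p in self.params if p.name.startswith(prefix + "[")]
        return np.asarray(vals)

    def to_growth_params(self) -> GrowthParams:
        v = {p.name: p.value for p in self.params if "[" not in p.name}
        if self.spec.base == "single":
            if self.spec.proliferation == "field":
                assert self.field_map is not None
                k_p_t: float | np.ndarray = self.field_map.field_from_values(
                    self._field_values("k_p_t")
                )
            else:
                k_p_t = v["k_p_t"]
            return GrowthParams(
                d_t_w=v["d_t_w"], d_t_g=v["d_t_g"], k_p_t=k_p_t,
                theta_t=v["theta_t"], lambda1=v["lambda1"],
            )
        if self.spec.proliferation == "field":
            assert self.field_map is not None
            k_p_e: float | np.ndarray = self.field_map.field_from_values(
                self._field_values("k_p_e")
            )
        else:
            k_p_e = v["k_p_e"]
        return GrowthParams(
            d_e_w=v["d_e_w"], d_e_g=v["d_e_g"], d_n_w=v["d_n_w"], d_n_g=v["d_n_g"],
            k_p_e=k_p_e, k_p_n=v["k_p_n"], theta_e=v["theta_e"],
            lambda1=v["lambda1"],
        )

    def to_therapy_params(self) -> TherapyParams:
        return TherapyParams(
            sf_rt_min=self["sf_rt_min"].value, sf_ct_min=self["sf_ct_min"].value
        )


def build_parameter_set(
    spec: ModelSpec,
    *,
    field_map: FieldProliferationMap | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    init: Mapping[str, float] | None = None,
) -> ParameterSet:
    """Free-parameter roster for a model spec with default bounds/guesses.

    ``bounds``/``init`` override individual parameters by name, or whole
    classes via the keys "diffusion", "proliferation", "theta", "lambda1",
    "sf".
    """
    bounds = dict(bounds or {})
    init = dict(init or {})

    def make(name: str, klass: str) -> Param:
        lo, hi, x0 = DEFAULT_PARAM_SPECS[klass]
        lo, hi = bounds.get(name, bounds.get(klass, (lo, hi)))
        x0 = init.get(name, init.get(klass, min(max(x0, lo), hi)))
        return Param(name=name, value=x0, lower=lo, upper=hi)

    params: list[Param] = []
    if spec.base == "single":
        prolif_name, theta_name = "k_p_t", "theta_t"
        diff_names = ["d_t_w", "d_t_g"]
    else:
        prolif_name, theta_name = "k_p_e", "theta_e"
        diff_names = ["d_e_w", "d_e_g", "d_n_w", "d_n_g"]

    if spec.proliferation == "field":
        if field_map is None:
            raise InvalidParameterError(
                "field proliferation requires a FieldProliferationMap"
            )
        for j in range(field_map.n_cells):
            params.append(make(f"{prolif_name}[{j}]", "proliferation"))
    else:
        params.append(make(prolif_name, "proliferation"))
    if spec.base == "two_species":
        params.append(make("k_p_n", "proliferation"))
    params.append(make(theta_name, "theta"))
    params.extend(make(n, "diffusion") for n in diff_names)
    params.append(make("lambda1", "lambda1"))
    params.append(make("sf_rt_min", "sf"))
    params.append(make("sf_ct_min", "sf"))
    return ParameterSet(spec=spec, params=params, field_map=field_map)


def parameter_set_from_truth(
    spec: ModelSpec,
    growth: GrowthParams,
    therapy: TherapyParams,
    *,
    field_map: FieldProliferationMap | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> ParameterSet:
    """A parameter set whose values equal a known generating truth."""
    pset = build_parameter_set(spec, field_map=field_map, bounds=bounds)
    values: dict[str, float] = {}
    if spec.base == "single":
        values.update(d_t_w=growth.d_t_w, d_t_g=growth.d_t_g, theta_t=growth.theta_t)
        if spec.proliferation == "global":
            values["k_p_t"] = float(growth.k_p_t)
    else:
        values.update(
            d_e_w=growth.d_e_w, d_e_g=growth.d_e_g,
            d_n_w=growth.d_n_w, d_n_g=growth.d_n_g,
            k_p_n=growth.k_p_n, theta_e=growth.theta_e,
        )
        if spec.proliferation == "global":
            values["k_p_e"] = float(growth.k_p_e)
    values.update(
        lambda1=growth.lambda1,
        sf_rt_min=therapy.sf_rt_min, sf_ct_min=therapy.sf_ct_min,
    )
    return pset.with_values(values)


def perturb_parameter_set(pset: ParameterSet, factor: float) -> ParameterSet:
    """Multiply every free value by ``factor``, clipped strictly inside bounds."""
    out = pset.with_free_vector(pset.free_vector())
    for p in out.params:
        if p.free:
            width = p.upper - p.lower
            p.value = float(
                np.clip(p.value * factor, p.lower + 1e-6 * width, p.upper - 1e-6 * width)
            )
    return out


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationScenario:
    """Which follow-up visits are fit and which are forecast."""

    id: int
    calibration_indices: tuple[int, ...]
    prediction_indices: tuple[int, ...]


def partition_visits(dataset: PatientDataset, scenario_id: int) -> CalibrationScenario:
    """Deterministic visit partition for scenarios 1-3.

    The baseline (index 0) is the initial condition, never a residual
    target.  Scenario 1 calibrates on every follow-up; scenario 2 on the
    first follow-up (1-month); scenario 3 on the first two follow-ups
    (1-month and 3-month).
    """
    n = len(dataset.visits)
    followups = tuple(range(1, n))
    if scenario_id == 1:
        return CalibrationScenario(1, followups, ())
    if scenario_id == 2:
        if n < 2:
            raise InsufficientDataError("scenario 2 requires at least one follow-up visit")
        return CalibrationScenario(2, followups[:1], followups[1:])
    if scenario_id == 3:
        if n < 3:
            raise InsufficientDataError(
                "scenario 3 requires both the 1-month and 3-month visits"
            )
        return CalibrationScenario(3, followups[:2], followups[2:])
    raise InvalidParameterError(f"unknown scenario id {scenario_id}")


# ---------------------------------------------------------------------------
# The inverse problem
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    parameter_set: ParameterSet
    sse: float
    n_obs: int
    n_free: int
    nfev: int
    success: bool
    message: str
    fitted_states: list[TumorState]

    def scalar_values(self) -> dict[str, float]:
        return self.parameter_set.scalar_values()


class CalibrationProblem:
    """Binds one model spec to one dataset and scenario.

    Precomputes the measured cell-fraction maps, the baseline initial
    condition, and the static domain context (whose elastic factorization
    is shared by every simulation of the fit).
    """

    def __init__(
        self,
        spec: ModelSpec,
        dataset: PatientDataset,
        scenario: CalibrationScenario | int,
        *,
        cellularity: CellularityParams | None = None,
        elasticity: ElasticityParams | None = None,
        settings: SimulationSettings | None = None,
        parameter_set: ParameterSet | None = None,
        field_downsample: int = 1,
        nonenhancing_mode: Literal["fixed", "linear_decay"] = "fixed",
        ctx: DomainContext | None = None,
    ) -> None:
        dataset.validate()
        self.spec = spec
        self.dataset = dataset
        self.scenario = (
            scenario if isinstance(scenario, CalibrationScenario)
            else partition_visits(dataset, scenario)
        )
        self.cellularity = cellularity or CellularityParams()
        self.settings = settings or SimulationSettings()
        baseline = dataset.baseline
        if ctx is not None:
            # Reuse a shared context (and its cached elastic factorization)
            # when fitting several models to one patient.
            self.ctx = ctx
        else:
            er = compute_enhancement_ratio(
                baseline.t1_post, baseline.t1_pre, baseline.brain_mask
            )
            self.ctx = DomainContext(
                grid=dataset.grid,
                brain_mask=baseline.brain_mask.astype(bool),
                tissue_labels=baseline.tissue_labels,
                er_field=er,
                elasticity=elasticity or ElasticityParams(),
            )
        self.initial = assign_initial_state(
            baseline, spec.base, self.cellularity, nonenhancing_mode=nonenhancing_mode
        )
        self.calibration_times = [
            dataset.visits[i].time for i in self.scenario.calibration_indices
        ]
        self.prediction_times = [
            dataset.visits[i].time for i in self.scenario.prediction_indices
        ]
        self._brain = self.ctx.brain_mask
        self.measured = [
            dwi_cellularity(dataset.visits[i], self.cellularity)[self._brain]
            for i in self.scenario.calibration_indices
        ]
        if parameter_set is not None:
            self.parameter_set = parameter_set
        else:
            fmap = None
            if spec.proliferation == "field":
                fmap = FieldProliferationMap(
                    grid=dataset.grid,
                    support=baseline.union_tumor_mask,
                    downsample=field_downsample,
                )
            self.parameter_set = build_parameter_set(spec, field_map=fmap)

    @property
    def n_obs(self) -> int:
        return int(self._brain.sum()) * len(self.measured)

    def simulate_states(
        self, pset: ParameterSet, times: Sequence[float]
    ) -> list[TumorState]:
        return simulate(
            self.spec,
            pset.to_growth_params(),
            pset.to_therapy_params(),
            self.initial,
            self.dataset.rt_schedule,
            self.dataset.ct_schedule,
            times,
            self.ctx,
            self.settings,
        )

    def residuals(self, pset: ParameterSet) -> np.ndarray:
        """Simulated minus measured total cell fraction, all calibration visits."""
        states = self.simulate_states(pset, self.calibration_times)
        parts = [
            s.total()[self._brain] - m for s, m in zip(states, self.measured)
        ]
        return np.concatenate(parts) if parts else np.empty(0)

    def residual_vector(self, x: np.ndarray) -> np.ndarray:
        return self.residuals(self.parameter_set.with_free_vector(x))


def calibrate(
    problem: CalibrationProblem,
    *,
    init: ParameterSet | None = None,
    ftol: float = 1e-6,
    xtol: float = 1e-8,
    gtol: float = 1e-10,
    max_iter: int = 100,
    max_nfev: int | None = None,
    diff_step: float = 1e-3,
) -> CalibrationResult:
    """Bounded least-squares fit of the free parameters.

    Stops on relative-SSE change (``ftol``), step norm (``xtol``), gradient
    norm (``gtol``) or the iteration budget; on non-convergence the
    best-so-far parameters are returned with ``success=False``.
    """
    pset = init if init is not None else problem.parameter_set
    x0 = pset.free_vector()
    lo, hi = pset.bounds()
    x0 = np.clip(x0, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo))
    if max_nfev is None:
        max_nfev = max_iter * (pset.n_free + 2)

    def fun(x: np.ndarray) -> np.ndarray:
        return problem.residuals(pset.with_free_vector(x))

    try:
        res = least_squares(
            fun, x0, bounds=(lo, hi), method="trf",
            x_scale=pset.scales(), diff_step=diff_step,
            ftol=ftol, xtol=xtol, gtol=gtol, max_nfev=max_nfev,
        )
    except (ValueError, SolverError) as exc:
        raise SolverError(
            f"calibration failed for {problem.spec.model_id}: {exc}"
        ) from exc

    best = pset.with_free_vector(res.x)
    fitted = problem.simulate_states(best, problem.calibration_times)
    return CalibrationResult(
        parameter_set=best,
        sse=float(2 * res.cost),
        n_obs=int(res.fun.size),
        n_free=pset.n_free,
        nfev=int(res.nfev),
        success=bool(res.status > 0),
        message=str(res.message),
        fitted_states=fitted,
    )


def forecast(
    problem: CalibrationProblem, result: CalibrationResult
) -> list[TumorState]:
    """Forward-run the calibrated model through the held-out visit times."""
    if not problem.prediction_times:
        return []
    return problem.simulate_states(result.parameter_set, problem.prediction_times)


# ---------------------------------------------------------------------------
# Noise robustness
# ---------------------------------------------------------------------------

def noise_robustness(
    config,
    noise_levels: Sequence[float],
    replicates: int,
    seed: int,
    *,
    scenario_id: int = 2,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    settings: SimulationSettings | None = None,
    calibrate_kwargs: Mapping | None = None,
) -> pd.DataFrame:
    """Parameter-estimation error versus ADC measurement noise.

    For each noise level and replicate, a phantom with known ground truth
    is regenerated with that ADC noise, recalibrated under the given
    scenario, and the percent error of every free scalar parameter
    recorded.  Deterministic given ``seed``.
    """
    from .phantom import PhantomConfig, synthesize_visits  # local: avoid cycle

    if not isinstance(config, PhantomConfig):
        raise InvalidParameterError("noise_robustness requires a PhantomConfig")
    calibrate_kwargs = dict(calibrate_kwargs or {})
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(noise_levels) * replicates) % (2**31)
    rows = []
    k = 0
    for level in noise_levels:
        for rep in range(replicates):
            cfg = replace(
                config,
                adc_noise_sd=float(level),
                seed=int(child_seeds[k]),
            )
            k += 1
            dataset, truth = synthesize_visits(cfg)
            fmap = None
            if cfg.model.proliferation == "field":
                fmap = FieldProliferationMap(
                    grid=dataset.grid, support=dataset.baseline.union_tumor_mask
                )
            pset = build_parameter_set(cfg.model, field_map=fmap, bounds=bounds)
            problem = CalibrationProblem(
                cfg.model, dataset, scenario_id,
                cellularity=truth.cellularity,
                elasticity=cfg.elasticity,
                settings=settings or cfg.settings,
                parameter_set=pset,
            )
            try:
                result = calibrate(problem, **calibrate_kwargs)
                status = "ok" if result.success else "not_converged"
            except SolverError as exc:
                rows.append(
                    {
                        "noise_sd": level, "replicate": rep, "parameter": None,
                        "truth": np.nan, "estimate": np.nan, "pct_error": np.nan,
                        "status": f"failed: {exc}",
                    }
                )
                continue
            truth_pset = parameter_set_from_truth(
                cfg.model, truth.growth, truth.therapy, field_map=fmap, bounds=bounds
            )
            est = result.scalar_values()
            for name, tv in truth_pset.scalar_values().items():
                if tv == 0:
                    continue
                rows.append(
                    {
                        "noise_sd": level, "replicate": rep, "parameter": name,
                        "truth": tv, "estimate": est[name],
                        "pct_error": 100.0 * abs(est[name] - tv) / abs(tv),
                        "status": status,
                    }
                )
    return pd.DataFrame(rows)
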