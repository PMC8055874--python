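"""Digital phantoms: synthetic virtual patients for the full pipeline.

No patient MRI ships with this package, so testing calibration, model
selection and evaluation requires synthetic longitudinal datasets with the
same structure: an ellipsoidal "brain" with a CSF core, a gray-matter
shell and a white-matter interior; a tumor seed with a smooth enhancing
core and a non-enhancing rim at the fixed fraction 0.16; visits generated
by running a chosen ground-truth model forward through a standard
chemoradiation schedule; and MRI-like observations derived from the
simulated fields.

The observation model is exactly invertible in the noiseless limit: ADC
encodes the total cell fraction through the inverse of the cellularity
mapping, the enhancement ratio is realized as t1_post = ER * t1_pre, and
tumor masks come from thresholding the noiseless species fields.  The
baseline enhancing profile is kept at or above the mask threshold inside
its support so that reconstructing the initial condition from the emitted
images reproduces the true one bit-for-bit — the property that parameter
recovery experiments rest on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    TISSUE_CSF,
    TISSUE_GRAY,
    TISSUE_WHITE,
    CellularityParams,
    ImageGrid,
    ImagingVisit,
    PatientDataset,
    TumorState,
)
from .errors import InvalidParameterError
from .forward import DomainContext, GrowthParams, SimulationSettings, simulate
from .io import write_nifti
from .mechanics import ElasticityParams
from .therapy import (
    ModelSpec,
    TherapyParams,
    TreatmentSchedule,
    build_standard_schedule,
    make_model_spec,
)


def _default_growth() -> GrowthParams:
    """Ground-truth growth parameters of the default virtual patient.

    Diffusion is higher in white matter than gray, and higher for the
    infiltrative non-enhancing species than the enhancing one; the
    non-enhancing rim proliferates faster, mirroring the view that the
    peritumoral region is the more invasive component.
    """
    return GrowthParams(
        d_e_w=0.05, d_e_g=0.02, d_n_w=0.10, d_n_g=0.04,
        k_p_e=0.04, k_p_n=0.06, theta_e=0.80, theta_n=0.16,
        beta_ne=4.0, beta_en=1.0, lambda1=2.0,
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, ground truth and noise of one virtual patient."""

    grid_shape: tuple[int, int, int] = (64, 64, 8)
    grid_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    brain_semiaxes_mm: tuple[float, float, float] = (28.0, 28.0, 17.5)
    csf_semiaxes_mm: tuple[float, float, float] = (7.0, 7.0, 5.0)
    gray_shell_mm: float = 3.0
    tumor_center_offset_mm: tuple[float, float, float] = (12.0, 0.0, 0.0)
    enhancing_radius_mm: float = 8.0
    rim_width_mm: float = 6.0
    peak_fraction: float = 0.75
    edge_fraction: float = 0.06
    mask_threshold: float = 0.05
    visit_times: tuple[float, ...] = (0.0, 30.0, 90.0, 150.0)
    adc_w: float = 3.0e-3
    adc_min: float = 0.6e-3
    adc_noise_sd: float = 0.03
    intensity_noise_sd: float = 0.02
    t1_baseline: float = 500.0
    seed: int = 0
    schedule_start_day: float = 7.0
    rt_weeks: int = 6
    adjuvant_cycles: int = 6
    model: ModelSpec = field(default_factory=lambda: make_model_spec("two_species", 8))
    growth: GrowthParams = field(default_factory=_default_growth)
    therapy: TherapyParams = field(
        default_factory=lambda: TherapyParams(sf_rt_min=0.97, sf_ct_min=0.98)
    )
    elasticity: ElasticityParams = field(default_factory=ElasticityParams)
    settings: SimulationSettings = field(
        default_factory=lambda: SimulationSettings(dt=2.0, mechanics_stride=5)
    )

    def __post_init__(self) -> None:
        if not (0 < self.peak_fraction <= 1):
            raise InvalidParameterError(f"peak_fraction must be in (0,1], got {self.peak_fraction}")
        if self.edge_fraction < self.mask_threshold:
            raise InvalidParameterError(
                "edge_fraction must be >= mask_threshold so baseline masks are "
                "exactly the seed support"
            )
        if self.adc_noise_sd < 0 or self.intensity_noise_sd < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")
        if 0.0 not in self.visit_times:
            raise InvalidParameterError("visit times must include the baseline t=0")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=self.grid_shape, spacing=self.grid_spacing)

    @property
    def cellularity(self) -> CellularityParams:
        return CellularityParams(adc_w=self.adc_w, adc_min=self.adc_min)

    def schedules(self) -> tuple[TreatmentSchedule, TreatmentSchedule]:
        return build_standard_schedule(
            start_day=self.schedule_start_day,
            weeks=self.rt_weeks,
            adjuvant_cycles=self.adjuvant_cycles,
        )


@dataclass
class GroundTruth:
    """The generating model, its parameters, and the noiseless fields."""

    config: PhantomConfig
    model: ModelSpec
    growth: GrowthParams
    therapy: TherapyParams
    cellularity: CellularityParams
    states: list[TumorState]
    er_field: np.ndarray
    tissue_labels: np.ndarray
    brain_mask: np.ndarray


def _ellipsoid_norm(
    grid: ImageGrid, center: np.ndarray, semiaxes
) -> np.ndarray:
    coords = grid.coordinate_arrays()
    q = np.zeros(grid.shape)
    for a in range(3):
        q += ((coords[a] - center[a]) / semiaxes[a]) ** 2
    return np.sqrt(q)


def make_brain_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Tissue label map and brain mask: CSF core, gray shell, white interior."""
    grid = config.grid
    extent = np.array(grid.shape) * np.array(grid.spacing)
    center = np.array(grid.origin) + extent / 2.0
    for a, name in enumerate("xyz"):
        if config.brain_semiaxes_mm[a] > extent[a] / 2.0:
            raise InvalidParameterError(
                f"brain semi-axis along {name} ({config.brain_semiaxes_mm[a]} mm) "
                f"exceeds the half grid extent ({extent[a] / 2.0} mm)"
            )
    rho = _ellipsoid_norm(grid, center, config.brain_semiaxes_mm)
    brain = rho <= 1.0
    inner_semi = tuple(
        max(s - config.gray_shell_mm, min(grid.spacing)) for s in config.brain_semiaxes_mm
    )
    inner = _ellipsoid_norm(grid, center, inner_semi) <= 1.0
    csf = _ellipsoid_norm(grid, center, config.csf_semiaxes_mm) <= 1.0
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[brain] = TISSUE_WHITE
    labels[brain & ~inner] = TISSUE_GRAY
    labels[brain & csf] = TISSUE_CSF
    return labels, brain


def tumor_seed_state(
    config: PhantomConfig, labels: np.ndarray, brain: np.ndarray
) -> TumorState:
    """Baseline tumor state: quadratic enhancing core, rim at the fixed 0.16.

    The enhancing profile equals ``edge_fraction`` at its support boundary
    (>= mask threshold), so the thresholded mask is exactly the seed ball
    intersected with non-CSF brain.
    """
    grid = config.grid
    extent = np.array(grid.shape) * np.array(grid.spacing)
    center = np.array(grid.origin) + extent / 2.0 + np.array(config.tumor_center_offset_mm)
    coords = grid.coordinate_arrays()
    r = np.sqrt(sum((coords[a] - center[a]) ** 2 for a in range(3)))
    allowed = brain & (labels != TISSUE_CSF)
    core = (r <= config.enhancing_radius_mm) & allowed
    rim = (r > config.enhancing_radius_mm) & (
        r <= config.enhancing_radius_mm + config.rim_width_mm
    ) & allowed
    if not core.any():
        raise InvalidParameterError("tumor seed lies entirely outside usable brain tissue")
    phi_e = np.zeros(grid.shape)
    shape_fn = 1.0 - (r / config.enhancing_radius_mm) ** 2
    phi_e[core] = (
        config.edge_fraction
        + (config.peak_fraction - config.edge_fraction) * shape_fn[core]
    )
    fixed_n = config.cellularity.phi_fixed_nonenhancing
    phi_n = np.where(rim, fixed_n, 0.0)
    if config.model.base == "single":
        return TumorState("single", time=0.0, phi_T=phi_e + phi_n)
    return TumorState("two_species", time=0.0, phi_E=phi_e, phi_N=phi_n)


def enhancement_ratio_profile(config: PhantomConfig, brain: np.ndarray) -> np.ndarray:
    """Radially decreasing ER: 2 at the tumor core, 1 at the rim edge and beyond."""
    grid = config.grid
    extent = np.array(grid.shape) * np.array(grid.spacing)
    center = np.array(grid.origin) + extent / 2.0 + np.array(config.tumor_center_offset_mm)
    coords = grid.coordinate_arrays()
    r = np.sqrt(sum((coords[a] - center[a]) ** 2 for a in range(3)))
    outer = config.enhancing_radius_mm + config.rim_width_mm
    er = 1.0 + np.clip(1.0 - r / outer, 0.0, 1.0)
    return np.where(brain, er, 1.0)


def derive_masks(
    state: TumorState, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Enhancing / non-enhancing masks by thresholding noiseless fields."""
    if state.kind == "single":
        enh = state.phi_T >= threshold
        non = np.zeros_like(enh)
    else:
        enh = state.phi_E >= threshold
        non = (state.phi_N >= threshold) & ~enh
    return enh, non


def synthesize_visits(config: PhantomConfig) -> tuple[PatientDataset, GroundTruth]:
    """Generate one virtual patient and the ground truth behind it.

    Runs the configured ground-truth model forward through the standard
    chemoradiation schedule, then converts each noiseless state to
    MRI-like observations: ADC from the inverted cellularity mapping of the
    total fraction (multiplicative Gaussian noise), T1 pairs realizing the
    prescribed enhancement-ratio profile, and masks thresholded from the
    noiseless species fields.  Deterministic given the seed.
    """
    grid = config.grid
    labels, brain = make_brain_phantom(config)
    initial = tumor_seed_state(config, labels, brain)
    er = enhancement_ratio_profile(config, brain)
    rt, ct = config.schedules()
    ctx = DomainContext(
        grid=grid, brain_mask=brain, tissue_labels=labels,
        er_field=er, elasticity=config.elasticity,
    )
    states = simulate(
        config.model, config.growth, config.therapy, initial,
        rt, ct, config.visit_times, ctx, config.settings,
    )

    rng = np.random.default_rng(config.seed)
    cell = config.cellularity
    visits: list[ImagingVisit] = []
    for state in states:
        total = state.total()
        adc_clean = np.where(
            brain, cell.adc_w - total * (cell.adc_w - cell.adc_min), cell.adc_w
        )
        noise = rng.standard_normal(grid.shape)
        adc = np.maximum(adc_clean * (1.0 + config.adc_noise_sd * noise), 1e-6)
        t1_pre_clean = np.full(grid.shape, config.t1_baseline)
        t1_pre = t1_pre_clean * (
            1.0 + config.intensity_noise_sd * rng.standard_normal(grid.shape)
        )
        t1_post = (er * t1_pre_clean) * (
            1.0 + config.intensity_noise_sd * rng.standard_normal(grid.shape)
        )
        enh, non = derive_masks(state, config.mask_threshold)
        visits.append(
            ImagingVisit(
                grid=grid, time=state.time, adc=adc,
                t1_pre=np.maximum(t1_pre, 1e-6), t1_post=np.maximum(t1_post, 1e-6),
                enhancing_mask=enh, nonenhancing_mask=non,
                brain_mask=brain, tissue_labels=labels,
            )
        )

    dataset = PatientDataset(
        patient_id=f"phantom-{config.seed:04d}", visits=visits,
        rt_schedule=rt, ct_schedule=ct,
    )
    dataset.validate()
    truth = GroundTruth(
        config=config, model=config.model, growth=config.growth,
        therapy=config.therapy, cellularity=cell, states=states,
        er_field=er, tissue_labels=labels, brain_mask=brain,
    )
    return dataset, truth


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Sidecar dump of the generating model: parameters (JSON) + noiseless fields."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = truth.config.grid
    meta = {
        "model": {
            "base": truth.model.base,
            "combination_id": truth.model.coupling.combination_id,
            "proliferation": truth.model.proliferation,
        },
        "growth": {
            k: v for k, v in asdict(truth.growth).items() if np.isscalar(v)
        },
        "therapy": asdict(truth.therapy),
        "cellularity": asdict(truth.cellularity),
        "visit_times": list(truth.config.visit_times),
        "seed": truth.config.seed,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    for state in truth.states:
        tag = f"t{state.time:07.2f}"
        if state.kind == "single":
            write_nifti(state.phi_T, grid, outdir / f"truth_phi_T_{tag}.nii.gz")
        else:
            write_nifti(state.phi_E, grid, outdir / f"truth_phi_E_{tag}.nii.gz")
            write_nifti(state.phi_N, grid, outdir / f"truth_phi_N_{tag}.nii.gz")
    write_nifti(truth.er_field, grid, outdir / "truth_er.nii.gz")
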