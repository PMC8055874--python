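"""Domain types and imaging-to-model mappings.

The package works on a fixed 3-D image grid shared by every volume of a
patient: ADC maps (mm^2/s) from diffusion-weighted MRI, pre/post-contrast
T1-weighted intensities, tumor masks, and a white/gray/CSF tissue label
map.  The central mapping converts ADC to a tumor cell volume fraction

    phi(x) = (ADC_w - ADC(x)) / (ADC_w - ADC_min)

where ``ADC_w`` is the ADC of free water and ``ADC_min`` the minimum ADC
measured in tumor; higher cellularity restricts water mobility and lowers
ADC, so phi decreases monotonically with ADC.  Values are clamped to
[0, 1] because phi is a volume fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    GridMismatchError,
    InvalidParameterError,
    InvariantViolationError,
)

# Tissue label codes shared across the package.
TISSUE_BACKGROUND = 0
TISSUE_WHITE = 1
TISSUE_GRAY = 2
TISSUE_CSF = 3

SpeciesKind = Literal["single", "two_species"]


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3-D voxel grid.

    ``spacing`` is in mm (in-plane usually isotropic, slice spacing often
    larger); ``origin`` is the world coordinate of voxel (0, 0, 0).  World
    coordinates are ``origin + index * spacing`` (0-based indices, no
    resampling anywhere in the package).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise InvalidParameterError("grid shape/spacing/origin must be 3-vectors")
        if any(int(n) < 1 for n in self.shape):
            raise InvalidParameterError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(h <= 0 for h in self.spacing):
            raise InvalidParameterError(f"grid spacing must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(h) for h in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (axis-aligned)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of every voxel, one array per axis."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def matches(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class CellularityParams:
    """Parameters of the ADC-to-cell-fraction mapping.

    ``adc_w`` defaults to 3.0e-3 mm^2/s (free water near body temperature).
    ``adc_min`` defaults to the per-patient minimum ADC over tumor voxels at
    baseline when constructed via :func:`cellularity_params_for_dataset`;
    here a fixed default is provided for direct use.  The non-enhancing
    clinical tumor volume is assigned the fixed fraction
    ``phi_fixed_nonenhancing`` (0.16) because its cell density is not
    reliably readable from ADC.
    """

    adc_w: float = 3.0e-3
    adc_min: float = 0.6e-3
    phi_fixed_nonenhancing: float = 0.16

    def __post_init__(self) -> None:
        if not (self.adc_w > self.adc_min > 0):
            raise InvalidParameterError(
                f"require adc_w > adc_min > 0, got adc_w={self.adc_w}, adc_min={self.adc_min}"
            )
        if not (0 < self.phi_fixed_nonenhancing < 1):
            raise InvalidParameterError(
                f"phi_fixed_nonenhancing must be in (0,1), got {self.phi_fixed_nonenhancing}"
            )


@dataclass
class ImagingVisit:
    """One co-registered imaging session.

    All fields live on the same :class:`ImageGrid`.  The enhancing mask is
    the contrast-enhancing tumor on post-contrast T1; the non-enhancing
    mask is the non-enhancing, T2-hyperintense clinical tumor volume; the
    two are disjoint by definition.
    """

    grid: ImageGrid
    time: float  # days since baseline
    adc: np.ndarray  # mm^2/s
    t1_pre: np.ndarray
    t1_post: np.ndarray
    enhancing_mask: np.ndarray
    nonenhancing_mask: np.ndarray
    brain_mask: np.ndarray
    tissue_labels: np.ndarray

    def validate(self) -> None:
        if self.time < 0:
            raise InvariantViolationError(f"visit time must be >= 0, got {self.time}")
        for name in ("adc", "t1_pre", "t1_post", "enhancing_mask",
                     "nonenhancing_mask", "brain_mask", "tissue_labels"):
            arr = getattr(self, name)
            if tuple(arr.shape) != self.grid.shape:
                raise GridMismatchError(
                    f"field '{name}' has shape {arr.shape}, grid is {self.grid.shape}"
                )
        enh = self.enhancing_mask.astype(bool)
        non = self.nonenhancing_mask.astype(bool)
        brain = self.brain_mask.astype(bool)
        if np.any(enh & non):
            raise InvariantViolationError(
                "enhancing and non-enhancing masks overlap "
                f"({int(np.sum(enh & non))} voxels)"
            )
        if np.any(enh & ~brain) or np.any(non & ~brain):
            raise InvariantViolationError("tumor masks extend outside the brain mask")
        if np.any(~np.isfinite(self.adc[brain])) or np.any(self.adc[brain] <= 0):
            raise InvariantViolationError("ADC must be finite and > 0 inside the brain mask")

    @property
    def union_tumor_mask(self) -> np.ndarray:
        return self.enhancing_mask.astype(bool) | self.nonenhancing_mask.astype(bool)


@dataclass
class TumorState:
    """Tumor volume-fraction field(s) at one time.

    ``single`` carries one field ``phi_T``; ``two_species`` carries the
    enhancing fraction ``phi_E`` and the non-enhancing (infiltrative)
    fraction ``phi_N``.
    """

    kind: SpeciesKind
    time: float
    phi_T: np.ndarray | None = None
    phi_E: np.ndarray | None = None
    phi_N: np.ndarray | None = None

    def total(self) -> np.ndarray:
        if self.kind == "single":
            assert self.phi_T is not None
            return self.phi_T
        assert self.phi_E is not None and self.phi_N is not None
        return self.phi_E + self.phi_N

    def fields(self) -> tuple[np.ndarray, ...]:
        if self.kind == "single":
            assert self.phi_T is not None
            return (self.phi_T,)
        assert self.phi_E is not None and self.phi_N is not None
        return (self.phi_E, self.phi_N)

    def copy(self) -> "TumorState":
        return TumorState(
            kind=self.kind,
            time=self.time,
            phi_T=None if self.phi_T is None else self.phi_T.copy(),
            phi_E=None if self.phi_E is None else self.phi_E.copy(),
            phi_N=None if self.phi_N is None else self.phi_N.copy(),
        )

    def validate(self, brain_mask: np.ndarray | None = None) -> None:
        for f in self.fields():
            if not np.all(np.isfinite(f)):
                raise InvariantViolationError("tumor state contains non-finite values")
            if f.min() < -1e-12 or f.max() > 1 + 1e-12:
                raise InvariantViolationError(
                    f"volume fractions outside [0,1]: min={f.min()}, max={f.max()}"
                )
            if brain_mask is not None and np.any(np.abs(f[~brain_mask.astype(bool)]) > 1e-12):
                raise InvariantViolationError("tumor fractions nonzero outside the brain mask")


@dataclass
class PatientDataset:
    """One patient's longitudinal visits plus the treatment schedules."""

    patient_id: str
    visits: list[ImagingVisit]
    rt_schedule: "TreatmentSchedule | None" = None  # noqa: F821 (therapy module)
    ct_schedule: "TreatmentSchedule | None" = None  # noqa: F821

    def validate(self) -> None:
        if len(self.visits) < 2:
            raise InvariantViolationError(
                f"dataset needs >= 2 visits (baseline + follow-up), got {len(self.visits)}"
            )
        times = [v.time for v in self.visits]
        if times[0] != 0:
            raise InvariantViolationError(f"first visit must be baseline at t=0, got {times[0]}")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise InvariantViolationError(f"visit times must strictly increase, got {times}")
        grid = self.visits[0].grid
        for v in self.visits:
            if not grid.matches(v.grid):
                raise GridMismatchError("visits do not share one image grid")
            v.validate()

    @property
    def grid(self) -> ImageGrid:
        return self.visits[0].grid

    @property
    def baseline(self) -> ImagingVisit:
        return self.visits[0]


# ---------------------------------------------------------------------------
# Imaging-to-model mappings
# ---------------------------------------------------------------------------

def estimate_cell_fraction(
    adc: np.ndarray, params: CellularityParams, mask: np.ndarray
) -> np.ndarray:
    """Map ADC to tumor cell volume fraction inside ``mask``.

    Returns ``(adc_w - adc) / (adc_w - adc_min)`` clamped to [0, 1] inside
    the mask and exactly zero outside.  ADC above the free-water value maps
    to 0 (fractions must stay physical).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("estimate_cell_fraction called with an empty mask", stacklevel=2)
        return np.zeros(adc.shape, dtype=float)
    vals = adc[mask]
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise InvalidParameterError("ADC must be finite and > 0 inside the mask")
    phi = np.zeros(adc.shape, dtype=float)
    phi[mask] = np.clip((params.adc_w - vals) / (params.adc_w - params.adc_min), 0.0, 1.0)
    return phi


def compute_enhancement_ratio(
    t1_post: np.ndarray, t1_pre: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Post/pre-contrast T1 intensity ratio, clamped to [1, 2].

    The enhancement ratio (ER) acts as a perfusion surrogate: well-perfused
    tumor enhances strongly (ER near 2).  Outside ``mask`` the ratio is set
    to 1 (no enhancement).
    """
    mask = np.asarray(mask, dtype=bool)
    n_bad = int(np.sum(mask & (t1_pre <= 0)))
    if n_bad:
        raise InvalidParameterError(
            f"t1_pre must be > 0 inside the mask; {n_bad} voxel(s) violate this"
        )
    er = np.ones(t1_post.shape, dtype=float)
    er[mask] = np.clip(t1_post[mask] / t1_pre[mask], 1.0, 2.0)
    return er


def _linear_decay_profile(
    enhancing_mask: np.ndarray,
    nonenhancing_mask: np.ndarray,
    grid: ImageGrid,
    interface_value: np.ndarray | float,
    periphery_value: float,
) -> np.ndarray:
    """Optional spatially-decaying non-enhancing cellularity.

    Interpolates linearly (in normalized distance) from the value at the
    enhancing interface to ``periphery_value`` at the outer edge of the
    non-enhancing region.
    """
    enh = enhancing_mask.astype(bool)
    non = nonenhancing_mask.astype(bool)
    out = np.zeros(enh.shape, dtype=float)
    if not non.any():
        return out
    sampling = grid.spacing
    # Distance to the enhancing region and to the exterior of the union.
    if enh.any():
        d_in = ndimage.distance_transform_edt(~enh, sampling=sampling)
    else:
        d_in = np.zeros(enh.shape)
    union = enh | non
    d_out = ndimage.distance_transform_edt(union, sampling=sampling)
    frac = np.zeros(enh.shape)
    denom = d_in + d_out
    ok = non & (denom > 0)
    frac[ok] = d_in[ok] / denom[ok]
    if np.isscalar(interface_value):
        iv = float(interface_value)  # type: ignore[arg-type]
    else:
        # Use the mean enhancing-boundary fraction as the interface value.
        iv_arr = np.asarray(interface_value)
        boundary = enh & ~ndimage.binary_erosion(enh)
        iv = float(iv_arr[boundary].mean()) if boundary.any() else periphery_value
    out[non] = iv * (1 - frac[non]) + periphery_value * frac[non]
    return out


def assign_initial_state(
    visit: ImagingVisit,
    kind: SpeciesKind,
    params: CellularityParams,
    *,
    nonenhancing_mode: Literal["fixed", "linear_decay"] = "fixed",
    periphery_value: float = 0.02,
) -> TumorState:
    """Build the model state for a visit from its masks and ADC.

    Single species: phi_T is ADC-derived inside the enhancing mask, the
    fixed non-enhancing fraction (0.16 by default) inside the non-enhancing
    clinical tumor volume, and zero elsewhere.  Two species: phi_E is the
    ADC-derived fraction restricted to the enhancing mask; phi_N is the
    fixed fraction on the non-enhancing mask; the two supports are disjoint.

    ``nonenhancing_mode="linear_decay"`` replaces the flat non-enhancing
    assignment with a profile decaying from the enhancing interface to
    ``periphery_value`` (off by default).
    """
    enh = visit.enhancing_mask.astype(bool)
    non = visit.nonenhancing_mask.astype(bool)
    if np.any(enh & non):
        raise InvariantViolationError("enhancing and non-enhancing masks overlap")
    phi_enh = estimate_cell_fraction(visit.adc, params, enh) if enh.any() else np.zeros(
        visit.grid.shape
    )
    if nonenhancing_mode == "fixed":
        phi_non = np.where(non, params.phi_fixed_nonenhancing, 0.0)
    elif nonenhancing_mode == "linear_decay":
        phi_non = _linear_decay_profile(
            enh, non, visit.grid, params.phi_fixed_nonenhancing, periphery_value
        )
    else:
        raise InvalidParameterError(f"unknown nonenhancing_mode {nonenhancing_mode!r}")

    if kind == "single":
        phi_t = phi_enh + phi_non
        return TumorState(kind="single", time=visit.time, phi_T=phi_t)
    if kind == "two_species":
        return TumorState(kind="two_species", time=visit.time, phi_E=phi_enh, phi_N=phi_non)
    raise InvalidParameterError(f"unknown model kind {kind!r}")


def dwi_cellularity(visit: ImagingVisit, params: CellularityParams) -> np.ndarray:
    """ADC-derived cell fraction over the whole brain mask.

    This is the voxel-wise measurement the calibration residuals compare
    against: DWI senses total cellularity wherever brain tissue is present,
    independent of the radiological region assignment.
    """
    return estimate_cell_fraction(visit.adc, params, visit.brain_mask)


def measured_cellularity(
    visit: ImagingVisit,
    params: CellularityParams,
    *,
    nonenhancing_mode: Literal["fixed", "linear_decay"] = "fixed",
) -> np.ndarray:
    """Region-assigned measured cellularity map (for display and metrics).

    ADC-derived inside the enhancing region, the fixed value inside the
    non-enhancing clinical tumor volume, zero elsewhere.
    """
    state = assign_initial_state(
        visit, "single", params, nonenhancing_mode=nonenhancing_mode
    )
    return state.phi_T  # type: ignore[return-value]


def cellularity_params_for_dataset(
    dataset: PatientDataset,
    *,
    adc_w: float = 3.0e-3,
    adc_min: float | None = None,
    phi_fixed_nonenhancing: float = 0.16,
    adc_min_scope: Literal["baseline", "all_visits"] = "baseline",
) -> CellularityParams:
    """Cellularity parameters with a per-patient ``adc_min``.

    ``adc_min`` defaults to the minimum ADC over tumor voxels at baseline
    (``adc_min_scope="baseline"``) or over all visits.  An explicit value
    overrides both.
    """
    if adc_min is None:
        visits: Sequence[ImagingVisit]
        visits = dataset.visits[:1] if adc_min_scope == "baseline" else dataset.visits
        vals = []
        for v in visits:
            m = v.union_tumor_mask
            if m.any():
                vals.append(float(v.adc[m].min()))
        if not vals:
            raise InvalidParameterError("no tumor voxels found to derive adc_min from")
        adc_min = min(vals)
    return CellularityParams(
        adc_w=adc_w, adc_min=adc_min, phi_fixed_nonenhancing=phi_fixed_nonenhancing
    )
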