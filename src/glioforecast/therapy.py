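"""Treatment schedules and spatially-varying treatment efficacy.

Radiotherapy (RT) and chemotherapy (CT) act as instantaneous multiplicative
reductions of the tumor fraction at each treatment day:

    phi_post = phi_pre * SF_RT * SF_CT

where each surviving fraction SF lies between a calibrated minimum
(SF_min) and 1 and may vary in space through one of four coupling
approaches:

    C1  efficacy falls as occupancy phi/theta rises (dense, slowly
        proliferating tumor is less susceptible):
        SF = SF_min + (1 - SF_min) * (1 - phi/theta)
    C2  efficacy falls in poorly perfused tissue, via the enhancement
        ratio ER in [1, 2]:
        SF = SF_min + ((1 - SF_min)/0.5) * (1/ER - 0.5)
    C3  linear variant of C2:
        SF = SF_min + ((1 - SF_min)/0.5) * (1 - ER/2)
    C4  uniform efficacy: SF = SF_min everywhere.

Ten (RT, CT) approach combinations are considered, and together with the
two base models (single / two species) and the two proliferation
parameterizations (global scalar / voxel field) they form a family of 40
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np

from .errors import InvalidParameterError, InvariantViolationError

Approach = Literal["C1", "C2", "C3", "C4"]
TherapyKind = Literal["RT", "CT"]

#: The ten (RT approach, CT approach) pairs, ids 1-10 in order:
#: 1-3 vary only RT (CT uniform), 4-6 vary only CT (RT uniform),
#: 7-10 apply the same approach to both therapies.
_COMBINATIONS: tuple[tuple[Approach, Approach], ...] = (
    ("C1", "C4"), ("C2", "C4"), ("C3", "C4"),
    ("C4", "C1"), ("C4", "C2"), ("C4", "C3"),
    ("C1", "C1"), ("C2", "C2"), ("C3", "C3"), ("C4", "C4"),
)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Event days (days since baseline) for one therapy.

    Dose metadata (Gy for RT, mg/kg for CT) is informational only; treatment
    efficacy enters the model exclusively through the surviving fractions.
    """

    kind: TherapyKind
    days: tuple[float, ...]
    dose: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise InvariantViolationError(
                f"{self.kind} schedule days must be sorted and unique: {days}"
            )
        if self.dose is not None and len(self.dose) != len(days):
            raise InvalidParameterError("dose list length must match event days")
        object.__setattr__(self, "days", days)

    def __len__(self) -> int:
        return len(self.days)

    @property
    def total_dose(self) -> float | None:
        return None if self.dose is None else float(sum(self.dose))


@dataclass(frozen=True)
class CouplingSpec:
    """One of the ten enumerated (RT, CT) coupling combinations."""

    rt_approach: Approach
    ct_approach: Approach
    combination_id: int

    def __post_init__(self) -> None:
        if not (1 <= self.combination_id <= 10):
            raise InvalidParameterError(f"combination id must be 1-10, got {self.combination_id}")
        expected = _COMBINATIONS[self.combination_id - 1]
        if (self.rt_approach, self.ct_approach) != expected:
            raise InvariantViolationError(
                f"combination {self.combination_id} is RT:{expected[0]}/CT:{expected[1]}, "
                f"got RT:{self.rt_approach}/CT:{self.ct_approach}"
            )


@dataclass(frozen=True)
class TherapyParams:
    """Minimum surviving fractions for RT and CT (shared across species)."""

    sf_rt_min: float = 0.8
    sf_ct_min: float = 0.8

    def __post_init__(self) -> None:
        for name, v in (("sf_rt_min", self.sf_rt_min), ("sf_ct_min", self.sf_ct_min)):
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the 40-model family."""

    base: Literal["single", "two_species"]
    coupling: CouplingSpec
    proliferation: Literal["global", "field"]

    def __post_init__(self) -> None:
        if self.base not in ("single", "two_species"):
            raise InvalidParameterError(f"unknown base model {self.base!r}")
        if self.proliferation not in ("global", "field"):
            raise InvalidParameterError(f"unknown proliferation mode {self.proliferation!r}")

    @property
    def model_id(self) -> str:
        return f"{self.base}-c{self.coupling.combination_id}-{self.proliferation}"


def enumerate_coupling_combinations() -> list[CouplingSpec]:
    """The ten coupling combinations, ids 1-10, deterministic order."""
    return [
        CouplingSpec(rt_approach=rt, ct_approach=ct, combination_id=i + 1)
        for i, (rt, ct) in enumerate(_COMBINATIONS)
    ]


def build_model_family() -> list[ModelSpec]:
    """All 40 models: {single, two_species} x 10 combinations x {global, field}."""
    return [
        ModelSpec(base=base, coupling=combo, proliferation=prolif)
        for base, combo, prolif in product(
            ("single", "two_species"),
            enumerate_coupling_combinations(),
            ("global", "field"),
        )
    ]


def make_model_spec(
    base: Literal["single", "two_species"],
    combination_id: int,
    proliferation: Literal["global", "field"] = "global",
) -> ModelSpec:
    """Convenience constructor selecting a family member by ids."""
    combo = enumerate_coupling_combinations()[combination_id - 1]
    return ModelSpec(base=base, coupling=combo, proliferation=proliferation)


def surviving_fraction(
    approach: Approach,
    sf_min: float,
    *,
    phi: np.ndarray | None = None,
    theta: float | None = None,
    er: np.ndarray | None = None,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-wise surviving fraction for one therapy event.

    ``phi``/``theta`` feed approach C1 (occupancy), ``er`` feeds C2/C3
    (perfusion surrogate).  Where ``support`` (typically phi > 0) is False
    the field is set to 1: treatment of empty voxels is vacuous.
    """
    if not (0 < sf_min <= 1):
        raise InvalidParameterError(f"sf_min must be in (0, 1], got {sf_min}")
    if approach == "C1":
        if phi is None or theta is None:
            raise InvalidParameterError("approach C1 requires phi and theta")
        occ = np.asarray(phi, dtype=float) / float(theta)
        if occ.max(initial=0.0) > 1 + 1e-9:
            raise InvariantViolationError(
                f"phi exceeds theta (max occupancy {occ.max():.4f})"
            )
        sf = sf_min + (1 - sf_min) * (1 - np.clip(occ, 0.0, 1.0))
    elif approach in ("C2", "C3"):
        if er is None:
            raise InvalidParameterError(f"approach {approach} requires the ER field")
        er = np.asarray(er, dtype=float)
        if er.min(initial=1.0) < 1 - 1e-9 or er.max(initial=1.0) > 2 + 1e-9:
            raise InvariantViolationError(
                f"ER outside [1,2]: min={er.min():.4f}, max={er.max():.4f} (clamp upstream)"
            )
        er = np.clip(er, 1.0, 2.0)
        if approach == "C2":
            sf = sf_min + ((1 - sf_min) / 0.5) * (1.0 / er - 0.5)
        else:
            sf = sf_min + ((1 - sf_min) / 0.5) * (1.0 - er / 2.0)
    elif approach == "C4":
        ref = phi if phi is not None else er
        if ref is None:
            raise InvalidParameterError("approach C4 needs phi or er for the field shape")
        sf = np.full(np.asarray(ref).shape, sf_min, dtype=float)
    else:
        raise InvalidParameterError(f"unknown coupling approach {approach!r}")

    sf = np.clip(sf, sf_min, 1.0)
    if support is not None:
        sf = np.where(np.asarray(support, dtype=bool), sf, 1.0)
    return sf


def apply_treatment(state, sf_rt: np.ndarray, sf_ct: np.ndarray):
    """Instantaneous treatment: multiply every species by SF_RT * SF_CT."""
    for name, sf in (("SF_RT", sf_rt), ("SF_CT", sf_ct)):
        sf = np.asarray(sf)
        if sf.min(initial=1.0) < -1e-12 or sf.max(initial=0.0) > 1 + 1e-12:
            raise InvariantViolationError(f"{name} outside [0,1]")
    factor = np.asarray(sf_rt, dtype=float) * np.asarray(sf_ct, dtype=float)
    out = state.copy()
    if out.kind == "single":
        out.phi_T = np.maximum(out.phi_T * factor, 0.0)
    else:
        out.phi_E = np.maximum(out.phi_E * factor, 0.0)
        out.phi_N = np.maximum(out.phi_N * factor, 0.0)
    return out


def build_standard_schedule(
    start_day: float = 0.0,
    weeks: int = 6,
    fraction_gy: float = 2.0,
    *,
    concurrent_ct_dose: float = 75.0,
    adjuvant_cycles: int = 6,
    adjuvant_dose: float = 150.0,
    adjuvant_gap_days: float = 28.0,
    adjuvant_cycle_days: float = 28.0,
) -> tuple[TreatmentSchedule, TreatmentSchedule]:
    """Standard-of-care chemoradiation schedule.

    RT: one fraction (default 2 Gy) per weekday for ``weeks`` weeks (default
    6, i.e. 30 fractions / 60 Gy), starting on a Monday at ``start_day``.
    CT: temozolomide daily (7 days/week) over the RT window, then adjuvant
    cycles of 5 consecutive days at the start of each 28-day cycle,
    beginning ``adjuvant_gap_days`` after the concurrent window ends.
    """
    if weeks < 1:
        raise InvalidParameterError(f"weeks must be >= 1, got {weeks}")
    rt_days = [
        start_day + 7 * w + d for w in range(weeks) for d in range(5)
    ]
    rt = TreatmentSchedule(
        kind="RT", days=tuple(rt_days), dose=tuple([fraction_gy] * len(rt_days))
    )
    concurrent_end = start_day + 7 * weeks  # exclusive
    ct_days = [start_day + d for d in range(int(7 * weeks))]
    adjuvant_start = concurrent_end + adjuvant_gap_days
    for c in range(adjuvant_cycles):
        cycle_start = adjuvant_start + c * adjuvant_cycle_days
        ct_days.extend(cycle_start + d for d in range(5))
    doses = [concurrent_ct_dose] * int(7 * weeks) + [adjuvant_dose] * (5 * adjuvant_cycles)
    ct = TreatmentSchedule(kind="CT", days=tuple(ct_days), dose=tuple(doses))
    return rt, ct
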