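"""Model selection (AIC) and error metrics for fits and forecasts.

Global metrics compare size and overlap (signed percent volume error,
Dice coefficient); local metrics compare voxel values (Pearson and Lin's
concordance correlation coefficients); rank agreement across visits uses
Kendall's tau-b.  Model selection ranks family members by the mean
Gaussian-residual AIC across patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CellularityParams,
    ImageGrid,
    PatientDataset,
    TumorState,
    dwi_cellularity,
)
from .errors import GridMismatchError, InvalidParameterError, UndefinedMetricError


def compute_aic(sse: float, n_obs: int, n_params: int) -> float:
    """Gaussian-residual AIC: n ln(SSE/n) + 2 (p + 1).

    The +1 counts the residual variance as an estimated parameter.  A zero
    SSE would send the criterion to -infinity; callers must floor it.
    """
    if sse <= 0:
        raise InvalidParameterError(
            "AIC undefined for sse <= 0; add a small epsilon floor to the SSE"
        )
    if not (n_obs > n_params >= 1):
        raise InvalidParameterError(
            f"require n_obs > n_params >= 1, got n_obs={n_obs}, n_params={n_params}"
        )
    return n_obs * math.log(sse / n_obs) + 2 * (n_params + 1)


def compute_aicc(sse: float, n_obs: int, n_params: int) -> float:
    """Small-sample corrected AIC (optional alternative criterion)."""
    k = n_params + 1
    aic = compute_aic(sse, n_obs, n_params)
    if n_obs - k - 1 <= 0:
        raise InvalidParameterError("AICc undefined: n_obs too small for the parameter count")
    return aic + 2 * k * (k + 1) / (n_obs - k - 1)


@dataclass(frozen=True)
class ModelScore:
    model_id: str
    n_params: int
    per_patient_aic: tuple[float, ...]
    mean_aic: float
    rank: int


def rank_models(
    aic_by_model: Mapping[str, Sequence[float]],
    n_params: Mapping[str, int],
) -> list[ModelScore]:
    """Rank family members by mean AIC across patients (ascending).

    Ties break toward fewer parameters, then lexicographic model id.
    Models with any non-finite AIC are excluded with a warning.
    """
    entries = []
    for model_id, aics in aic_by_model.items():
        aics = tuple(float(a) for a in aics)
        if not all(np.isfinite(aics)):
            warnings.warn(f"model {model_id} excluded: non-finite AIC", stacklevel=2)
            continue
        entries.append((float(np.mean(aics)), n_params[model_id], model_id, aics))
    entries.sort()
    return [
        ModelScore(model_id=mid, n_params=npar, per_patient_aic=aics,
                   mean_aic=mean, rank=i + 1)
        for i, (mean, npar, mid, aics) in enumerate(entries)
    ]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def percent_volume_error(pred_volume: float, meas_volume: float) -> float:
    """Signed percent error 100 (pred - meas)/meas."""
    if meas_volume <= 0:
        raise UndefinedMetricError("percent volume error undefined for zero measured volume")
    return 100.0 * (pred_volume - meas_volume) / meas_volume


def voxel_agreement(
    pred_field: np.ndarray, meas_field: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """(PCC, CCC) over in-mask voxels.

    CCC is Lin's concordance 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)
    with population moments; |CCC| <= |PCC| always.
    """
    m = np.asarray(mask, dtype=bool)
    x = np.asarray(pred_field, dtype=float)[m]
    y = np.asarray(meas_field, dtype=float)[m]
    if x.size < 3:
        raise UndefinedMetricError(f"need >= 3 in-mask voxels, got {x.size}")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    for name, v in (("predicted", sx2), ("measured", sy2)):
        if v == 0:
            raise UndefinedMetricError(f"{name} field has zero variance in the mask")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    pcc = sxy / math.sqrt(sx2 * sy2)
    ccc = 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    return float(pcc), float(ccc)


def kcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall rank correlation (tau-b, tie corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InvalidParameterError("kcc needs two equal-length sequences of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError("kcc undefined when either input is all ties")
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def cell_count(state: TumorState, grid: ImageGrid) -> float:
    """Total cellularity: sum of fractions times voxel volume (relative units)."""
    return float(state.total().sum()) * grid.voxel_volume


def _predicted_masks(state: TumorState, threshold: float):
    if state.kind == "single":
        enh = state.phi_T >= threshold
        non = np.zeros_like(enh)
    else:
        enh = state.phi_E >= threshold
        non = (state.phi_N >= threshold) & ~enh
    return enh, non


def evaluate(
    predicted_states: Sequence[TumorState],
    dataset: PatientDataset,
    *,
    cellularity: CellularityParams | None = None,
    threshold: float = 0.05,
    time_tol: float = 1e-6,
) -> pd.DataFrame:
    """Full error report for predicted states against measured visits.

    Predicted states are matched to visits by time.  Per visit and region
    (enhancing / non-enhancing where the model resolves species, plus the
    union): percent volume error and Dice between the thresholded
    prediction and the measured mask.  Per visit: PCC and CCC of the
    predicted total cell fraction against the DWI-derived fraction over
    the union of measured and predicted tumor masks.  Per dataset: Kendall tau of predicted-vs-measured enhancing
    volumes and cell counts across visits (when >= 2 visits align).

    Long format: columns (visit_time, region, metric, value).
    """
    cellularity = cellularity or CellularityParams()
    voxvol = dataset.grid.voxel_volume
    rows: list[dict] = []
    aligned: list[tuple[TumorState, object]] = []
    for state in predicted_states:
        match = [v for v in dataset.visits if abs(v.time - state.time) <= time_tol]
        if match:
            aligned.append((state, match[0]))
    if not aligned:
        raise InvalidParameterError("no predicted state aligns with a measured visit time")

    vol_pred, vol_meas, cc_pred, cc_meas = [], [], [], []
    for state, visit in aligned:
        meas_enh = visit.enhancing_mask.astype(bool)
        meas_non = visit.nonenhancing_mask.astype(bool)
        pred_enh, pred_non = _predicted_masks(state, threshold)
        regions = [("total", pred_enh | pred_non, meas_enh | meas_non)]
        if state.kind == "two_species":
            regions = [
                ("enhancing", pred_enh, meas_enh),
                ("nonenhancing", pred_non, meas_non),
            ] + regions
        for region, pm, mm in regions:
            rows.append(
                {"visit_time": visit.time, "region": region, "metric": "dice",
                 "value": dice(pm, mm)}
            )
            if mm.any():
                rows.append(
                    {"visit_time": visit.time, "region": region,
                     "metric": "percent_volume_error",
                     "value": percent_volume_error(pm.sum() * voxvol, mm.sum() * voxvol)}
                )
        meas_map = dwi_cellularity(visit, cellularity)
        union = meas_enh | meas_non | pred_enh | pred_non
        try:
            pcc, ccc = voxel_agreement(state.total(), meas_map, union)
            rows.append({"visit_time": visit.time, "region": "total",
                         "metric": "pcc", "value": pcc})
            rows.append({"visit_time": visit.time, "region": "total",
                         "metric": "ccc", "value": ccc})
        except UndefinedMetricError as exc:
            warnings.warn(f"voxel agreement skipped at t={visit.time}: {exc}", stacklevel=2)
        vol_pred.append(float(pred_enh.sum()) * voxvol)
        vol_meas.append(float(meas_enh.sum()) * voxvol)
        field = state.phi_E if state.kind == "two_species" else state.phi_T
        cc_pred.append(float(field[pred_enh].sum()) * voxvol)
        cc_meas.append(float(meas_map[meas_enh].sum()) * voxvol)

    if len(aligned) >= 2:
        for metric, p, m in (
            ("kcc_enhancing_volume", vol_pred, vol_meas),
            ("kcc_enhancing_cell_count", cc_pred, cc_meas),
        ):
            try:
                rows.append(
                    {"visit_time": np.nan, "region": "enhancing",
                     "metric": metric, "value": kcc(p, m)}
                )
            except UndefinedMetricError as exc:
                warnings.warn(f"{metric} skipped: {exc}", stacklevel=2)
    return pd.DataFrame(rows)
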