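# glioforecast

Image-driven forecasting of high-grade glioma response to chemoradiation.

High-grade gliomas respond very unevenly to the standard course of
radiotherapy plus temozolomide, and radiological response assessment only
labels progression months after the fact.  `glioforecast` takes the
opposite route: it calibrates a patient-specific, biologically-based
mathematical model of tumor growth and treatment response to that
patient's own longitudinal MRI, then runs the model forward to forecast
*where* and *how much* tumor will be present at future visits.  It is a
research library for computational oncologists working with longitudinal
multiparametric MRI (contrast-enhanced T1, T2-FLAIR, diffusion-weighted
imaging) of unresected or partially resected disease.

## The model

Tumor burden is a volume-fraction field on the image grid.  Cellularity is
read from the apparent diffusion coefficient,

    φ(x̄, t) = (ADC_w − ADC(x̄, t)) / (ADC_w − ADC_min),

and evolved by a family of mechanically-coupled reaction–diffusion models.
The single-species model tracks the total fraction φ_T:

    ∂φ_T/∂t = ∇·(D_T ∇φ_T) + k_pT φ_T (1 − φ_T/θ_T),

while the two-species model splits the contrast-enhancing (φ_E) and
non-enhancing, T2-hyperintense (φ_N) compartments into competing species
with couplings β_NE = 4, β_EN = 1 and fixed θ_N = 0.16.  Tissue stress
inhibits invasion: the displacement u driven by ∇φ solves the linear
elastic equilibrium ∇·(G∇u) + ∇[G/(1−2ν)](∇·u) = λ₂∇φ with a rigid skull,
and the von Mises stress damps diffusion as D = D₀ exp(−λ₁ σ_vm).
Radiotherapy and chemotherapy act as instantaneous events
φ⁺ = φ⁻·SF_RT·SF_CT, with four ways to spatialize each surviving fraction
(by cell density, by the enhancement ratio ER = T1_post/T1_pre in two
variants, or uniformly) combined into ten (RT, CT) pairings.  Two base
models × ten pairings × {global, voxel-field} proliferation give a
40-member family; free parameters are fit per patient by bounded damped
least squares against voxel-wise cellularity at the calibration visits,
and the family member with the lowest mean AIC across patients is
selected.  Forecast quality is scored globally (percent volume error,
Dice) and locally (Pearson and Lin concordance correlations, Kendall
rank correlation across visits).

Because no patient images are distributed, the package includes a digital
phantom generator (`glioforecast.phantom`) that synthesizes virtual
patients — anatomy, nested tumor masks, ADC, T1 pairs, schedules — from a
known ground-truth model, making the whole pipeline testable end to end.
See `docs/methods.md` for assumptions, parameter defaults, and numerics.

## Worked example

`examples/04_calibrate_and_forecast.py` builds a noisy 32×32×4 virtual
patient from the two-species ground truth, calibrates the generating
model class on the baseline and 1-month visits only (scenario 2), and
forecasts the held-out 3-month visit:

```
calibrated 10 parameters against 1455 voxel residuals
SSE 1.2260, converged=True, 32 residual evaluations
parameter     truth  estimate  error %
k_p_e        0.0400    0.0325    18.76
k_p_n        0.0600    0.0636     5.98
theta_e      0.8000    1.0000    25.00
d_e_w        0.0500    0.0419    16.19
d_e_g        0.0200    0.0000   100.00
d_n_w        0.1000    0.1100    10.00
d_n_g        0.0400    0.0429     7.31
lambda1      2.0000    0.0000   100.00
sf_rt_min    0.9700    0.9855     1.59
sf_ct_min    0.9800    0.9642     1.61

3-month forecast scores (prediction never saw this visit):
metric          ccc   dice    pcc  percent_volume_error
region
enhancing       NaN  0.955    NaN                -1.786
nonenhancing    NaN  0.959    NaN                 7.763
total         0.771  0.967  0.839                 6.783
```

The numbers tell a typical inverse-problem story: with one noisy
follow-up, weakly identified parameters (the stress coupling λ₁ and the
gray-matter diffusion of the enhancing species, which barely expresses
itself in 30 days) collapse to a bound, yet the forecast is accurate —
the enhancing tumor volume is predicted to −1.8 %, mask overlap (Dice)
exceeds 0.95 in both compartments, and the voxel-wise predicted
cellularity correlates at PCC 0.84 (CCC 0.77) with the DWI measurement.
On noiseless phantoms the same calibration recovers every generating
parameter to machine precision (see `tests/test_acceptance.py`).

The other example scripts cover phantom synthesis (`01`), forward
simulation with and without therapy (`02`), the treatment-coupling
approaches (`03`), and AIC model selection (`05`).  A thin CLI mirrors
the pipeline stages:

```sh
glioforecast phantom --out patient0/
glioforecast fit --manifest patient0/manifest.yaml --model two_species:8 \
    --scenario 2 --out fit0/
glioforecast forecast --manifest patient0/manifest.yaml \
    --fit-result fit0/fit_result.json --out pred0/
glioforecast evaluate --manifest patient0/manifest.yaml \
    --predictions pred0/ --out report0/
```

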