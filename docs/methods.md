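# Methods

## The model family

`glioforecast` forecasts the spatial response of unresected high-grade
glioma to chemoradiation from longitudinal multiparametric MRI.  Tumor
burden is represented as a volume-fraction field on the image grid and
evolved by reaction–diffusion dynamics.

**Single species.**  The total tumor fraction φ_T obeys

    ∂φ_T/∂t = ∇·(D_T(x,t) ∇φ_T) + k_pT φ_T (1 − φ_T/θ_T)

with tissue-wise uninhibited diffusion (one coefficient for white matter,
one for gray), logistic proliferation with carrying capacity θ_T, and no
diffusion into CSF or beyond the brain mask.

**Two species.**  The enhancing (φ_E) and non-enhancing / T2-hyperintense
(φ_N) compartments evolve as coupled reaction–diffusion species:

    ∂φ_E/∂t = ∇·(D_E ∇φ_E) + k_pE φ_E (1 − (φ_E + β_NE φ_N)/θ_E)
    ∂φ_N/∂t = ∇·(D_N ∇φ_N) + k_pN φ_N (1 − (φ_N + β_EN φ_E)/θ_N)

with fixed asymmetric competition weights β_NE = 4, β_EN = 1 and fixed
θ_N = 0.16.  The non-enhancing compartment models the infiltrative
peritumoral disease; it is both the more invasive (larger D_N) and — at
its fixed low carrying capacity — strongly suppressed wherever the
enhancing compartment is dense.

**Mechanical coupling.**  Tissue stress inhibits invasion.  At each
mechanics update the quasi-static linear-elastic equilibrium

    ∇·(G ∇u) + ∇[G/(1−2ν) (∇·u)] − λ₂ ∇φ = 0,   u = 0 at the skull

is solved for the displacement u driven by the tumor-fraction gradient
(G: shear modulus, white 2.7 kPa / gray 3.1 kPa / CSF 0.1 kPa; ν = 0.45;
λ₂ = 1).  The von Mises stress σ_vm of the resulting stress tensor damps
diffusion exponentially, D = D₀ exp(−λ₁ σ_vm), with λ₁ (1/kPa) calibrated
per patient.

**Treatment.**  Radiotherapy and chemotherapy act as instantaneous
multiplicative events on their scheduled days:
φ⁺ = φ⁻ · SF_RT · SF_CT, applied to every species.  Each surviving
fraction varies in space through one of four coupling approaches:
C1 (efficacy falls with occupancy φ/θ), C2 (efficacy falls with poor
perfusion via the enhancement ratio, SF = SF_min + 2(1−SF_min)(ER⁻¹−½)),
C3 (the linear variant, SF = SF_min + 2(1−SF_min)(1−ER/2)), and C4
(uniform SF = SF_min).  Because 1/ER is convex, C2 lies at or below C3
everywhere on ER ∈ [1,2], with equality only at the endpoints.  Ten
(RT, CT) combinations are enumerated; with two base models and two
proliferation parameterizations (global scalar, or a voxel field on the
baseline tumor) the family has 40 members.  The enhancement-ratio field
is held at the most recently measured visit: the model does not evolve
vasculature.

## Imaging-to-model mappings

Cellularity is estimated from the apparent diffusion coefficient as
φ = (ADC_w − ADC)/(ADC_w − ADC_min), clamped to [0, 1].  ADC_w defaults
to 3.0×10⁻³ mm²/s (free water near body temperature); ADC_min defaults to
the per-patient minimum ADC over tumor voxels at baseline (configurable:
an explicit value, or the minimum over all visits).  Initial conditions
assign the ADC-derived fraction inside the enhancing tumor, the fixed
fraction 0.16 inside the non-enhancing clinical tumor volume (whose cell
density is not reliably readable from imaging), and zero elsewhere.  An
optional alternative assigns a linearly decaying profile from the
enhancing interface to a small periphery value.  The enhancement ratio
ER = T1_post/T1_pre is clamped to [1, 2].

## Calibration

Free parameters (Table: proliferation rates, carrying capacity of the
enhancing/total species, four (two) tissue-wise diffusion coefficients,
λ₁, SF_RT,min, SF_CT,min — 10 scalars for the two-species model, 7 for
the single-species model, plus lattice values in field-proliferation
mode) are estimated by bounded damped least squares
(`scipy.optimize.least_squares`, trust-region-reflective — the
bound-honoring equivalent of Levenberg–Marquardt).  Residuals are the
simulated minus the DWI-derived total cell fraction at every brain-mask
voxel of every calibration visit; the baseline visit supplies the
initial condition and is never a residual target.  Comparing against the
DWI-derived map over the whole brain (rather than the region-assigned
display map, which flattens the non-enhancing compartment to 0.16) keeps
the synthetic observation model exactly invertible, so on noiseless
phantoms the generating parameters are an exact global minimum; species
identity is pinned down by the species-specific initial condition and
the fixed asymmetric couplings.  Default bounds/initials: D ∈ [0, 1]
mm²/day (init 0.05), k_p ∈ [0, 0.5]/day (init 0.05), θ ∈ [0.5, 1]
(init 1), λ₁ ∈ [0, 10]/kPa (init 0.1), SF_min ∈ [0.01, 1] (init 0.8).
Stopping: relative SSE change below `ftol` (default 1e−6), step norm
below `xtol`, gradient below `gtol`, or the iteration budget; on
non-convergence the best-so-far parameters are returned flagged.

Three calibration scenarios: (1) all follow-up visits (fit assessment),
(2) the 1-month visit only, (3) the 1-month and 3-month visits; held-out
visits are forecast by running the calibrated model forward from
baseline.

Field-proliferation mode assigns one free rate per lattice cell
(configurable downsampling of the voxel grid) intersecting the baseline
tumor; the assembled field is extended to the rest of the brain by
nearest neighbor so later-invaded voxels inherit the closest calibrated
rate.

## Model selection and evaluation

Models are ranked by the Gaussian-residual AIC,
n·ln(SSE/n) + 2(p + 1) (the +1 counts the residual variance; AICc is
available as an option), averaged across patients; ties break toward
fewer parameters.  Global agreement uses the signed percent volume error
and the Dice coefficient per region (enhancing, non-enhancing, union;
predicted masks threshold the species fields at 0.05, matching the
phantom's mask-derivation threshold so oracle identities hold).  Local
agreement uses Pearson and Lin's concordance correlation over the union
of measured and predicted tumor masks, against the DWI-derived fraction.
Rank agreement across visits uses Kendall's tau-b on enhancing volumes
and cell counts (Σφ × voxel volume, a relative-units surrogate adequate
for rank statistics).  Two empty masks define Dice = 1 (logged), so
empty-region comparisons do not fail spuriously.

## Numerics

Explicit forward-Euler time stepping with conservative flux-form central
differences and harmonic face averaging of D; a zero face coefficient
(CSF, background, grid edge) yields a no-flux boundary, so pure
diffusion conserves mass to round-off.  Fractions are clamped to [0, θ]
after each step to guard logistic overshoot at finite dt.  The stability
bound dt ≤ 0.5·safety / (D_max Σ 1/h_i²) is always enforced: when a
fixed dt is requested, the step actually used is min(dt, bound).  A
fixed dt (rather than a per-trial stable dt) is the recommended setting
for calibration because it keeps the number of time steps — and hence
the least-squares objective — continuous in the trial diffusion
coefficients.

The elastic operator is discretized with second-order central
differences on the anisotropic image grid (harmonic averaging of G at
tissue interfaces), with u = 0 on and beyond the brain-mask boundary
(rigid skull) and a small positive CSF shear modulus (0.1 kPa) for
well-posedness.  The forcing gradient ∇φ extends φ beyond the brain by
nearest neighbor before differencing, so a spatially constant φ yields
zero forcing.  Because the operator depends only on the (static) tissue
geometry, it is assembled and LU-factorized once and cached; each
mechanics update is then a pair of triangular solves, with the residual
checked against a 1e−8 relative tolerance.  Treatment events map to the
first simulation step at or after their scheduled day; multiple events
landing on one step are applied as a single combined multiplicative
event with surviving fractions computed from the common pre-treatment
state.  States are sampled at the step nearest each requested record
time.

## The digital phantom

No patient data ships with the package, so a phantom generator emulates
its structure: an ellipsoidal brain (semi-axes 28×28×17.5 mm on the
default 64×64×8 grid of 1×1×5 mm voxels) with a CSF core and a 3 mm
gray-matter shell; a tumor seed offset toward the gray matter with a
quadratic enhancing profile (peak fraction 0.75, edge 0.06) of radius
8 mm and a 6 mm non-enhancing rim at 0.16; a radially decreasing
enhancement ratio (2 at the core, 1 at the rim edge); the standard
chemoradiation course (30 weekday fractions of 2 Gy over 6 weeks
starting day 7, daily concurrent temozolomide, then six 5-day adjuvant
cycles every 28 days); and visits at 0, 30, 90 and 150 days.  The
default ground truth is the two-species model with both therapies
coupled to the enhancement ratio (combination 8) and a global
proliferation rate: k_pE = 0.04, k_pN = 0.06 /day, θ_E = 0.8,
D_E = 0.05/0.02 and D_N = 0.10/0.04 mm²/day (white/gray), λ₁ = 2 /kPa,
SF_RT,min = 0.97, SF_CT,min = 0.98 — a responding tumor that regrows
after the concurrent phase.

Observations invert the model mappings exactly in the noiseless limit:
ADC encodes the total cell fraction via the inverse cellularity mapping
(multiplicative Gaussian noise, default s.d. 3%, approximating Rician
noise at moderate SNR); T1 pairs realize the prescribed ER field
(t1_post = ER·t1_pre, independent 2% intensity noise); masks threshold
the noiseless species fields at 0.05, and the baseline enhancing profile
stays at or above that threshold inside its support, so reconstructing
the initial condition from the emitted images reproduces the true one
exactly.  What the phantom does **not** emulate: real anatomy and
segmentation error, Rician noise at low SNR, registration error,
partial-volume effects, and any mismatch between the generating model
family and actual tumor biology.  Passing phantom tests therefore
demonstrates the correctness and identifiability of the pipeline under
its own assumptions, not clinical accuracy.

## Experiment scales and settings

Phantom experiments run with dt = 2 days and a mechanics stride of 5
steps (stress re-solved every 10 days).  The stride trades accuracy for
speed: stress evolves on the tumor-volume timescale (weeks), and ground
truth and calibration share one discrete scheme, so parameter recovery
is unaffected; per-step library defaults remain dt = stability bound and
stride 1.  Calibration experiments on phantoms bound diffusion to
[0, 0.11] mm²/day so the fixed 2-day step is stable over the whole
search box (the generic [0, 1] default remains for general use).  The
parameter-recovery experiment uses the full 64×64×8 phantom (scenario 1,
initial guesses at twice the truth, clipped into bounds); the
noise-robustness and model-selection experiments use 32×32×4 phantoms
(the latter over a reduced 8-member family — both bases × combinations
{1, 2, 4, 8} × global proliferation — with a capped iteration budget
shared by every member).

## Known limitations

- Forward Euler limits dt through the usual parabolic CFL bound; stiff
  (high-D) settings would favor an implicit scheme, which is out of scope.
- The ER field is static; vascular response to therapy is not modeled.
- The linear-elastic, rigid-skull mechanical model ignores ventricle
  collapse and large-deformation effects.
- AIC values depend on the residual definition (whole-brain voxel count);
  comparisons are meaningful within one residual convention only.
- Voxel-wise proliferation fields make the inverse problem
  high-dimensional; the lattice downsampling option trades resolution
  for conditioning and runtime.
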