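# Methods

## Constitutive model and kinematics

All products are modeled as homogeneous, isotropic, perfectly
incompressible hyperelastic solids. Deformation enters only through the
first and second principal invariants. For uniaxial stretch λ (lateral
stretches 1/√λ by incompressibility):

    I₁ = λ² + 2/λ,   I₂ = 2λ + 1/λ²,
    ∂I₁/∂λ = 2λ − 2/λ²,   ∂I₂/∂λ = 2 − 2/λ³,

and for simple shear with engineering strain γ: I₁ = I₂ = 3 + γ², both
derivatives 2γ. The deformation gradient, the pressure Lagrange
multiplier, and I₃ are never materialized: the zero-lateral-stress
condition (uniaxial) and the plane-shear boundary condition eliminate them
analytically, leaving the closed-form nominal stresses quoted in the
README.

The free energy is the eight-term library (linear, exponential-linear,
quadratic, exponential-quadratic in each of I₁−3 and I₂−3) with
non-negative linear weights w₁..w₈ (kPa) and non-negative exponents
w₂*, w₄*, w₆*, w₈* (dimensionless). Non-negativity keeps every term
polyconvex, so any admissible parameter vector is materially stable.

**Derivative convention.** Stresses use the *exact* partial derivatives of
ψ, including the chain-rule exponent factors: the Demiray term contributes
w₂w₂*·exp(w₂*[I₁−3]) to ∂ψ/∂I₁, not w₂·exp(·). A formulation that drops
these factors is not the derivative of the stated energy and breaks the
small-strain identity μ = 2(w₁ + w₂w₂* + w₅ + w₆w₆*), which this package
relies on for modulus conversions (it reduces to μ = 2w₁ + 2w₅ for
Mooney–Rivlin-type weights; E = 3μ at ν = ½). This identity is verified
against finite differences of the stress at the reference state.

**Overflow guard.** Exponential arguments above 50 raise a flag
(`OverflowFlag`) in normal evaluation; during optimizer trial steps they
are clipped at 50 and the candidate is treated as divergent. Within the
exponent bounds used for fitting (≤ 50) and the strain ranges tested
(|I−3| ≤ ~0.35), clipping never activates at the optimum.

## Preprocessing

Raw per-sample records (monotone control series with nominal stress in
kPa) are resampled with an **interpolating cubic spline** (natural end
conditions) onto 21 equidistant control points per mode:

* tension: λ ∈ [1, λ_max],
* compression: λ from 1.0 down to 0.9,
* shear: γ ∈ [0, 0.1].

Natural end conditions only affect endpoint curvature of noisy data; the
spline passes exactly through on-grid samples, reproduces linear laws to
machine precision, and refuses extrapolation. Loading and unloading
branches are separate records of the same sample and are averaged after
resampling (hysteresis is not modeled). Per-product mean curves carry the
pointwise mean, SEM = SD/√n (sample SD, ddof = 1; zero for n = 1), and n.

λ_max is the largest stretch before any tension sample's stress drops by
more than 5% (configurable) of its running maximum — "failure onset". If
no sample drops, the last common stretch is used with a warning. Default
per-product λ_max values for the synthetic presets are TF/ET 1.12, PS/ST/FT
1.15, AS/PH 1.20, AH 1.35, reflecting that the two stiff/brittle products
fail just above 10% stretch, animal hotdog stretches to 35%, and the rest
fail between 15 and 20%.

Scalar signatures: origin-constrained regression stiffnesses
E = (ε·σ)/(ε·ε) with ε = λ−1 for tension/compression and E_shr = 3(γ·τ)/(γ·γ)
for shear (the factor 3 converts shear modulus to Young's modulus at
ν = ½); E_mean ± SD across the three moduli; tension–compression asymmetry
as the ratio of tensile stress at +10% stretch to compressive stress
magnitude at −10%, read off the (spline-interpolated) mean curves; peak
stress/stretch as per-sample tensile maxima averaged over the
tension-to-failure records when available, else from the mean curve. Note
that the regression stiffness of a nonlinear curve is range-dependent: a
neo-Hookean tension curve regressed over [1, 1.1] sits about 7% below its
small-strain limit 6w₁, while compression over [0.9, 1] sits above it;
three-mode averages largely cancel this.

## Model discovery

The loss is the sum over modes of the mean squared stress residual on the
21-point grids (per-mode normalization equalizes mode influence despite
different point counts or ranges). Fitting exploits that, with exponents
fixed, the stress is linear in w₁..w₈:

* subsets of the linear-in-weight terms {1, 3, 5, 7} are solved exactly by
  non-negative least squares on the per-mode-weighted design matrix;
* subsets with exponential terms add an outer bounded search
  (L-BFGS-B, exponents in [10⁻³, 50]) with NNLS profiling of the linear
  weights at each trial point, restarted from a deterministic log-spaced
  grid of 8 points (seeded jitter in ≥ 2 dimensions). During the sweep,
  each two-term candidate additionally starts from the optimal exponents of
  its constituent one-term fits, so adding a term can never lose the
  one-term minimum.

The contract is on the minimum reached, not the trajectory; any optimizer
attaining it is equivalent. Inactive weights are exactly zero in reported
results. The sweep enumerates all 8 + 28 = 36 one- and two-term subsets
(of the 2⁸ − 1 = 255 possible models), fills the symmetric 8×8 error map
with each subset's mean MSE (average of the three per-mode MSEs), and
selects the lowest-error model per cardinality with lexicographic
tie-breaking for determinism. Goodness of fit is the pooled
R² = 1 − SS_res/SS_tot over the concatenated three-mode stress vector
(per-mode values also reported). Nested-model monotonicity (a superset
never fits worse) holds to 10⁻⁶ relative, with an absolute floor of 10⁻¹²
kPa² for machine-zero losses on noiseless data.

**Identifiability caveat.** The I₁ and I₂ stress bases are nearly
collinear over small strain ranges, so two-term weight *splits* (e.g.
w₁ vs w₅) have high variance under noise even when their sum is tight;
similarly an exponential-quadratic pair (w, w*) is constrained mainly
through its product w·w* when the quadratic argument stays ≪ 1 (for the AS
preset, w₄*[I₁−3]² ≤ 0.14 over its full range). Replicate averaging
removes sampling noise from well-identified weights but cannot resolve a
structurally flat direction; the amplitude of such a pair is recovered
with bias under noise while the product is stable.

## Synthetic data generator

The generator emulates the study conditions: per product, 5 samples per
mode (the study tested at least n = 5), each sample drawing its linear
weights from the preset with multiplicative lognormal scatter (SD 0.10 —
keeps weights positive and yields SEM bands matching the "little
sample-to-sample variation" of the real tests), closed-form stress on a
dense 101-point grid per mode, additive i.i.d. Gaussian noise with SD 2%
of the sample's peak stress, and the reference point forced to zero
stress. Exponents are not scattered (they are material constants of the
preset). A fixed seed gives byte-identical output. Parameter-recovery
checks under noise use scatter 0 and noise 5% so they probe the fitting
stage against data noise alone.

Ground truth is the published best-in-class parameter sets of the eight
products, both the one-term set (e.g. TF: 22.08·[I₂−3]; ST: Demiray
3.21/3.92) and the two-term set (e.g. TF: Mooney–Rivlin 12.27/20.94; AS:
3.63·[I₁−3] + exponential-quadratic 11.85/11.83). The **stand-in curve
sets** used where the study's processed mean-curve table would be needed
are the noiseless datasets generated from the two-term presets. They
reproduce the moduli implied by those models exactly, and mean regression
stiffnesses to a few percent — but they inherit only what the two-term
models encode. In particular, uniaxial I₁-based terms are intrinsically
stiffer in compression than tension (asymmetry ≈ 0.74–0.82), so the large
tensile asymmetry measured for the animal products is *not* reproducible
from any of these models; and one-term refits of stand-in curves agree
with the published one-term parameters only where the published one- and
two-term models coincide (the tofus). Passing tests on synthetic data
demonstrate the pipeline's correctness and the estimators' consistency,
not fidelity of the stand-in to the original measurements; real data
additionally contain hysteresis, failure softening, and mode-dependent
nonlinearity that the generator does not emulate.

## Survey statistics

Twelve texture features on a 5-point Likert scale. Summaries report
per-product mean ± SD sorted by agreement with average-rank ties;
across-product significance uses Kruskal–Wallis at α = 0.05 (a repository
convention — appropriate for ordinal data). Spearman's ρ is the Pearson
correlation of tie-averaged ranks; two-sided p-values come from exact
enumeration of all n! orderings for n ≤ 9 (the study compares 8 products,
40320 orderings) and the t-approximation beyond. Instrument scoring (Food
Neophobia Survey: 10 items on 1–7, totals 10–70; Meat Attachment
Questionnaire: 16 items on 1–5, totals 16–80) reverse-keys the configured
items as (min+max) − response before summation; the reverse-key sets are
configuration, defaulting to the instruments' conventional keys.

## Problem sizes and runtime

Default analyses use 21-point grids, 5 samples per mode, 8 optimizer
starts, and 36 fits per product; a full eight-product simulate → sweep →
report run completes in well under a minute on one CPU, and the
noisy-recovery checks use 20 replicates per product.

## Known limitations

Isotropy and incompressibility are assumed (reasonable for processed
products, not for fibrous whole-muscle meat). No viscoelasticity, rate
dependence, hysteresis, or temperature effects. Subsets of cardinality ≥ 3,
regularization paths, and weight uncertainty quantification are out of
scope. The stand-in curve sets are synthetic reconstructions from published
model parameters, with the fidelity limits described above.
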