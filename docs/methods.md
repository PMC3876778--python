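# Methods

## Model structure and assumptions

The multi-hit-repair (MHR) model treats cell killing as the outcome of a
competition on a chain of populations. A *hit* is one unit of potentially
lethal radiation damage; no specific lesion type is implied. The model
assumes:

* hits arrive at rate αR independently of how many hits a cell already
  carries (a constant per-hit probability along the chain);
* repair moves a cell exactly one level up the chain per event, at rate
  c_r·P, where the repair probability P is a function of the instantaneous
  damage state variables only;
* elimination (rate c_e) and overflow past the cutoff k_max are terminal —
  removed cells never re-enter the system;
* heat below ~44 °C kills no cells directly; it acts only through Λ in P;
* damage kinetics are first order: dΓ/dt = R − γΓ and the Υ/Λ exchange
  dΥ/dt = −k₁Υ + k₂Λ. One effective protein species is modelled; distinct
  repair pathways would need separate Υ/Λ pairs.

The calibration condition lim ∫γΓ dt = D_tot ties Γ to the physical dose,
so Γ carries units of Gy. It implies no damage saturation, which limits
validity to doses well below the regime (≳200 Gy) where bulk protein and
membrane damage dominate.

Survival is S = N/N₀ with α defined on the natural log (ln S = −αD in the
no-repair limit); the conversion factor log₁₀e is applied exactly once, at
reporting. *Asymptotic* survival means N after every damaged population has
resolved to repaired or eliminated (ΣLₖ < 10⁻⁹·N₀ and |dN/dt| < 10⁻⁹·N₀/h),
found by continuing beam-off integration up to a configurable horizon
(default 200 h; non-convergence raises instead of returning a biased value).

## Parameters

| name | meaning | units | default / typical |
|---|---|---|---|
| α (`alpha`) | radiosensitivity (hit rate per unit dose) | Gy⁻¹ | 0.5–2 |
| c_r | repair rate constant | h⁻¹ | 4–100 |
| c_e | elimination rate constant | h⁻¹ | 1–60 |
| μ_Γ (`mu_gamma`) | sensitivity of P to Γ | Gy⁻¹ | 0.2–1.0 |
| γ (`gamma`) | Γ decay constant | h⁻¹ | 1–10 |
| k_max | chain cutoff | — | 6 |
| a | thermal damage-rate anchor at 38 °C (k₁ = a·10⁻³ h⁻¹) | — | 0.56 |
| E_a | activation energy of thermal protein damage | J/mol | 1.528·10⁶ (below 43 °C) |
| k₂ | thermal protein repair rate | h⁻¹ | 2.76 |
| μ_Λ (`mu_lambda`) | sensitivity of P to Λ | — | 29.19 |

Two reference radiation sets ship as constants: `NONAPOPTOTIC_FIBROBLAST`
(α = 1.1, c_r = 100, c_e = 10, μ_Γ = 0.5, γ = 1.45 — a repair-competent,
p53-deficient fibroblast line whose survival curve tracks the LQ law with
α = 0.13 Gy⁻¹, β = 0.054 Gy⁻²) and `T98G` (α = 0.27, c_r = 90, c_e = 19,
μ_Γ = 0.8, γ = 1.45 — a radioresistant glioblastoma line used for
high-dose-rate studies).

The Arrhenius rate is implemented in anchored form,

    k₁(T) = a·10⁻³ h⁻¹ · exp[(E_a/R_gas)(1/311.16 K − 1/T)],

i.e. the tabulated `a` fixes k₁ at 38 °C and E_a sets the temperature
sensitivity. Combining a raw prefactor κ with e^(−E_a/R_gas·T) directly is
numerically useless at these activation energies (the exponent is ≈ −600);
anchoring is the standard regrouping and reproduces the same temperature
dependence. A single E_a is used; the model is intended for T ≤ 43 °C, and
a different E_a above 43 °C can be supplied by the caller if needed.
Temperatures convert as T[K] = T[°C] + 273.16 throughout.

Initial conditions: N = 1, all Lₖ = 0, Γ = 0, Υ = 1, Λ = 0, ledgers 0
(undamaged cells, full repair capacity).

### Repair-probability variants

* `exponential` (default): P = e^(−(μ_Γ Γ + μ_Λ Λ)) — monotone decreasing
  in both damage variables.
* `gaussian`: P_Γ = e^(−ξ(Γ−Γ_c)²) — induced repair peaking at a
  characteristic dose Γ_c, for modelling low-dose hypersensitivity.
* `sigmoidal`: a logistic step in Γ with user-supplied midpoint and
  steepness, normalised so P(0) = 1 (the shape is specified qualitatively
  in the literature; the normalisation makes the variants interchangeable
  at Γ = 0). Both alternatives keep the e^(−μ_Λ Λ) thermal factor.

## Numerical integration

The coupled system (N, L₁…L_kmax, Γ, Υ, Λ plus the eliminated/overflow/dose
ledgers) is integrated with classical fixed-step RK4. Step sizes: 10⁻³ h
during beam-on, dropping to 5·10⁻⁵ h above 300 Gy/h where a fraction lasts
only seconds; 10⁻³ h beam-off. Steps are clipped so segment boundaries are
hit exactly, making trajectories independent of output cadence and
bit-reproducible. A step that drives a population negative beyond 10⁻¹⁰ is
retried at half size (bounded recursion); conservation
N + ΣL + eliminated + overflow = N₀ holds to round-off because the
right-hand side sums to zero identically.

Accuracy scales as (λ·dt)⁴ with the fastest local rate
λ ≈ αR + c_r·P + c_e; the defaults keep λ·dt ≲ 0.5 for the reference
parameter sets, which is amply stable for RK4 and step-size converged below
10⁻⁵ in final log₁₀S (verified by step-halving in the tests). For
oracle-grade comparisons (e.g. the c_r = 0 closed form at 10⁻⁵ relative) a
beam-on step of 2·10⁻⁴ h is used so that λ·dt ≲ 0.1.

Protocols are contiguous piecewise-constant segments of (dose rate,
temperature); builders insert beam-off body-temperature segments for gaps.
The HT-RT builder measures the signed time gap between the midpoints of the
heating and irradiation intervals (negative gap = irradiation first) and
merges overlapping windows into segments carrying both exposures.

## Chain-cutoff diagnostics

`cutoff_scan` reruns one fractionation scheme at several cutoffs and
reports, per cumulative dose, log₁₀S(k_max), the ratio against the k_max=6
reference, and the difference Δlog₁₀S = log₁₀S(6) − log₁₀S(k). With 8 Gy
fractions at 240 Gy/h and the fibroblast set, the ratio at k_max = 1 is
1.254 and is dose-independent to ~10⁻¹⁴ under exact inter-fraction
recovery — residual spread in this statistic is purely numerical.

Δ decays with k_max in a near-geometric way. `fit_exponential_decay`
returns (a, b) of Δ = a·e^(−b·k) — exact for two points, least squares on
ln Δ otherwise. For the 5×2 Gy, 60 Gy/h course the informative summary is
the **per-level attenuation factor** e^b = Δₖ/Δₖ₊₁: the two-point solve
over k ∈ {1, 2} gives Δ(1) = 1.02 and e^b = 3.31 (≈3.8 per level when all
k ≤ 5 enter the fit), i.e. each additional chain level shrinks the cutoff
error roughly 3–4-fold, which is why k_max = 6 is an adequate default:
beyond 4–5 hits, recovery is negligible against elimination.

## Evolutionary fitter

The fitness is f = Σᵢ wᵢ(log₁₀S_model,i − log₁₀S_obs,i)² over a tabular
dataset of exposure descriptors; a record whose simulation does not
converge scores +∞ and the candidate is rejected. The optimiser is a
seeded (1+1) evolution strategy: every free parameter is multiplied by
(1 + ε·r), r ~ U(−1, 1) drawn per parameter in declaration order, and the
mutant is accepted iff f does not increase — so the fitness trace is
monotone and positivity is preserved by construction. The default schedule
is 10⁵ steps with ε = 0.02, reduced to 0.01 after step 66000. The
multiplicative form (1 + ε·r) is used rather than a bare factor ε·r, which
would flip parameter signs half the time and cannot act as a local search.

The fitness landscape of this model is smooth but flat: clearly different
parameter sets produce nearly identical curves (e.g. c_r can move ±16% and
μ_Γ ±10% within typical experimental error bars). Recovery is therefore
judged in curve space, not parameter space. The packaged recovery study
refits (c_r, μ_Γ) on noiseless self-generated data (6 doses × 2 dose
rates, starts perturbed ~10%) with 600 steps and the ε switch scaled to
step 400, at dt = dt_off = 5·10⁻³ h on both the generating and fitting
side so discretisation cancels in the residuals; it reaches a maximum
curve residual < 2·10⁻⁴ log₁₀S in about a minute. Problem sizes were
chosen to make the study a quick self-check; the full published schedule
is the default for real fits.

Weighted records support anchor points — e.g. HT-RT baseline survival at
large |time gap| entered as explicit double-weight records rather than
optimiser special-casing.

## Synthetic data

`synthesize_dataset` draws log₁₀S observations around the LQ reference law
with i.i.d. Gaussian noise of fixed standard deviation on the log scale —
a stand-in for a clonogenic assay curve (e.g. α = 0.13 Gy⁻¹,
β = 0.054 Gy⁻² mimics a p53-deficient fibroblast line). `model_dataset`
generates data from the MHR model itself for self-consistency studies. The
generator does not emulate dose-dependent error bars, plating-efficiency
normalisation, finite colony counts, or inter-replicate correlation; a
passing recovery test therefore demonstrates identifiability of the
procedure under ideal sampling, not robustness to real assay artefacts.

## Known limitations

* No mitotic/cell-cycle compartments and no tumour subpopulations — one
  homogeneous population per run.
* Repair kinetics of Γ are first order only; hit probability does not vary
  with k (a per-k α would turn the chain into a tree).
* The cutoff overflow counts every hit beyond k_max as death; repair of
  deeper populations is deliberately neglected.
* High-dose-rate behaviour plateaus; experimentally observed extra killing
  of some glioblastoma lines at ≳1440 Gy/h with high dose per pulse is not
  reproduced by this parameterisation.
* Thermal-dose isoeffect measures (e.g. CEM43) are out of scope; the HT-RT
  module works directly on the (T, t) timeline.
* The fixed-step integrator is explicit; parameter sets far stiffer than
  the reference ones (c_r ≫ 10³ h⁻¹) would need smaller dt_off than the
  default.
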