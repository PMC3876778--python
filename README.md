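# mhrsim

A simulator and fitting workbench for the **multi-hit-repair (MHR) model**
of clonogenic cell survival under ionising radiation and moderate
hyperthermia.

Classical survival laws such as the linear-quadratic (LQ) model,
ln S(D) = −(αD + βD²), describe dose-response curves but not the dynamics
behind them: dose-rate effects, recovery between fractions, the
linear-quadratic-*linear* shape at high dose, or the synergy between heat
and radiation with its dependence on the time gap between the two. The MHR
model addresses these with a small ODE system that radiobiologists,
medical physicists and modellers can run against arbitrary treatment
timelines.

## The model

Vital cells N collect radiation-induced *hits* that move them down a chain
of damaged populations L₁ … L_kmax; repair moves them back up one level at
a time, elimination (an apoptosis-like pathway) removes them irreversibly:

    dN/dt   = −αR·N + c_r·P·L₁
    dL₁/dt  =  αR·N − (αR + c_r·P + c_e)·L₁ + c_r·P·L₂
    dLₖ/dt  =  αR·Lₖ₋₁ − (αR + c_r·P + c_e)·Lₖ + c_r·P·Lₖ₊₁
    dL_kmax/dt = αR·L_kmax−1 − (αR + c_r·P + c_e)·L_kmax

with dose rate R (Gy/h), radiosensitivity α (Gy⁻¹), repair and elimination
rate constants c_r, c_e (h⁻¹). Cells hit beyond the chain cutoff k_max
are counted dead (*overflow*), as are eliminated cells, so that
N + ΣLₖ + eliminated + overflow is conserved exactly.

The repair probability P couples the chain to two damage state variables:

* the **biological dose equivalent** Γ (Gy), dΓ/dt = R − γΓ, tracking
  radiation damage to repair proteins and calibrated so ∫γΓ dt equals the
  delivered dose;
* the **heat-damaged protein fraction** Λ (with functional fraction
  Υ = 1 − Λ), dΛ/dt = k₁(T)·Υ − k₂·Λ, where k₁ follows an Arrhenius law in
  temperature;

with P = e^(−(μ_Γ·Γ + μ_Λ·Λ)) in the base model (Gaussian induced-repair
and sigmoidal variants are also available). Survival is S = N/N₀, reported
as log₁₀S once all damaged populations have resolved.

The package provides the kinetics and population system, a fixed-step RK4
integrator over piecewise-constant dose-rate/temperature protocols,
builders for fractionated radiotherapy and hyperthermia-radiotherapy
(HT-RT) time-gap experiments, chain-cutoff and dose-rate scans, an LQ
reference law, synthetic survival-data generation, and a seeded (1+1)
evolution-strategy fitter minimising weighted squared log₁₀S residuals.

## Worked example

```python
import mhrsim as m

# repair-competent fibroblast parameter set
rad = m.RadiationParams(alpha=1.1, c_r=100.0, c_e=10.0,
                        mu_gamma=0.5, gamma=1.45, k_max=6)

one = m.asymptotic_survival(m.fractionation_protocol(1, 2.0, 60.0), rad)
five = m.asymptotic_survival(m.fractionation_protocol(5, 2.0, 60.0, gap=24.0), rad)
print(round(one, 4), round(five, 4))
# -0.1711 -0.8554

print(m.dose_rate_scan(m.T98G, 10.0, [12.0, 60.0, 240.0, 3000.0]))
#    dose_rate_Gy_h    log10S
# 0            12.0 -0.867110
# 1            60.0 -1.021670
# 2           240.0 -1.112910
# 3          3000.0 -1.163307
```

A single 2 Gy fraction at 60 Gy/h kills ~33% of cells (log₁₀S = −0.171);
five daily fractions give exactly five times that decrement (−0.855),
the straight-line fractionation envelope expected under complete
inter-fraction repair. The dose-rate scan shows the characteristic
behaviour of a 10 Gy exposure of T98G glioblastoma cells: survival falls
with increasing dose rate (less repair time during delivery) and
plateaus above ~240 Gy/h just short of the no-repair bound
−α·D·log₁₀e ≈ −1.173.

The same experiments are available from the shell via the `mhr` command
(`mhr simulate`, `fractionate`, `cutoff-scan`, `doserate-scan`,
`htrt-scan`, `synth`, `fit`); every run echoes its resolved configuration
and seed next to its CSV outputs.

See `docs/methods.md` for the model assumptions, parameter units and
defaults, numerical settings and known limitations.

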