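# coliastherm

Thermal limits on butterfly flight initiation, in silico.

Flight is the fitness-critical activity of adult *Colias* butterflies, and it
is only possible above a body-temperature threshold. Along Rocky Mountain
elevation gradients two levers of local adaptation set how quickly an
individual reaches that threshold on a cold morning: **morphology** (darker,
more melanic ventral hindwings absorb more solar radiation; longer thoracic
setae cut convective loss) and **physiology** (the thermal sensitivity of the
willingness to initiate flight). `coliastherm` is a simulation pipeline for
ecophysiologists who want to quantify the relative contributions of these two
mechanisms: it couples a biophysical heat budget to a stochastic
flight-initiation hazard, drives both through simulated reciprocal-transplant
(full sun) and common-garden (no direct sun) field experiments on synthetic
micrometeorology, and decomposes the resulting species differences.

## The models

**Steady-state heat budget.** The thorax is a lumped cylinder (diameter *D*,
length *L*, surface *A* = π*DL*) at equilibrium:

    α S a_proj A  =  h_tot A (T_b − T_air)  +  ε σ A (T_b⁴ − T_rad⁴)

with absorptivity α, solar flux *S*, projected-area fraction `a_proj`
(lateral basking for the direct beam, a smaller factor for diffuse light in
tents), series fur-plus-boundary-layer conductance
`1/h_tot = 1/h_c + d_setae/k_fur`, `h_c` from a cylinder Nusselt–Reynolds
correlation `Nu = 0.6 Re^0.5`, and a view-factor-weighted radiant temperature
`T_rad` mixing sky and ground. The thermal time constant
`τ = C / (A (h_tot + 4εσT³))` is ≈30 s in light wind, so the steady-state
model is adequate at the 1–2 min cadence of trial observations (a transient
integrator is included to verify exactly this).

**Flight-initiation hazard.** At each trial check, a butterfly that has not
yet flown initiates with probability

    q(T) = p_mot · Φ((T − μ) / σ_T)

where *T* is its driving temperature (predicted body temperature in cages;
the shared physical-mimic temperature in tents), μ the mean threshold, σ_T
its spread and `p_mot` a per-check motivation probability. The same hazard
defines an interval-censored likelihood, so thermal sensitivities can be
recovered from record tables by maximum likelihood with bootstrap CIs.

**Decomposition.** With direct sun the species initiation-time gap reflects
sensitivity *and* morphology; without direct sun only sensitivity. Hence
physiology contributes `Δt_no_sun / Δt_sun × 100` percent and morphology the
rest. With the published field advantages (5 min without sun, 35 min with)
this gives 14.29% / 85.71%, i.e. **15% physiology / 85% morphology** at the
reported 5-point precision.

## Worked example

```python
from coliastherm import EnvSample, Morphology, steady_state_Tb
env = EnvSample(time=600, air_temp=15.0, soil_temp=22.0, solar=800.0, wind=1.0)
steady_state_Tb(Morphology(0.691, 1.27), env)   # 21.11  (dark, furry meadii)
steady_state_Tb(Morphology(0.518, 0.63), env)   # 18.01  (pale eriphyle)
```

The same environment leaves the high-elevation phenotype 3.1 °C warmer —
the morphological lever. Running the full pipeline
(`python examples/05_garden_and_decomposition.py`) prints:

```
initiation advantage of the high-elevation species:
  without direct sun (garden):    15.0 min  CI (12.2, 17.8)
  with direct sun (transplant):   46.7 min  CI (44.3, 49.1)
  driving-temp offset in garden:  0.82 C    CI (0.76, 0.89)
thermal sensitivity contributes 32.2% (~30%), morphology 67.8% (~70%)
published advantages (5, 35) min -> 15% / 85%
```

The garden recovers the configured 0.8 °C species offset in threshold
temperature; the decomposition applied to the published field advantages
reproduces the canonical 15/85 split. Each script in `examples/` is a short
narrative of one capability (microclimate generation, body temperature,
single trials, both experiment designs, sensitivity fitting).

A thin CLI wraps the same functions:

```
coliastherm --seed 1 --out runs generate
coliastherm --seed 1 --out runs transplant --n-per-cell 24
coliastherm --out runs decompose --dt-no-sun 5 --dt-sun 35
coliastherm defaults          # audit of every default with provenance tag
```

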