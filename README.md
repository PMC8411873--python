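# firehealth

Quantifies the air-quality, public-health and equity impacts of
eliminating forest and vegetation fires, from paired gridded
atmospheric-chemistry scenarios ("all sources" vs "fires off").  It is
aimed at researchers doing health impact assessments of biomass-burning
smoke: given matched concentration fields (annual/monthly PM2.5 and
PM10, daily-maximum-8-h ozone), gridded population, baseline health
rates and a gridded infant-mortality-rate (IMR) poverty proxy, it
computes exposure metrics, attributable disease burdens with
uncertainty, model-evaluation statistics against monitoring stations,
and poverty-exposure disparity summaries.  A synthetic-data generator
produces all of these inputs with known ground truth, so the entire
chain is testable without chemical-transport-model output.

## Methods at a glance

**PM2.5 relative risk** uses the GEMM (Global Exposure Mortality Model)
curve

    RR(z) = exp( θ · log(1 + z/α) / (1 + exp(−(z − μ)/ν)) ),   z = max(0, C − cf)

with cause-specific coefficients (θ, α, μ, ν) and counterfactual
cf = 2.4 μg m⁻³.  **Ozone** mortality uses a log-linear response,
RR = RR₁₀^(max(0, ADM8h − TMREL)/10), defaulting to RR₁₀ = 1.12
(95% CI 1.08–1.16) per 10 ppbv above TMREL = 26.7 ppbv.

**Attributable burden** per grid cell, cause and age group is

    ΔM = AF(RR(C)) · baseline_rate · age_fraction · population,   AF = (RR − 1)/RR

and the **fire-attributable burden** follows the subtraction method,

    M_FIRE = M_ALL − M_FIRE_OFF,

the difference between burdens computed with and without fire
emissions.  95% uncertainty intervals come from Monte Carlo propagation
(θ normal; baseline rates lognormal; age fractions logit-normal, all
matched to their 95UIs), with draws shared across scenarios and regions
so differences and group totals aggregate per draw.

**Model evaluation** isolates the fire-derived PM signal by subtracting
each calendar year's minimum monthly mean, selects stations where fires
contribute ≥ 20% of simulated annual PM10, and scores the model with
the normalized mean bias factor (NMBF: Σm/Σo − 1 if the model is high,
1 − Σo/Σm if low), Pearson r and normalized standard deviation.

**Equity analysis** bins fire-derived PM2.5 exposure by IMR, compares
mean exposure between high-poverty (IMR ≥ 60) and low-poverty
(IMR ≤ 20) cells with a 99%-confidence Welch test, splits each poverty
class's exposure into fire vs nonfire shares, and maps a 3×3
poverty × exposure classification.

## Worked example

```python
from firehealth import demo_config, run_pipeline

cfg = demo_config(seed=1)          # 40x40 cells at 0.25 deg, 12 months, 12 stations
arts = run_pipeline(cfg, "out")
print(arts["summary"].table.loc[4, ["region", "pm25_exposure_reduction_pct",
                                    "pm25_burden_reduction_pct", "pm25_mortality"]])
```

The demo run prints, for the whole domain, a population-weighted PM2.5
exposure reduction of **21.7%** when fires are switched off, a burden
reduction of **14.1%** — smaller than the exposure reduction, as the
concave GEMM response implies — and **7,416** (95UI 5,777–8,952) averted
premature deaths per year at the synthetic population and baseline
rates.  The station composite gives NMBF = **−0.27** (the "model"
series underestimates the bias-inflated synthetic observations by a
factor 1.27) with r² = 0.997, and the equity stage reports that cells
with IMR ≥ 60 see a mean fire-derived PM2.5 of **11.6 μg m⁻³** against
**0.5 μg m⁻³** where IMR ≤ 20 (significant at 99%), with fire
contributing **48%** of the total exposure of the "very poor" class.

The same pipeline is available from the shell:

```sh
firehealth all --seed 1 --outdir out          # or: simulate / exposure / burden /
firehealth report --config examples/demo_config.yaml --outdir out
```

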