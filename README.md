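# greenrisk

Bayesian small-area disease mapping for studies that relate an area-level
environmental exposure — here, urban vegetation cover measured by the
Enhanced Vegetation Index (EVI) — to age- and sex-stratified health
outcome counts, with full adjustment for spatially structured and
unstructured residual risk.

The package is aimed at spatial epidemiologists who have, per region
(e.g. a city neighborhood): stratified observed counts and populations, a
handful of area-level covariates, and a contiguity structure. It
provides the complete workflow: EVI construction from reflectance
rasters, indirect standardization, Moran's I screening, the
Besag–York–Mollié (BYM) Poisson-lognormal model fitted by MCMC, and
relative-risk map export. A synthetic-data generator with known ground
truth makes every stage testable without any external data.

## The model

For region *i* = 1, …, *n* within one (sex, age-group) stratum, with
observed count *O_i* and expected count *E_i* from indirect
standardization,

```
O_i ~ Poisson(E_i · r_i)
log r_i = β₀ + β₁X₁ᵢ + … + β₅X₅ᵢ + uᵢ + sᵢ
```

where X₁ is the zonal-mean EVI, X₂…X₅ are deprivation-style covariates,
*uᵢ* ~ N(0, 1/τ_u) is an exchangeable effect absorbing overdispersion,
and *s* follows an intrinsic conditional autoregressive (ICAR) prior —
a Gaussian kernel penalizing squared differences between contiguity
neighbors, identified by a sum-to-zero constraint. Priors are
β ~ N(0, 100²) and τ_u, τ_s ~ Gamma(0.5, 0.0005), all configurable.

Two posterior functionals summarize the fit beyond the coefficients:

- the **spatial fraction** ψ = SD(s) / (SD(s) + SD(u)) per draw — ψ → 1
  means residual risk variation is predominantly spatial;
- the **relative risk** r_i = exp(β₀ + x_i′β + u_i + s_i) per region,
  with r_i > 1 flagging elevated area-specific risk.

Inference is Metropolis-within-Gibbs with adaptive random-walk updates,
graph-colored single-site updates for *s*, conjugate Gamma draws for the
precisions, and likelihood-invariant "ridge" translations that decorrelate
the slopes from the smooth component of the spatial field. Chains are
bit-reproducible given a seed.

## Worked example

Simulate a 140-region study with a strong negative vegetation effect
(β₁ = −4.544), screen one stratum for spatial autocorrelation, and fit
the model:

```python
import numpy as np
from greenrisk import (generate_lattice, build_weights,
                       morans_i_permutation, BYMPoissonModel)
from greenrisk.simulate import (SimulationTruth, simulate_covariates,
                                simulate_populations, simulate_counts)
from greenrisk.standardize import expected

geog = generate_lattice(10, 14)                       # 140 regions
cov = simulate_covariates(geog, seed=1)
pop = simulate_populations(geog, seed=2)
truth = SimulationTruth(beta=(0, -4.544, 0, 0, 0, 0),
                        sigma_u=0.1, sigma_s=0.5, seed=3)
counts = simulate_counts(geog, cov, pop, truth).drop(columns=["expected"])
table = expected(counts)                              # indirect standardization

stratum = table[(table.sex == "male") & (table.age_group == "20-44")]
stratum = stratum.set_index("region_id").loc[list(geog.region_ids)]
y, E = stratum.observed.to_numpy(float), stratum.expected.to_numpy(float)

W = build_weights(geog, style="row")
I, p = morans_i_permutation(np.log((y + 0.5) / E), W, seed=0)
print(f"Moran's I (log SIR) = {I:.3f}, pseudo-p = {p:.3f}")

X = cov.set_index("region_id").loc[list(geog.region_ids),
                                   ["X1", "X2", "X3", "X4", "X5"]]
model = BYMPoissonModel(random_state=0).fit(X.to_numpy(), y,
                                            expected=E, adjacency=geog)
print(model.summary_.coefficients.round(3))
m, lo, hi = model.summary_.psi
print(f"psi = {m:.3f} (95% CI {lo:.3f} to {hi:.3f})")
```

Output:

```
Moran's I (log SIR) = 0.648, pseudo-p = 0.001
        mean   q025   q975  significant
beta0  1.906  1.245  2.561         True
beta1 -4.942 -6.427 -3.442         True
beta2 -0.020 -0.094  0.054        False
beta3  0.009 -0.072  0.085        False
beta4 -0.016 -0.093  0.060        False
beta5  0.033 -0.035  0.101        False
psi = 0.908 (95% CI 0.757 to 0.972)
```

The permutation test confirms strong positive spatial autocorrelation in
the crude log standardized incidence ratios (p at the 999-permutation
floor). The fitted vegetation coefficient is decisively negative and its
95% credible interval covers the generative value −4.544; the nuisance
covariates, generated with zero effect, are correctly non-significant.
ψ ≈ 0.9 says the residual risk variation is predominantly spatial, as
built into the simulation (σ_s = 0.5 vs σ_u = 0.1).

The same workflow is scriptable from the shell:

```sh
greenrisk simulate --rows 10 --cols 14 --seed 1 --out study/
greenrisk expected --counts study/stratum_table.csv --out study/with_e.csv
greenrisk run-study --seed 1 --out study/results
greenrisk export-map --rr study/results/rr_male_20-44.csv \
    --rows 10 --cols 14 --out study/risk_map.geojson
```

## Layout

- `greenrisk.geography` — areal units, lattices, edge-list I/O
- `greenrisk.simulate` — synthetic studies with known ground truth
- `greenrisk.evi` — EVI from blue/red/NIR bands, zonal means
- `greenrisk.spatial` — spatial weights, Moran's I permutation test
- `greenrisk.standardize` — rates, expected counts, SIRs
- `greenrisk.bym` — the `BYMPoissonModel` estimator and posterior summaries
- `greenrisk.pipeline` — study orchestration, GeoJSON/CSV map export

See `docs/methods.md` for modeling details, numerical choices and known
limitations.
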