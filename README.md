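# pollistab

Hierarchical partitioning of temporal invariability for plant–pollinator
metacommunities.

Field ecologists increasingly ask not just *how much* pollination a
landscape delivers but *how stable* that delivery is through time, and at
which organizational level the stability arises. `pollistab` takes
long-format survey tables — per-round flower counts, pollinator visit
records, and per-individual fruit set across several sites and years — and
decomposes the temporal invariability of each system variable (floral
availability, visitation rate, plant–pollinator interaction frequency,
fruit set) across a hierarchy of organizational levels and spatial scales.
It also fits Taylor's power law relating temporal variance to mean
abundance, and ships a synthetic two-trophic metacommunity generator with
known ground-truth synchrony for testing every stage without field data.

## The statistic

Write `x[u, k, t]` for the value of unit *u* (a plant species, a
pollinator species, or a plant–pollinator pair, depending on the variable)
in site *k* in year *t*, and let μ be the temporal mean of the regional
total. Four weighted coefficients of variation span the
population/community × local/regional grid:

    CV_S,L = Σ_{u,k} sd(x[u,k,·]) / μ         population, local
    CV_C,L = Σ_k sd(Σ_u x[u,k,·]) / μ         community, local
    CV_S,R = Σ_u sd(Σ_k x[u,k,·]) / μ         population, regional
    CV_C,R = sd(Σ_{u,k} x[u,k,·]) / μ         community (gamma), regional

Synchrony indices are ratios of adjacent CVs — species synchrony
Ψ_S→C,L = CV_C,L / CV_S,L, spatial synchrony Ψ_C,L→R = CV_C,R / CV_C,L,
and the two regional-route analogues — so the chain
CV_C,R = CV_S,L · Ψ_S→C,L · Ψ_C,L→R holds exactly and every Ψ ∈ [0, 1]
(an aggregate's SD cannot exceed the sum of its parts' SDs). Invariability,
the stability measure, is 1/CV, and is therefore non-decreasing from
population to community to region: asynchrony among species and among
sites buffers the aggregate (the insurance hypothesis).

Taylor's power law, Var = a · meanᵇ across units, is estimated by OLS on
log₁₀ axes. The default regresses log₁₀(SD) on log₁₀(mean), so b = 0.5
corresponds to variance growing linearly with the mean (the Poisson
benchmark); a `var_vs_mean` convention reporting the literal
variance-on-mean slope is also available.

## Worked example

```python
import pollistab as ps

config = ps.SynthConfig(seed=11)          # 8 plants, 12 pollinators, 5 sites, 2 years
flowers, visits, fruitset = ps.simulate_dataset(config)
result = ps.run_study(flowers, visits, fruitset)

res = result.partitions["fruit_set"]
print(f"fruit set: CV_S,L={res.cv_s_l:.3f}  CV_C,L={res.cv_c_l:.3f}  CV_C,R={res.cv_c_r:.3f}")
print(f"species synchrony = {res.phi_s2c_l:.3f}, spatial synchrony = {res.phi_c_l2r:.3f}")
print(f"invariability population={res.inv_s_l:.2f}  community={res.inv_c_l:.2f}  region={res.inv_c_r:.2f}")
fit = result.taylor[("flower_availability", "population")]
print(f"Taylor b (flowers, population) = {fit.b:.3f}  (r^2 = {fit.r_squared:.3f}, n = {fit.n_units})")
```

prints

```
fruit set: CV_S,L=0.063  CV_C,L=0.026  CV_C,R=0.015
species synchrony = 0.407, spatial synchrony = 0.573
invariability population=15.80  community=38.80  region=67.76
Taylor b (flowers, population) = 0.569  (r^2 = 0.366, n = 39)
```

Fruit set fluctuates far less at the regional level (invariability 67.8)
than for single populations (15.8): species synchrony of 0.41 and spatial
synchrony of 0.57 mean population- and site-level fluctuations partly
cancel in the aggregate. The flower-count Taylor exponent near 0.5 says
the temporal variance of a species' floral abundance grows roughly
linearly with its mean.

The same analysis runs from the shell:

```
pollistab simulate --seed 11 --out data/
pollistab partition --flowers data/flowers.csv --visits data/visits.csv \
    --fruitset data/fruitset.csv --out results/
pollistab taylor --table data/flowers.csv --kind flowers \
    --variable flower_availability --level population
```

`results/` then holds `summary.csv` (tidy
`variable,level,component,value` rows), `report.json` (all components plus
degeneracy flags and conventions), and `level_ordering.json`.

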