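# carmap

Small-area disease mapping for rare outcomes: indirect age/sex
standardization of areal case counts, Bayesian smoothing of incidence rate
ratios with a Leroux conditional-autoregressive (CAR) spatial Poisson model,
and posterior exceedance-probability flagging of excess-risk areas.  Built
for epidemiologists mapping registry diseases (the motivating case is
pleural mesothelioma over Danish parishes) whose raw per-area rates are too
unstable to read directly, and whose registry data cannot be shared — so the
package ships a synthetic registry generator that makes the entire pipeline
testable and reproducible without any restricted data.

## Model

For area i with observed cases O_i and indirectly standardized expected
cases E_i = Σ_s n_{i,s} r_s (stratum person-years times national stratum
rates over 7 age groups × 2 sexes):

    O_i | φ ~ Poisson(E_i exp(β + φ_i))
    φ ~ N(0, τ² [ρ(D − W) + (1 − ρ) I]⁻¹)      (Leroux CAR prior)
    β ~ N(0, V_β),   τ² ~ IG(a, b),   ρ ~ U[0, 1)

with W the binary adjacency matrix of the areas and D its degree matrix.
The smoothed IRR is θ_i = exp(β + φ_i); an area is flagged at threshold c
when P(θ_i > c | data) > 0.95 (defaults c = 1.25 and c = 2.0, i.e. risk
elevated by more than 25% or 100%).  Fitting is adaptive
Metropolis-within-Gibbs; residual spatial autocorrelation is checked with
Moran's I.  See `docs/methods.md` for the full account.

## Worked example

```python
import carmap
from carmap import synthetic as syn

# A 10x10 synthetic world: Danish-like parish populations, 32 years of
# person-years, a Leroux risk surface with a 4-area hotspot at 3x risk,
# and ICD-coded registry records including 10% non-qualifying decoys.
ds = syn.simulate_dataset(nx=10, ny=10, seed=42, decoy_fraction=0.1,
                          hotspot_areas=["A0044", "A0045", "A0054", "A0055"],
                          hotspot_multiplier=3.0)
records = syn.apply_case_definition(ds["records"])
print(f"{len(ds['records'])} registry records, {len(records)} qualifying cases")

model = carmap.LerouxCAR.from_table(ds["table"], ds["graph"])
results = model.fit(carmap.McmcConfig(n_burnin=2000, n_sample=10000,
                                      thin=10, seed=1))
print(results.summary())
summary = results.area_summary()          # per-area risk table
print(results.moran_test())
```

Output:

```
485 registry records, 441 qualifying cases
Leroux CAR spatial Poisson model
areas: 100   retained draws: 1000   chains: 1

         mean      sd    q2.5   q97.5
param
beta  -0.0872  0.0756 -0.2423  0.0552
tau2   0.2936  0.1262  0.1199  0.5938
rho    0.5073  0.2442  0.0536  0.9307

acceptance rates: phi=0.39 beta=0.40 rho=0.41
Moran's I = -0.0213 (null -0.0101), z = -0.161, two-sided p = 0.872 [row-standardized]
```

`beta` near zero says the model's baseline matches the national rate (a
consequence of internal standardization, where Σ E_i = Σ O_i exactly);
`tau2` and `rho` are the variance and spatial dependence of the log-risk
surface; the Moran p of 0.87 says the CAR effect absorbed the spatial
structure of the residuals.  In this run one hotspot area is flagged at
c = 1.25:

```
area_id  observed  expected  raw_irr  post_mean_irr  p_gt_1_25  p_gt_2
  A0054      37.0 12.863522 2.876351       2.395396        1.0   0.818
```

— its raw IRR of 2.88 is shrunk to a posterior mean of 2.40, with
P(θ > 1.25) = 1.00 and P(θ > 2) = 0.82.  The other hotspot areas have
smaller populations, hence too few expected cases to clear the 95%
exceedance bar on their own; this conservatism under shrinkage is discussed
in `docs/methods.md`.

## Command line

Every stage is a subcommand runnable standalone on the previous stage's
outputs:

```sh
carmap simulate --nx 15 --ny 15 --seed 7 --out data/
carmap standardize --counts data/counts.csv --out out/
carmap fit --counts data/counts.csv --adjacency data/graph.gal --out out/ --seed 7
carmap flag --fit-dir out/ --thresholds 1.25,2.0 --prob 0.95
carmap diagnose --fit-dir out/ --adjacency data/graph.gal
carmap run-all --counts data/counts.csv --adjacency data/graph.gal --out out/ --seed 7
```

Adjacency may come from a GAL neighbor file, an edge-list CSV, or a GeoJSON
FeatureCollection (queen contiguity).  `run-all` writes the per-area risk
summary (CSV, plus GeoJSON when polygons are supplied), posterior draws, and
a JSON manifest recording every modelling default so runs can be compared by
diffing manifests.

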