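# chacoedge

Agriculture-driven **edge effects** on tropical dry-forest structure:
simulation, Bayesian multilevel estimation, and degradation-footprint
accounting for fragmented landscapes such as the Argentine Dry Chaco.

When agriculture expands into forest, the remaining forest next to the new
edge degrades — lower tree cover, lower shrub cover, less aboveground biomass
(AGB) — and the damage reaches hundreds of meters beyond the cleared plot and
keeps intensifying for decades.  `chacoedge` implements the full analysis
chain needed to quantify this:

1. **Landscape** — generate a seeded synthetic landscape (forest mask,
   tree/shrub-cover and AGB rasters, climate gradients, roads, homesteads)
   with rectangular deforestation plots carrying a clearing year (1976–2020)
   and a post-deforestation land use (cropland, pasture, silvopasture), or
   ingest real rasters/vectors in the same plain-text formats.
2. **Sampling** — a space-for-time design: 3000 random forest points within
   2000 m of a plot (and ≥ 10 km from the region boundary), each with the
   distance to and attributes of its nearest plot, edge age, climate and
   accessibility covariates, and the deforestation-legacy statistic
   `Dist_Time` (area under the point's annual distance-to-nearest-cleared-plot
   curve, in m·yr).
3. **Model** — a Bayesian multilevel regression on the standardized log scale,

   ```
   FS_i ~ Normal(mu_i, sigma)
   mu_i = alpha_LC[i] + beta_dist,LC[i]·Dist_i + beta_age,LC[i]·Age_i
        + beta_dist×age,LC[i]·Dist_i·Age_i
        + beta_T·Temp_i + beta_P·Precip_i + beta_DT·Dist_Time_i
        + beta_H·Dist_Home_i + beta_R·Dist_Roads_i
   ```

   with the intercept and the distance, age and interaction slopes varying by
   land use under partial pooling (group means ~ N(0,1), group sds and sigma
   ~ half-Student-t(3,0,1)).  Distance and age enter as log(x+1); the
   response is z-scored log(FS+1).  Fitting uses an in-package NUTS sampler
   on an analytically collapsed posterior (all Gaussian location parameters
   integrated out; exact conjugate completion per draw), 2 chains × 2000
   iterations with 500 warmup = 3000 retained draws, with rank-normalized
   split-R̂ and ESS diagnostics and posterior-predictive checks.
4. **Metrics** — conditional-effect curves in natural units over 0–2000 m,
   and from them the **penetration depth** (distance at which the curve first
   sustainedly reaches 90 % of its 2000-m value) and the signed **edge
   magnitude** (relative difference between the edge and 2000 m, in %), per
   structure variable, land use, and optionally edge age (the
   degradation-debt trajectory).
5. **Footprint** — buffer the forest inward by the land-use-specific depths,
   attribute each forest cell to its nearest plot, convert the fitted curve
   into a per-cell relative deficit `r(d) = 1 − FS(d)/FS(2000)`, and report
   affected area, degraded area (deficit ≥ 10 %), total AGB loss, and the
   loss as a share of remaining-forest AGB.

## Worked example

```python
from chacoedge import (LandscapeConfig, generate_landscape, simulate_structure,
    sample_points, standardize, EdgeEffectsRegressor, conditional_curve, curve_metrics)

land, plots = generate_landscape(LandscapeConfig(), seed=1)
simulate_structure(land, plots, seed=2)                    # fill structure rasters
points = sample_points(land, plots, n=3000, seed=3)        # space-for-time sample
design = standardize(points, "agb")
model = EdgeEffectsRegressor(include_age=False, seed=4).fit(design)
print("max R-hat:", round(max(model.rhat_.values()), 3))
for lu in ("cropland", "pasture", "silvopasture"):
    m = curve_metrics(conditional_curve(model.draws_, design, lu))
    print(f"{lu:13s} depth {m.penetration_depth_m:6.0f} m   magnitude {m.magnitude_pct:5.1f} %")
```

prints

```
max R-hat: 1.004
cropland      depth    490 m   magnitude  43.5 %
pasture       depth    171 m   magnitude  27.8 %
silvopasture  depth      0 m   magnitude   4.0 %
```

i.e. on this synthetic landscape the chains converged (R̂ ≤ 1.004), biomass
near cropland edges is depressed by ~44 % at the border and recovers to 90 %
of its interior value only ~490 m into the forest, pastures show a weaker and
shallower effect, and silvopastures show essentially none — the qualitative
ranking built into the generator.

The same analysis runs end-to-end from the shell:

```bash
chacoedge run --config examples/demo.yaml --seed 7 --outdir out/
```

producing the point table, posterior draws with diagnostics, curve and metric
tables, deficit rasters, a footprint summary, and a manifest with file hashes
(re-running with the same config and seed reproduces byte-identical outputs).

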