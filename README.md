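# beescape

Spatiotemporal landscape floral resources and wild-bee visitation
modelling for agroecosystem pollination studies.

`beescape` is for ecologists who survey bee visits on farm transects and
want to know **at which spatial radius and which within-season timescale
landscape floral resources predict local bee activity**.  It implements
the full analysis chain:

1. **Floral reward proxy** — a flower (or Asteraceae capitulum) is an
   elliptic cylinder: area `A = πab`, volume `V = πabh` with
   `a = max(length, width)/2`, `b = min(length, width)/2`, `h` the
   receptacle-to-sexual-organ height.  Validation against published
   nectar-sugar (µg/day) and pollen (µl) values uses log–log Pearson
   correlations and an ANCOVA on measurement source.
2. **Landscape resource integration** — quadrat flower counts →
   transect densities (mm³/m²) → land-type medians per period → exact
   polygon∩disc areas within 250/500/750 m buffers → total floral volume
   per (location, period, radius), with unknown land imputed two ways
   (*median* and *minimum* variants) and soybean counted only while it
   flowers.
3. **Temporal predictors** — cube-root-scale regressors: `TransectFR`,
   `PresentFR`, `FirstTimePeriodFR`, `ChangeInFR` (accumulated declines
   since the taxon's foraging onset, ≤ 0), `CumulativeFR`,
   `AllOtherVisits`, and a log observation-time offset.
4. **ZINB-GLMM** — zero-inflated negative-binomial mixed models,
   `log μ = xᵀβ + offset + u_site + v_period` with crossed random
   intercepts, fitted by Laplace-approximated maximum likelihood
   (authored here, validated against brute-force quadrature and an
   independent fixed-effects ZINB); plus zero-inflation, simulated
   residual, collinearity/VIF and Moran's I diagnostics.
5. **Hypothesis selection** — candidate families H0 (no resource
   effect), H1 (local), H2 (present landscape), H3a (onset + declines;
   single-brood genera), H3b (cumulative; multi-brood genera), each full
   and reduced, ranked by ΔAICc **summed across both imputation
   variants**; coefficients of the winner are Akaike-weight model-averaged
   (ΔAICc < 7, full averaging).
6. **Synthetic data** — a generator that emulates the study design
   (27 Voronoi-mosaic farm sites, ~102 locations, 4 periods, genus
   foraging windows, ZINB visits) with stored ground truth, so every
   stage is testable without any field data.

See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate one study-shaped season under the "onset + declines" hypothesis
(H3a) and run the whole pipeline on it:

```python
from beescape.simulate import SimulationConfig, run_end_to_end

cfg = SimulationConfig(seed=11, n_sites=8, n_locations=30,
                       hypothesis="H3a", taxon="Lasioglossum")
report = run_end_to_end(cfg)
print("winner:", report["winner"], "| truth:", report["truth"]["hypothesis"])
print(report["selection"].table[["hypothesis", "scale", "total_delta_aicc"]]
      .head(5).to_string())
```

printed:

```
winner: ('H3a', 500) | truth: H3a
  hypothesis  scale  total_delta_aicc
0        H3a  500.0          0.000000
1         H2  500.0         25.768845
2        H3b  500.0         67.233013
3         H0    NaN        105.125213
4         H1    NaN        107.187796
```

The generating family wins with a summed ΔAICc of 0 while every
competitor sits ≥ 25 units behind — at a standardized effect of 1 the
onset-resource and decline terms carry overwhelming evidence.  The
`report["selection"].averaged` tables then give the model-averaged
coefficients with 95% CIs under each imputation variant.

The same stages are available as a CLI for file-based workflows:

```bash
beescape simulate --seed 3 --hypothesis H1 --out data/
beescape validate-proxy --species data/species.csv --out proxy.json
beescape resources --patches data/patches.geojson --locations data/locations.csv \
    --quadrats data/quadrats.csv --species data/species.csv --radii 250,500,750 \
    --out resources.csv
```

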