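# stygoscale

**Scale-of-effect analysis linking terrestrial land use to groundwater
quality and groundwater-amphipod occurrence.**

Shallow aquifers used for drinking-water extraction sit under a mosaic of
forest, pasture, crop, and built land. Groundwater amphipods (stygobiotic
crustaceans such as *Niphargus*) and nitrate concentrations both respond
to that mosaic — but at what distance from the extraction site does land
use matter most, and do regulatory protection zones reach that far?
`stygoscale` packages the full analysis chain for this question, for
landscape and groundwater ecologists:

1. **Buffers** — round buffers of radius *r* around each site, and
   topography-restricted *catchment* buffers: the subset of the round
   buffer no more than 5 m below the site's elevation and connected to it
   (gaps up to 50 m bridged), approximating the surface drainage area.
2. **Scale scan** — one binomial GLM per (buffer size, buffer type,
   land-use class), `presence ~ coverage%`, scored by McFadden's
   pseudo-R² = 1 − D/D₀ with a 70%-subsampling SD. The *scale of effect*
   is the buffer size maximizing the mean pseudo-R² across class × type
   combinations.
3. **Spatial mixed models** — GLMMs with a Matérn-correlated site-level
   random effect, corr(d) = 2^(1−ν)/Γ(ν)·(ρd)^ν·K_ν(ρd):
   Gamma log-link models of nitrate vs land use, and a binomial model of
   presence vs the forest–agriculture gradient
   (100·forest/(forest+pasture+crop)) plus covariates, pruned by stepwise
   backward AIC. Estimation is Laplace-approximate ML.
4. **Zone comparison** — the identified scale interval expressed as a
   fold ratio of the median protection-zone extent, plus
   sampled-vs-random site composition tests (Wilcoxon + Bonferroni).
5. **Synthetic ground truth** — Gaussian-random-field DEMs, rank-sliced
   land-use mosaics, and presence/nitrate/zone simulators with a known
   true scale, so every stage is testable without any external data.

## Worked example

`examples/03_scale_scan.py` simulates 150 sites on an 8×8 km landscape
whose presence truth operates at 600 m, then scans 6 buffer sizes × 2
buffer types × 3 land-use classes:

```
 size_m  mean_r2  sd_of_mean  n_combos
    100   0.0903      0.0160         6
    200   0.1362      0.0271         6
    400   0.2112      0.0435         6
    600   0.2270      0.0526         6
    800   0.1984      0.0482         6
   1000   0.1293      0.0280         6

scale of effect: 600 m (truth: 600 m)
protection zones: median 315 m, 70% below 400 m; the identified scale is 1.3- to 3.2-fold larger
```

The pseudo-R² profile is hump-shaped and peaks at the true 600 m scale;
the simulated protection-zone distribution (log-normal, median ≈ 327 m)
falls well short of it — the management-relevant gap the fold ratio
quantifies. The other examples cover landscape generation, catchment
delineation, the nitrate and presence mixed models, model selection, and
the one-call pipeline (`stygoscale.pipeline.run`), which writes every
table plus a seeded manifest for byte-identical reruns.

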