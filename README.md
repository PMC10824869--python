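# reefrubble

Coral reefs hit by bleaching, cyclones or ship groundings shed large
volumes of loose skeletal fragments — rubble. Where rubble collects and
stays mobile it smothers coral recruits and can stall reef recovery for
decades, so managers need to know *which reefs have the kind of seafloor
that traps rubble*. `reefrubble` answers that question from bathymetry
alone: it samples depth profiles along transects laid across the forereef
slope, classifies every 10-m point with a moving-window decision tree, and
aggregates the flags into reef- and region-scale susceptibility metrics,
parameter sensitivities and depth/aspect effect estimates.

It is aimed at marine spatial ecologists and reef geomorphologists working
with 10-m satellite-derived bathymetry (or any gridded depth product), and
at anyone who wants a fully synthetic, reproducible test bed for
terrain-based rubble susceptibility analysis.

## The algorithm

Depths are positive-down metres. For each focal point *i* on a transect
profile, a window *W* extending 50 m (5 samples) to each side is examined
and the point **accumulates rubble** iff

1. `max(W) − min(W) < 5 m` — otherwise the point is on or near a steep
   slope and rubble rolls off to the reef base;
2. the point is not a *local topographic high* (strictly shallower than
   everything on both sides of the window); and
3. either the **depression rule** holds — the shallowest point on *each*
   side of the focal point lies ≥ 0.5 m (the rubble height *h*) above it,
   so an *h*-thick rubble layer fits below the flanks — or the **flat
   rule** holds — `max(W) − min(W) ≤ 0.5 m`.

Per transect, *potential rubble cover* is the percentage of flagged
points, reported overall and for the shallow (< 10 m) and deep sections.
Per reef, susceptibility at threshold *t* is the share of transects with
cover > *t* (critical thresholds 30/40/50%), and the *linear distance* of
susceptible slope is (count exceeding *t*) × 500 m transect spacing.
A one-at-a-time (OAT) analysis perturbs each of the four parameters by
±20% and tracks reef counts and top-decile rankings. Depth and aspect
effects on cover are estimated with a two-component beta-regression
mixture, `logit(μ_k) = x'β_k`, fitted by EM after Smithson–Verkuilen
compression `y* = (y(n−1)+0.5)/n`.

## Worked example

```bash
reefrubble simulate --reefs 4 --seed 7 --out demo_profiles.csv
reefrubble evaluate --profiles demo_profiles.csv --out summary.csv
reefrubble aggregate --summary summary.csv --out-reef reef.csv --out-region region.csv
```

stderr reports `wrote 18 profiles`, `evaluated 18 transects`,
`4 reefs aggregated`; `reef.csv` at the 30% threshold contains

```
reef_id  threshold  n_transects  n_exceeding  pct_exceeding  linear_distance_km
    R00         30            5            3           60.0                 1.5
    R01         30            4            0            0.0                 0.0
    R02         30            4            0            0.0                 0.0
    R03         30            5            0            0.0                 0.0
```

Reef R00 (a gently sloping platform) has 3 of its 5 transects with more
than 30% of their points able to trap rubble — 1.5 km of susceptible
slope — while the steeper reefs trap none at that threshold. The region
table (`region.csv`) shows the nested threshold counts: 3 problematic
reefs at the 10% threshold, 1 at 30%.

The same stages are available as library calls (`make_profile`,
`evaluate_transect`, `reef_susceptibility`, `run_oat`,
`fit_beta_mixture`, ...); `reefrubble all --demo --out out/` runs the whole
pipeline on a packaged synthetic reef set and writes a manifest.

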