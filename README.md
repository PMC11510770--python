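# portair

Regional-baseline / local-emission separation and QA for low-cost NO and
NO₂ sensor networks in port environments.

Container terminals are intense, spatially patchy NOx sources: individual
trucks and ships produce minute-scale concentration spikes that hourly
regulatory analyzers cannot resolve. Dense networks of low-cost
electrochemical sensors can — once calibrated — and their high-resolution
series can be split into a slowly varying **regional background** and a
spiky **local emission signal**, quantifying how much of the pollution at
each site is made on the spot. `portair` is for air-quality researchers and
practitioners who want that workflow as a tested library and CLI rather
than a one-off script.

## The method

Each calibrated series is modeled as `C(t) = B(t) + L(t)`. The background
`B` is estimated with the **lowest-percentile method**: the series is cut
into 8-h windows anchored at local midnight; each window contributes an
anchor `(t_center, q_p)` where `q_p` is its low empirical quantile
(p = 0.01 by default, effectively the window minimum); the anchors are
smoothed into a continuous curve with a thin-plate regression spline whose
penalty is chosen by generalized cross-validation; and `L = C − B` (clipped
at zero). Per-series contributions are `local% = 100·mean(L)/mean(C)` and
`regional% = 100 − local%`.

Upstream of that, raw sensor signals are field-calibrated by OLS against a
colocated reference analyzer, `ref ~ 1 + raw + T + RH`, and scored with

```
RMSE = sqrt( Σₜ (Sensorₜ − Refₜ)² / (N − 1) )
R²   = 1 − Σₜ (Sensorₜ − Refₜ)² / Σₜ (Sensorₜ − R̄ef)²
```

Downstream, the package computes per-site summary statistics, pooled
functional-zone statistics (outer ring OR, surrounding roads SR,
operational areas OA, berthing areas BA), diurnal profiles, NOx = NO + NO₂
mass sums, NO/NOx oxidation ratios, and ppb↔μg/m³ conversion. A synthetic
campaign generator with known ground truth (`portair.synth`) stands in for
raw network data and drives all recovery tests; see `docs/methods.md`.

## Worked example

```python
from portair import decompose, default_scenario, generate_network, site_nox_table

# a 17-site, 21-day synthetic campaign with known truth
bundle = generate_network(default_scenario(seed=0))
st = bundle.channels[("8", "NO")]          # an operational-area site
dec = decompose(st.total_true)
truth = 100 * st.local.values.mean() / st.total_true.values.mean()
print(f"site 8 NO: mean {st.total_true.values.mean():.0f} ug/m3, "
      f"local {dec.local_fraction:.1f}%, regional {dec.regional_fraction:.1f}%")
print(f"generator truth: local {truth:.1f}%")

# published campaign statistics: NOx sums and oxidation ratios
table = site_nox_table().set_index("site_id")
print(table.loc[["8", "1"], ["no_mean", "no2_mean", "nox_mean_rounded", "no_nox_1dp"]])
```

prints

```
site 8 NO: mean 263 ug/m3, local 86.1%, regional 13.9%
generator truth: local 92.1%
         no_mean  no2_mean  nox_mean_rounded  no_nox_1dp
site_id
8         289.78     80.30               370         0.8
1          47.36     41.86                89         0.5
```

The decomposition attributes 86% of this busy site's NO to local emissions
against a generator truth of 92% — the few-point shortfall is the method's
known bias at plume-dense sites (night-time anchors ride on overlapping
plume tails; see `docs/methods.md`). The table reproduces the published
per-site arithmetic: site 8 carries the network-maximum NOx of 370 μg/m³
with an NO/NOx ratio of 0.8 (fresh, little-oxidized emissions), site 1 the
minimum of 89 μg/m³.

## Command line

```
portair synth     --out data/ --seed 1            # synthetic campaign + truth
portair calibrate --raw ... --ref ... --met ...   # OLS calibration model (JSON)
portair validate  --sensor ... --ref ... --out .. # R2 / RMSE per channel
portair decompose --input data/truth_total.csv --out dec/
portair summarize --input ... --sites ... --out summaries/ [--plot]
portair run       --config pipeline.yaml          # whole pipeline + manifest
```

Logs go to stderr, results only to files; exit codes distinguish config
(2), data (3) and numerical (4) failures.

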