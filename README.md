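# nanorisk

Probabilistic occupational risk assessment for airborne nanomaterials.

`nanorisk` implements the four classical risk-assessment steps as a
reproducible Monte Carlo pipeline for inhalation exposure to engineered
nanomaterials (the packaged reference scenario covers single-walled
carbon-nanotube film production):

1. **Dose–response assessment** — continuous benchmark-dose (BMC)
   modeling of animal inhalation data: five mean families (linear,
   quadratic polynomial, power, Hill, exponential) fitted by maximum
   likelihood on per-group summary statistics, benchmark response of one
   control-group SD, one-sided 95% profile-likelihood bounds
   (BMCL/BMCU), reliability screening, and Akaike-weighted model
   averaging into lognormal BMC_a/BMCL_a/BMCU_a summaries.
2. **Extrapolation** — the animal BMCL is divided by stochastic
   interspecies, intraspecies and residual uncertainty factors to give a
   human guidance value

   BMC_h = BMCL_a / (EF_inter × EF_intra × UF)  [µg/m³],

   sampled by Latin hypercube Monte Carlo with an exact
   product-of-lognormals closed form carried as a cross-check.
3. **Exposure assessment** — per (measurement technique, work event)
   cell, a lognormal is moment-matched to the published arithmetic mean
   and SD of the mass concentration: σ² = ln(1 + (SD/mean)²),
   GM = mean/√(1 + (SD/mean)²).
4. **Risk characterization** — the risk characterization ratio
   RCR = EXP / BMC_h is sampled elementwise; P(RCR ≥ 1) is the
   probability of a relevant occupational risk, and a work event is
   significant when that probability reaches 95%. A nominal range
   sensitivity analysis attributes the RCR swing to each input.

Every distribution is carried as (GM, GSD) — the geometric mean /
geometric standard deviation convention of occupational hygiene — and
all randomness flows from one root seed through named child streams, so
runs are bit-reproducible.

## Worked example

```python
from nanorisk import ScenarioConfig, run_scenario

res = run_scenario(ScenarioConfig.paper_scenario(seed=1))
print(res.bmch_dist.gm, res.bmch_dist.gsd)
print(res.risk_table[["mt", "we", "gm", "gsd", "significant",
                      "probability_pct"]].to_string(index=False))
```

prints (10,000 Latin hypercube iterations):

```
10.000032797796393 1.4948114064418356
 mt  we    gm  gsd significant  probability_pct
MT1 WE1 0.081  1.6          no              0.0
MT1 WE2 0.100  1.5          no              0.0
MT1 WE3 0.120  1.5          no              0.0
MT1  WH 0.120  1.6          no              0.0
MT2 WE1 0.052  7.2          no              6.7
MT2 WE2 2.500  1.5         yes             98.2
MT2 WE3 0.280  3.7          no             16.8
MT2  WH 0.200  5.0          no             15.6
MT3 WE1 0.057  2.5          no              0.1
MT3 WE2 0.160  1.8          no              0.1
MT3 WE3   NaN  NaN        n.a.              NaN
MT3  WH 0.038  5.5          no              2.9
```

The human guidance value resolves to GM ≈ 10 µg/m³ (GSD ≈ 1.5). Each
row is one work event characterized by one measurement technique: WE1
is film production with local exhaust ventilation, WE2 production
without it, WE3 reactor cleaning, WH whole working hours; MT3/WE3 was
not measured. Only production without ventilation (MT2/WE2) carries a
statistically significant risk: its RCR distribution has geometric mean
2.5 and 98.2% of its mass at or above 1. The accompanying sensitivity
table shows that the three extrapolation factors dominate the RCR
uncertainty (≈27% each), exposure contributes ≈17%, and the animal
BMCL is nearly negligible (≈0.7%).

The same run is available from the shell:

```sh
nanorisk run-all --seed 1 --out-dir out/
```

which writes `bmd_fits.csv` (when animal data are supplied),
`bmch.csv`, `exposure_table.csv`, `risk_table.csv`, `sensitivity.csv`
and a `run_manifest.json` recording the seed and settings. See
`nanorisk --help` for the `bmd`, `extrapolate`, `exposure`, `risk`,
`sensitivity`, `validate` and `simulate` subcommands.

## Layout

- `src/nanorisk/distributions.py` — lognormal algebra, moment matching,
  Latin hypercube sampling, seed derivation
- `src/nanorisk/bmd.py` — continuous benchmark-dose engine
- `src/nanorisk/extrapolation.py` — uncertainty-factor extrapolation
- `src/nanorisk/exposure.py` — exposure distributions and the packaged
  measurement table
- `src/nanorisk/risk.py` — RCR, exceedance probability, significance
- `src/nanorisk/sensitivity.py` — nominal range sensitivity analysis
- `src/nanorisk/synthetic.py` — ground-truth data generators
- `src/nanorisk/config.py`, `pipeline.py`, `cli.py` — scenario
  configuration, orchestration, command line

`docs/methods.md` documents the statistical model, defaults and known
limitations.
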