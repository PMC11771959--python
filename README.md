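# aeroforage

Analysis pipeline for studying how an aerial insectivore foraging from a
central breeding colony responds to the abundance of its airborne insect
prey.  It joins two data streams:

* **Reverse-GPS tracking fixes** (ATLAS-style time-difference-of-arrival
  localizations: tag id, timestamp, planar x/y in meters, localization
  standard error *StdLoc*, number of receiving base stations *NBS*), and
* **Vertical-beam radar echoes** (timestamp, altitude, radar cross section,
  target class), summarized as the insect **movement traffic rate (MoTR)** —
  the number of insects crossing a 1 km transect per hour.

It is written for movement ecologists who want a tested, reusable and fully
simulatable version of this analysis: every stage can be exercised on
synthetic data with known ground truth, so filters, metrics and models are
verifiable without any field data.

## What it computes

1. **Fix filtering** — daylight restriction, then four quality filters with
   full attrition accounting: flight speed > 30 m/s (iterative later-fix
   removal), StdLoc above a pooled Tukey fence (Q3 + 1.5·IQR), NBS < 4,
   consecutive displacements > 500 m, and exclusion of days with fewer than
   four active tags.
2. **Solar timing** — NOAA-style sunrise/sunset (zenith 90.833°) anchoring
   all timing metrics.
3. **Behavioral metrics per day** — mean/max distance from the colony, daily
   route (only for tags with ≥ 10 h of consistent activity), foraging
   duration and its day-length-standardized complement
   (net = day length − foraging), colony visits (reception gaps ≥ 60 s
   bounded by near-colony fixes — the colony building blocks reception),
   visit frequency, mean flight speed, evening arrival / morning departure
   offsets within a ±60 min window around sunset/sunrise, roost duration,
   and mean inter-individual distance (5-min clock-aligned bins, ≥ 4 birds).
4. **Radar MoTR** — per-echo transect normalization `1000 m / w(altitude)`
   with `w(a) = 2·a·tan(θ/2)` for a conical beam (default θ = 105°, band
   50–700 m, RCS ≥ 3 mm², local window 05:00–20:00); daily MoTR is the mean
   of the 15 hourly values.
5. **Inference** — gamma (log link) and Gaussian GLMs, Spearman rank
   correlations, maximum-likelihood distribution choice, AICc
   (`−2logL + 2k + 2k(k+1)/(n−k−1)`), Akaike weights, all-subsets model
   averaging (full average over the Δ < 2 set), and a ten-prediction model
   battery relating daily behavior to MoTR.
6. **Synthetic data** — a generator producing fix/echo tables plus a truth
   record: truncated-gamma daily MoTR, out-and-back foraging trips whose
   log distance, visit rate, heading concentration and arrival time are
   linear in MoTR, reception-gap visits, ~10 m localization noise, gross
   outliers, heavy-tailed StdLoc and low-NBS dropouts, and a Poisson echo
   stream whose expected daily MoTR equals the configured truth.

## Worked example

```python
from aeroforage import run_all
from aeroforage.config import RunConfig, TruthConfig

cfg = RunConfig(seed=1, truth=TruthConfig(n_days=31, tags_per_day=6,
                                          fix_interval_s=15))
out = run_all(cfg, "runs/demo")   # simulate -> filter -> metrics -> MoTR -> fit
```

With this seed the run simulates 501,487 fixes and 387,961 echoes over 31
days.  The attrition report (`attrition.json`) shows the filter chain at
work — fractions of the daylight fix count removed per stage:

```
speed 0.1008   stdloc 0.1049   nbs 0.0397   jump 0.0101   min_tags 0.0
total removed 0.2556          StdLoc fence 17.0 m
```

(the generator injects 10% gross outliers, 10% StdLoc contamination and 4%
low-NBS fixes, so the chain is recovering the defect rates it was given).
`model_report.json` holds the fitted battery; the directional effects of
MoTR, all recovered with the expected sign at n = 31 days:

```
mean distance     (gamma GLM)  estimate -0.000507  t -3.71  p 0.0009
max distance      (gaussian)   estimate -4.41      t -3.08  p 0.0044
visit frequency   (gamma GLM)  estimate +0.000464  t  6.36  p <0.001
evening arrival   (gaussian)   estimate -0.00975   t -7.57  p <0.001
inter-indiv dist  (gamma GLM)  estimate -0.000221  t -4.54  p <0.001
```

i.e. on insect-rich days the simulated birds forage closer to the colony,
visit it more often, arrive earlier in the evening and fly closer together —
and the pipeline measures exactly that from the raw fix and echo tables.

The same stages are available as a CLI:

```bash
aeroforage simulate --seed 1 --config cfg.yaml --out-dir runs/demo
aeroforage filter   --fixes runs/demo/fixes.csv --out-dir runs/demo
aeroforage metrics  --fixes runs/demo/fixes_filtered.csv --out runs/demo/metrics.csv
aeroforage motr     --echoes runs/demo/echoes.csv --out runs/demo/motr_daily.csv
aeroforage fit      --metrics runs/demo/metrics.csv --motr runs/demo/motr_daily.csv \
                    --out runs/demo/report.json
aeroforage run-all  --seed 1 --out-dir runs/demo   # everything at once
```

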