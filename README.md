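# benthicsplit

Automated splitting of marine species-occurrence databases into **benthic**
and **pelagic** subsets, for biodiversity informatics and macroecological
gap analysis.

Open-access occurrence repositories (OBIS-style Darwin Core exports) record
an observation depth but not whether the organism was living on the seafloor
or in the water column. `benthicsplit` classifies every record by modelling
the **benthic data cloud**: the band of record depths lying just above the
seabed. For each record it compares the reported depth *d* with the seabed
depth *z* at the same location (from a GEBCO-style bathymetry grid) and
labels the record benthic when *d* is at or below a location-specific
**benthic-minimum threshold** *t(z)*:

```
label = benthic   if d >= t(z)
        pelagic   otherwise,        30 m <= t(z) <= z
```

The threshold curve is learned from the data in three steps:

1. **Depth horizons.** Records whose seabed depth matches one of 14
   predefined horizons (100–6000 m by default) form training subsets; each
   subset is trimmed at the 95th percentile of record depth to discard
   erroneous entries deeper than the bathymetry allows.
2. **k-medoids clustering.** Within each subset the (0–1 normalised) record
   depths are clustered with PAM (exact, via a globally optimal 1-D dynamic
   program; the CLARA subsampling strategy above a size threshold), testing
   k = 2..10 and selecting k by maximum average silhouette width (ASW). The
   cluster whose depth range contains the horizon's seabed depth is the
   benthic cloud; its shallowest member is that horizon's *benthic minimum*.
3. **Threshold smooth.** The 14 (seabed depth, benthic minimum) pairs are
   fitted with a penalized cubic B-spline (Gaussian errors, identity link,
   second-order difference penalty, GCV-chosen smoothing) giving *t(z)* at
   any seabed depth, clamped into [30 m, z].

The package also computes the standard gap-analysis summaries (1°×1° grid
counts, hemisphere fractions, depth medians, kernel-density profiles along
latitude and depth, top-phylum tallies, seafloor-coverage fractions) and
ships a synthetic-data generator with known ground truth so the whole
pipeline is testable offline.

## Worked example

Generate a synthetic study (50,000 records over a shelf–slope–abyss
bathymetry with a 66% benthic mix) and run the full pipeline:

```
$ benthicsplit simulate --out-dir demo --seed 7
wrote 50000 records to demo

$ benthicsplit run demo/occurrences.csv demo/bathymetry.nc --out-dir demo/out --seed 7
50000 raw -> 50000 classified (34191 benthic + 15809 pelagic); manifest: demo/out/manifest.json
```

`demo/out/` then contains the labelled records (`classified.csv`), the
per-horizon audit, the fitted threshold model (`model.json`), gridded
counts, a summary report and a run manifest whose conservation ledger
reconciles every stage (raw = valid + rejected; classified = benthic +
pelagic). Highlights from this run:

- 14 horizon envelopes used; ASW of the chosen solutions 0.58–0.99
  (e.g. horizon 250 m: k = 2, ASW 0.84, benthic minimum 177 m);
- threshold smooth: effective degrees of freedom 2.0, 98.7% of deviance
  explained — the generated benthic minima are nearly linear in seabed
  depth, and the penalized smooth recognises that;
- benthic median depth 3175 m vs pelagic median 131 m, 79% of both classes
  from the northern hemisphere — the marginal structure the generator was
  asked for.

Because the generator records true labels, recovery can be scored exactly
(`evaluate_recovery`): at these settings the pipeline relabels ~98% of
records correctly, and records reported deeper than the seabed (a classic
data-entry error) are flagged by `qc_flag` while remaining in the benthic
class.

Equivalent library calls:

```python
from benthicsplit import (GeneratorConfig, make_bathymetry, simulate_records,
                          evaluate_recovery)
from benthicsplit.pipeline import PipelineConfig, run_pipeline

grid = make_bathymetry(seed=7)
cfg = PipelineConfig(seed=7)
records, info = simulate_records(cfg.generator, grid)
manifest, results = run_pipeline(cfg, records, grid, out_dir="demo/out")
print(evaluate_recovery(results["classified"], records).accuracy)
```

Real data drop in the same way: an OBIS export (CSV with
`decimalLatitude`, `decimalLongitude`, `depth`, `phylum`, ...) plus a
GEBCO-style NetCDF elevation grid.

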