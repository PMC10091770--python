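# palaeodiv

Occurrence-based palaeodiversity analysis for the Palaeozoic ray-finned
fish (Actinopterygii) fossil record — and, more generally, for any
literature-compiled fossil occurrence table with taxon, locality,
stratigraphy and description-year fields.

Raw ("face-value") richness curves computed from such compilations are
notoriously entangled with sampling effort: bins with more sampled
localities, more rock units and wider spatial coverage tend to yield more
taxa whether or not true diversity changed. `palaeodiv` implements the
standard first-pass workflow for confronting that problem:

1. **Clean** the occurrence table: drop taxonomically indeterminate
   records and records known only from scales or teeth, keeping
   genus-determinate material; normalise open nomenclature (`cf.`,
   `aff.`, quoted waste-basket genera like `'Elonichthys'`) into a
   qualifier flag.
2. **Bin** occurrences into composite time intervals of roughly equal
   (~9 Myr) length built from ICS stages and regional substages
   (packaged, user-editable tables), or into plain ICS stages for
   comparison. Dating resolution order is substage → stage → numeric age
   range, with an explicit straddling policy (`strict`,
   `all_overlapping`, `midpoint`).
3. **Count** sampled-in-bin genus and species richness
   (*S*<sub>bin</sub> = number of distinct taxa observed in the bin,
   no range-through interpolation) alongside three per-bin sampling
   proxies: unique localities, unique geological units, and occupied
   equal-area grid cells (deterministic zonal grid, default 50 km
   spacing).
4. **Regress** richness on each proxy, on interval length and on a sea
   level series by simple OLS, reporting slope, *R*², the two-sided
   slope *p*-value (*t*, *n*−2 df) and *n* — including freshwater-only,
   marine-only and Devonian-excluded variants.
5. **Accumulate** collector's curves: cumulative counts of species
   described through publication year, globally and by present-day
   region.

A seeded synthetic-occurrence generator with known true diversity,
per-interval/per-region sampling effort, waste-basket taxonomy and
description-year histories makes every stage testable end to end without
any external download.

## Worked example

```python
import palaeodiv as pdv
from palaeodiv.occurrences import clean_occurrences

# a synthetic record with constant true diversity (40 genera per bin)
# but sampling effort sweeping 2-60 localities per bin
cfg = pdv.scenario("flat_diversity_varying_effort")
table, truth = pdv.generate_occurrences(cfg)
table = clean_occurrences(table)

ts = pdv.load_default_timescale()
bins = pdv.load_default_scheme(ts)          # 20 bins, 5.9-12.2 Myr each
binned = pdv.assign_to_intervals(table, bins, ts)

suite = pdv.regression_suite(table, bins, ts, pdv.build_grid(50.0))
r = suite["localities"]
print(f"richness ~ localities: R2={r.r_squared:.2f} p={r.p_value:.2g} n={r.n}")
rl = suite["interval_length"]
print(f"richness ~ interval length: R2={rl.r_squared:.2f} p={rl.p_value:.2g}")
```

prints

```
richness ~ localities: R2=0.78 p=2.3e-07 n=20
richness ~ interval length: R2=0.11 p=0.15
```

(a warning notes that the sea-level panels are skipped when no sea-level
series is supplied).

True diversity is flat by construction, yet sampled richness tracks the
number of localities almost perfectly — the textbook sampling artefact
this workflow is designed to expose — while bin duration (deliberately
near-equalised by the composite scheme) explains nothing.

The same analysis is available from the shell:

```bash
palaeodiv simulate scratch/sim --scenario flat_diversity_varying_effort
palaeodiv report scratch/sim/occurrences.csv scratch/report
```

which writes the dataset summary, per-bin richness/proxy series for both
binning schemes, the regression table, collector's curves and a JSON run
log.

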