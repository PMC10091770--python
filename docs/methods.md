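# Methods

This note documents the models, conventions and numerical choices behind
`palaeodiv`, in the order the pipeline applies them.

## Occurrence model and cleaning rules

An occurrence is one record of a taxon at a geographic locality in a
dated stratigraphic context. The canonical schema (the native CSV
dialect) carries taxonomy (genus, species, qualifier), geography
(locality name, WGS84 coordinates, country, one of nine present-day
regions), stratigraphy (geological unit, ICS stage, regional substage,
optional numeric age range in Ma), environment (marine/freshwater/
unknown), material (body fossil, scales only, teeth only, other),
authority and the year the species was described. A mapping from
standard Paleobiology Database occurrence-download columns is provided.

Cleaning retains only body fossils confidently assigned at least to
genus level:

* records with `qualifier = indet` (no valid genus) are dropped;
* records known solely from scales or teeth are dropped;
* genus-determinate but species-indeterminate records (`Genus sp.`) are
  **kept** — they inform genus-level counts but are ignored by
  species-level counts;
* open nomenclature (`cf.`, `aff.`) and quoted waste-basket genus names
  (`'Elonichthys'`) are preserved as a qualifier and count toward the
  named taxon. The rationale is that these qualifications express doubt
  about affinity, not about the existence of a distinct record, and
  waste-basket species are conventionally tallied under their genus.

Cleaning is idempotent, and each rule logs the number of records it
removed, so `n_kept + n_removed = n_input` is checkable.

Locality identity is the canonicalised locality name plus coordinates
rounded to 2 decimal degrees (~1 km). Literature sources frequently
report the same site with slightly different coordinates; rounding
absorbs that jitter without merging genuinely distinct sites.
Geological-unit identity is the canonicalised unit name (formation
preferred where several ranks are given).

## Timescale and composite intervals

Ages are Ma before present, positive, older = larger. All membership
tests use half-open spans `[end_ma, start_ma)` that include the younger
bound, so a datum dated exactly to a stage boundary belongs
deterministically to the older bin.

The packaged stage table holds ICS boundary ages (2021 chart usage) for
Lochkovian–Changhsingian; it is plain CSV and user-replaceable. Two
useful sanity anchors: the Kasimovian spans 3.3 Myr and the Visean
15.8 Myr, the extremes that motivate equal-length binning in the first
place. Regional substage spans (Bohemian Emsian subdivisions; British
Dinantian/Namurian substages Chadian–Brigantian, Pendleian,
Arnsbergian; an early/late Famennian split at 365.0 Ma) are likewise
packaged as editable CSV. Published numeric ages for several of these
substages are genuinely uncertain; the packaged values follow common
regional usage and exist chiefly so that long stages can be split and
inconsistently filed records can be re-placed.

The packaged equal-length scheme tiles Lochkovian–Changhsingian with 20
composite bins, each 5.9–12.2 Myr (mean 8.4 Myr, target ~9 Myr),
by merging short stages (Lochkovian+Pragian, Eifelian+Givetian,
Kasimovian+Gzhelian, Asselian+Sakmarian, Wordian+Capitanian,
Wuchiapingian+Changhsingian) and splitting long ones at substage
boundaries (Emsian → Zlichovian/Dalejan; Famennian → early/late;
Visean → Chadian–Holkerian / Asbian–Brigantian). Where the historical
record of which merges were used is ambiguous (chiefly the Guadalupian–
Lopingian), the scheme takes the most duration-balanced admissible
partition: {Roadian}, {Wordian–Capitanian}, {Lopingian}; the Capitanian
alone (4.8 Myr) would fall outside the 5–13 Myr band the scheme is
designed to stay within. Scheme construction validates contiguity of
each composite's members, non-overlap and gap-freedom of the whole
scheme, and round-trips losslessly through its CSV form.

## Binning policies

Dating resolution order per record: substage span if present, else
stage span, else `[min_ma, max_ma]`. The substage wins even when it
contradicts the named stage, because regional substage assignments are
generally the better-constrained datum (the classic case being
Arnsbergian localities filed under the Bashkirian that belong in the
Serpukhovian).

Three policies handle spans that straddle bin boundaries. `strict`
(default) assigns only spans lying wholly within one bin — the most
conservative reading of "sampled in bin" — leaving e.g. a bare "Visean"
record unassigned under the split-Visean scheme. `all_overlapping` and
`midpoint` are exposed for sensitivity analysis. Every record lands in
exactly one of *assignments* or *unassigned* (with a reason), so record
totals are conserved across schemes and policies.

## Richness and sampling proxies

Sampled-in-bin richness is the number of distinct genera (or species
binomials, among species-determinate records) assigned to a bin; bins
with no assignments are reported as zero, not omitted. No range-through
counting, no subsampling standardisation (rarefaction/coverage-based
estimators are deliberately out of scope).

Three per-bin effort proxies: unique localities, unique geological
units, occupied equal-area grid cells. Deduplication is within-bin; a
locality sampled in two bins counts once in each. These satisfy
`grid_cells ≤ localities ≤ occurrences` per bin by construction.

## Equal-area grid

The grid is a zonal equal-area partition parameterised by a target
spacing (default 50 km). The total cell count is
`round(4πR²/s²)` (R = 6371.0088 km); latitude bands
(`round(πR/s)` of them) receive cells by largest-remainder
apportionment of `N · Δsin(φ)/2`, and band boundaries are then placed
in sin(latitude) so each band's area share equals its cell share.
Consequently **every cell has exactly the same area**; cells are
near-square away from the poles. Construction is fully deterministic —
no random orientation — so grid-dependent statistics are reproducible
bit-for-bit. Published analyses built on external icosahedral
discrete-global-grid software are not exactly reproducible (the mesh
orientation is not recoverable from methods text), so replicated
grid-cell statistics carry a tolerance (±0.05 on R² is used in the
acceptance checks). Present-day coordinates only; no palaeorotation.

Boundary conventions: a point exactly on a band or cell boundary
resolves to the lower-index side; poles belong to their adjacent band.

## Regressions

Each fit is simple OLS (via statsmodels) of per-bin richness on one
covariate, on raw counts — no log transform by default (a `log_y`
option exists). R² is the coefficient of determination, identical to
the squared Pearson correlation for simple regression (cross-checked in
tests); the p-value is the two-sided t-test of zero slope with n−2 df.
Bins missing on either side are dropped pairwise and counted. Zero
covariate variance and n < 3 raise immediately rather than returning
degenerate statistics.

Sea level is aggregated to bins by the within-bin mean of the series
samples (default) or by linear interpolation at the bin midpoint; the
choice matters little for smooth series and both are exposed because
the aggregation used in prior work is unstated. The nine-panel suite
covers overall genus richness against the three proxies, interval
length and sea level, freshwater-only and marine-only richness against
sea level, and the sea-level fits with Devonian bins (bins older than
358.9 Ma) excluded. No multiple-testing correction, GLS or
autocorrelation adjustment is applied — the suite replicates the plain
first-pass analysis, and its p-values should be read accordingly.

## Collector's curves

Each species enters once, at its earliest description year across all
its records; regional attribution follows the region of that
earliest-described record, ties broken alphabetically (a deterministic
rule; the convention used in prior compilations is unstated). Species
without a description year are excluded. Regional final counts
therefore sum exactly to the global total. Curves are stored sparsely
(only years with new species) and can be densified for plotting.

## Synthetic-data generator

The generator realises the qualitative structure the analysis discusses,
not a taphonomic model:

* **Effort**: locality counts ~ Poisson(rate) per (interval, region);
  occurrences per locality ~ geometric with mean 3 (≥1), giving
  overdispersed compound-Poisson bin totals with analytic expectation
  `Σ rates × mean` (tested against simulation).
* **Taxonomy**: per-bin true genus pools are nested (bin richness R
  uses the first R names of a global pool), so richness is comparable
  across bins. Genus abundances follow a rank-frequency law
  rank^(−e); the default exponent is e = 0.5 — a mild dominance
  gradient, chosen because genus-level rank-abundance within a time bin
  is far flatter than within-genus species skew, and because at the
  preset sampling intensities it lets sampled richness track true
  richness (the documented purpose of the trend-recovery preset).
  Species-per-genus counts are Zipf(1.5)-distributed (truncated at 40),
  yielding a few large waste-basket genera among many monotypic ones;
  species within a genus follow a rank^(−1) abundance law.
* **Cleaning targets**: indeterminate and scales-only flags are
  independent Bernoulli draws, so the expected cleaned fraction is
  `(1−p_indet)(1−p_scales)` (tested).
* **Description years**: per species, start year (1830) plus an
  exponential waiting time (rate 0.015/yr), capped at 2022.
* **Dating**: each occurrence is stamped with a stage or substage drawn
  uniformly from its bin's members, so strict binning recovers the
  generating bin exactly.

One seeded NumPy generator drives everything in a fixed iteration
order; a configuration regenerates byte-identically.

Two presets define reference conditions. `flat_diversity_varying_effort`
(constant 40 genera, locality rates sweeping 2–60 across bins) is the
bias demonstration: the richness–localities slope is positive and
significant (p < 0.05) in ≥95 of 100 replicates even though true
diversity is flat. `trending_diversity_uniform_effort` (richness ramp
5→80, constant rate 30) is the recovery check: Spearman ρ between true
and sampled richness is ≥0.8 in ≥95 of 100 replicates.

What the generator does *not* emulate: spatially autocorrelated
sampling, Lagerstätten (single sites contributing huge within-site
diversity), taphonomic or body-size filters, synonymy error, and
palaeogeographic drift. Passing tests therefore show the *pipeline* is
correct and the analysis behaves as designed under known conditions —
not that real compilations satisfy those conditions.

## Problem sizes and determinism

Replicate-based checks use 100 replicates per preset (a few thousand
occurrences each) and oracle-based checks use 100 random small tables;
both complete in seconds. `scripts/acceptance.py` derives every seed
from its `--seed` argument. The packaged analysis contains no other
source of randomness: given the same inputs, every output file is
byte-identical across runs.

## Known limitations

* Substage boundary ages are approximate and editable; analyses that
  hinge on precise substage spans inherit that uncertainty.
* The equal-length scheme is a reconstruction constrained by the stated
  merges/splits and the 5–13 Myr band; other admissible Permian
  partitions exist.
* Occupied-cell counts depend on grid orientation near cell boundaries;
  comparisons against counts from other grid systems should use a
  tolerance.
* Face-value richness and these regressions are diagnostic, not
  corrective: the package deliberately stops short of subsampling
  standardisation.
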