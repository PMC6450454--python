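# Methods

## Model

The package measures inequity in acute-care utilization for an
ambulatory care sensitive condition as a set of observed-to-expected
ratios. All counting happens in demographic strata g: half-open integer
age bands × race/ethnicity categories × genders. The default grid is
3 × 4 × 2 = 24 cells (bands 20–44 / 45–64 / 65+, categories AA,
Hispanic, White (non-Hispanic), Asian/Other; both lists are config).
Ages below the lowest band are flagged out of range and reported, never
silently binned; a patient whose age crosses a band boundary within the
window is counted as a patient in both strata, which keeps observed
counts additive over time windows.

**Catchment.** The facility's catchment area is the smallest set of
census tracts holding at least τ (default 0.80) of its distinct
patients, built greedily in descending patient-count order with ties
broken by ascending tract id. The greedy prefix is provably a
minimum-cardinality covering set (any k tracts hold at most as many
patients as the top k), and the tie rule makes it unique and
deterministic. The patient basis is all-cause by default
(condition-specific is a config switch), and the catchment is
recomputed per analysis window unless a frozen one is supplied.

**Expected counts.** For each stratum, E_g = Pop_g · prev_g · u · f
with Pop_g the catchment population, prev_g the resolved prevalence,
u = U/P_total the average utilization propensity (distinct observed
patients over the estimated condition population P_total = Σ Pop_g
prev_g) and f = C/U the average encounters per observed patient. u and
f are deliberately *not* stratum-specific: stratum-specific rates would
make every ratio identically 1. Using the pooled averages encodes the
equitable-utilization counterfactual and gives the conservation
identity Σ E_g = Σ O_g exactly (u·f = C/P_total), hence also a unit
E-weighted mean score. Two invariances follow and are property-tested:
E_g is unchanged under any uniform scaling of tract populations and
under any uniform scaling of the prevalence table (u absorbs both).

**Prevalence resolution.** Public prevalence sources publish at mixed
granularity, so each stratum resolves its prevalence through a
most-specific-first chain — full stratum → race×age → race → age →
overall — and the level used is recorded in the output table. An
overall entry is mandatory for the configured condition, so resolution
cannot fail on valid inputs.

**Scoring.** HES_g = O_g/E_g for strata with E_g > 0. E_g = 0 with
O_g = 0 is undefined-but-benign (excluded silently); E_g = 0 with
O_g > 0 is flagged invalid and excluded from the index with a warning —
capping would invent a number, exclusion is auditable. The index is
1 + Σ_X w_g (HES_g − 1), with X the valid strata scoring above 1 and
weights w_g = O_g renormalized over X. Weighting by *observed*
encounters over the *excess* set matches the reading of the index as
"the weighted average excess among groups above expectation". An
all-strata variant (weights over all valid strata, excess clamped at 0)
is available as `index_weighting="all"` for sensitivity analysis.

A property boundary worth knowing: under the default excess-only
weighting, moving one encounter from a non-excess stratum into a
barely-excess stratum can *lower* the index, because the receiving
stratum's weight grows faster than its excess (e.g. HES (4.0, 1.1) with
O (40, 11), E (10, 10)). The all-strata variant has a fixed denominator
and is monotone under such moves; the test suite pins both behaviours.
No sampling uncertainty is attached to the index; it is a descriptive
ratio.

## Synthetic data and what passing tests show

The generator emulates the three input tables under a known mechanism:
tract populations split each stratum total over 12 tracts by a
Dirichlet(1) share vector plus one "far" tract holding 5% (so the 80%
rule genuinely excludes someone); carriers ~ Binomial(Pop, prev);
patients ~ Binomial(carriers, u0·m_g); encounters per patient
1 + Poisson(λ0), guaranteeing f ≥ 1. Planted multipliers m_g act on
propensity by default; a frequency mode scales the mean encounters per
patient by m_g instead (Poisson rate (1+λ0)m − 1, valid for
m ≥ 1/(1+λ0)). In both modes m enters the observed counts only through
the u·f product, so one closed form covers both:

    HES*_g = m_g / m̄,   m̄ = Σ_g π_g m_g,

with π_g the condition-population shares. The expected index follows by
applying the index definition to HES* with weights π_g m_g.

Default scenario conditions, chosen once: calendar-2016 window, one
facility, 10,000 residents per stratum, overall prevalence 0.089 (the
scale of adult asthma prevalence in California), u0 = 0.10, λ0 = 0.35
(mean frequency 1.35, the scale of the motivating ED example of 877
encounters from 649 patients). The recovery experiment scores
independent replicates (seeds spawned from one master seed) and
compares mean per-stratum scores with HES*; at 10⁵ residents per
stratum the maximum absolute error stays below 0.05 over 20 replicates,
and under m ≡ 1 the index concentrates near 1 from above (it is ≥ 1 by
construction, so the null expectation is slightly above 1 at finite n —
about +0.03 at this size).

The generator does **not** emulate: realistic ICD code mixtures,
comorbidity or seasonal structure, migration between tracts, census
undercount, or disagreement between tract demographics and patient
demographics. Passing recovery tests therefore show the *estimator*
recovers planted utilization disparities under the model's own
assumptions — not that real prevalence tables or ACS denominators are
unbiased for a particular catchment.

## Numerical and I/O choices

* Counts are integers; E_g and HES are kept as floats, never rounded,
  since rounding would bias small strata. Conservation is asserted at
  1e-9 relative.
* Greedy catchment comparisons use an absolute 1e-9 slack on
  τ·total to keep integer count comparisons robust to float τ.
* Stratum and catchment CSVs are written at `%.17g` so the index is
  recomputable from the emitted stratum table alone to 1e-9; the JSON
  report rounds display values to 6 significant digits. Outputs carry
  no wall-clock fields, so identical inputs give byte-identical files.
* Monthly series default to trailing-12-month windows ending at each
  month start; calendar months are the alternative shape. Windows with
  no scorable encounters yield flagged rows, not dropped rows.
* Stoplight bands (index < 1.25 green, < 1.5 yellow, else red) are
  presentational defaults, not part of the metric.

## Problem sizes

The test suite exercises: exhaustive index-definition checks on all
1- and 2-stratum integer instances with O, E ≤ 20 plus 6,000 seeded
random 3–5-stratum instances; brute-force catchment verification on
400 random instances of ≤ 10 tracts; conservation on 100 random
scenarios at ~10³ residents per stratum; and recovery at 10⁵ residents
per stratum × 24 strata × 20 replicates. These sizes give stable
Monte-Carlo margins for the stated tolerances.

## Limitations

Tract ids must be supplied (no geocoding); no FHIR/HL7 ingestion; no
small-area prevalence estimation or raking of ACS counts; no
confidence intervals on HES or the index; no spatial contiguity or
gravity modelling of catchments. Strata with zero observed but
positive expected encounters appear in the drill-down with HES = 0 so
under-utilization remains visible.
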