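# Methods

## Record selection and displacement tables

An admission row is one event (no deduplication of transfers or
readmissions of the same newborn — administrative hospitalization tables
count authorization rows, and the package follows that convention).  The
neonatal window is the closed interval 0–27 days; ages are validated
non-negative and the filter keeps exactly `0 <= age_days <= 27`, preserving
input order.  Municipality codes are 6-digit; 7-digit codes (6 digits plus
a check digit, IBGE style) are accepted with the check digit dropped.

Neonatal records partition exhaustively and disjointly into
same-municipality, displaced in-state, and out-of-state (a reserved
sentinel code `999999`, never present in the registry).  Out-of-state
records are excluded from every metric and network, but their share among
displaced admissions is always reported, because it is the natural audit
figure (~1% under the default generator, matching the structure the
pipeline is designed for).  Displaced in-state records aggregate into one
flow per (origin, destination, biennium); the biennium is derived from the
admission year alone, with the six biennia 2008-2009 … 2018-2019 indexed
1–6.

## Distances

Distance is the great-circle (haversine) distance between municipality
*seat* coordinates on a sphere of radius 6,371 km.  Road distance, travel
time and cost are deliberately out of scope: they need a routing network
that administrative tables do not carry, and straight-line seat-to-seat
distance is reproducible from coordinates alone.  All distance statistics
are therefore lower bounds on travelled distance.

The two-level statistic (origin-level flow-weighted mean `d_i`, then
region-level outflow-weighted mean `m_j`) is algebraically identical to the
single-pass flow-weighted mean of pairwise distances over all the region's
displaced records; the test suite enforces this identity to 1e-9 relative
tolerance and it is the module's main oracle.  A region-biennium cell with
zero displaced flow has no defined weighted mean and is reported missing,
never zero.

Denominator conventions: the *displaced share* of a region divides its
residents' displaced in-state admissions by all their in-state neonatal
admissions; the *same-region share* divides intra-regional displaced flow
by total displaced flow (displaced-only denominator — shares near 100% are
only meaningful this way).  Presentation rounding is two decimals,
round-half-even; internal computation is unrounded.

## Indicators

Per region × biennium, from birth records: % live births < 1,500 g,
% gestational age < 28 weeks, % 5-minute Apgar ≤ 7, % maternal age ≥ 35
years.  TMN = deaths at age 0–27 days per 1,000 live births.  NICU beds
(types I–III pooled) per 1,000 live births use the regional bed stock
averaged over the biennium's two year-end counts — a bed census is a stock,
births are a flow, so averaging the two observed stocks is the least
arbitrary biennial summary.  Cells with zero births are missing, not zero.

## Networks

Graphs are directed and simple: parallel flows collapse into one weighted
edge, no self-loops.  Nodes are the municipalities participating in at
least one displacement of the biennium, positioned at seat coordinates and
coloured by macroregion (leste = red, noroeste = blue, norte = green,
oeste = yellow); edges carry the outflow and the origin's macroregion
colour.  In-degree counts distinct origins served by a destination; inflow
sums their admissions.  The "frequent destination" selection is all region
seats plus any municipality whose inflow reaches a configurable threshold
(default 100) in either compared biennium — the published comparisons
highlight seats plus a handful of emerging non-seat destinations without
stating a rule, so the threshold is explicit and tunable here.  GEXF and
GraphML exports round-trip all node/edge attributes through `networkx`.

## Mixed models

Trend and association models are linear with a random intercept per health
region, estimated by REML via `statsmodels` MixedLM.  The biennium is coded
1…6; the slope is invariant to that choice, only the intercept moves.
Fixed effects get Wald 95% CIs.  Variance components are reported as SDs
with a selectable CI method: the default is a log-scale Wald interval for
the random-intercept SD (from the REML information matrix, with the
log-scale SE capped near the boundary, where the Wald approximation
degenerates) and a scaled chi-square interval for the residual SD using
`n − p − n_units` degrees of freedom; a seeded parametric bootstrap
(percentile, default 200 refits) is available where the extra cost is
justified.  Covariates enter raw (unstandardized), so coefficients read as
effect per unit of the indicator.  Missing cells are dropped listwise.
Exactly collinear designs are reported with a condition-number warning and,
if estimation fails outright, a minimum-norm least-squares fallback flagged
`converged=False`.  Noise-free inputs (a panel that fits exactly) are
detected and solved by ordinary least squares, because the REML problem is
degenerate there and the mixed-model optimiser can misattribute the
intercept to the random effects.

The multivariable TMN models are nested: Model 1 has the biennium only,
Model 2 adds the flow-weighted distance, Model 3 adds the displaced share,
NICU beds per 1,000 and the four birth indicators.  No multiple-testing
adjustment is applied across the eight trend responses, mirroring the
per-indicator presentation this analysis supports.

Because coefficient values from the real state panel are functions of data
the package does not ship, the acceptance surface for the models is
*parameter recovery*: panels simulated at the study's 22 × 6 shape with a
known slope (−0.35), random-intercept SD (0.94) and residual SD (1.34 —
the scale of the fitted TMN trend) must be re-estimated with bias within
Monte-Carlo error and 95% CI coverage between 90% and 98% over 500
replicates.

## The synthetic-data generator

The generator defines the study conditions everything else is tested
under.  Geography: region patches tiled on a rectangular lattice inside
four macroregion blocks spanning a Paraná-sized bounding box; each region's
seat sits at its patch centre, other municipalities on a jittered grid.
With 22 regions the region→macroregion membership follows the standard
Paraná grouping (leste: 1–6, 21; oeste: 7–10, 20; noroeste: 11–15; norte:
16–19, 22); other region counts fall back to contiguous blocks.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| regions × municipalities | 22 × 18 | a 396-municipality state of 22 health regions |
| years | 2008–2019 | six biennia |
| admissions / muni-year | 30, growing 5%/yr | ≈190k admissions over the period with demand roughly doubling |
| displacement probability | 0.38 | displaced share of neonatal admissions in the mid-to-high 30s % |
| out-of-state probability | 0.01 | ~1% of displaced admissions leave the state |
| seat attraction, distance decay | 150, 3.0 | displaced flow concentrates on region seats (the modal destination of every region is its seat), intra-regional share ≈ 75%, state flow-weighted distance ≈ 50 km |
| neonatal age share | 0.80 | the 0–27-day filter must have a tail (28–364 d) to remove |
| births / muni-year | 375 | ≈150k live births/yr statewide |
| prevalences | <1,500 g 1.2%, GA<28w 0.45%, Apgar≤7 2.1%, ≥35y 12% | plausible vital-statistics margins for the setting |
| neonatal death rate | 8.98/1,000, −0.31 per biennium | a TMN declining from ≈9.0 to ≈7.4 across the six biennia |
| post-neonatal death rate | 2.5/1,000 | exercises the age-at-death filter |
| NICU beds | seats: mean 30 + 1/yr; non-seats: 3% chance of a few | ≈2.3–3 beds per 1,000 live births, rising, concentrated at seats |

All randomness flows from one seed through independent named generator
streams per table, so identical parameters give byte-identical tables.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: there is no dominant metropolis, so flows are
less concentrated than a real state capital makes them (more distinct OD
pairs per admission, and no non-seat municipality grows past the frequent-
destination threshold); regions are statistically exchangeable (no regional
heterogeneity in death rates or displacement propensity beyond sampling
noise, so end-to-end random-intercept SDs are near zero — the panel
simulator, not the generator, is the instrument for testing between-region
variance estimation); birth attributes are drawn independently rather than
jointly (no correlation between prematurity, weight and Apgar); and there
are no recording errors, late registrations or underreporting.

## Problem sizes

The default end-to-end dataset is ≈190k admissions, ≈1.8M births; the unit
suite additionally uses an 8 × 5-municipality state for brute-force
oracles.  The recovery study uses 500 replicates (200 in the acceptance
script, where it is one of several recomputed quantities) — enough for a
Monte-Carlo SE of ≈0.003 on the slope.
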