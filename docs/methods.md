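# Methods

## Field measures

A leaf-marking quadrat (default 10 × 20 cm, 0.02 m²) yields daily areal
leaf productivity `mass_new_g / (area_m2 · days_marked)` (g dry m⁻² d⁻¹),
foliar biomass `(mass_new_g + mass_old_g) / area_m2`, shoot density
`n_shoots / area_m2`, and growth per shoot
`mass_new_g / (n_shoots · days_marked)` — the last undefined (missing,
never 0) on a shoot-free quadrat. Annual productivity is the mean of all
of a year's per-sample daily rates, both growth seasons pooled, times
365; a strict mode that requires both seasons to be represented in the
year is available (`annual_productivity` operates on whatever samples
the caller groups) but is not the default, because sampling effort in
voluntary monitoring networks is irregular and discarding one-season
years would silently drop stations.

A core of diameter d samples π(d/2)² m². Compartment masses are divided
by that area; the above-ground community total is turtlegrass + other
seagrasses + calcareous algae (somatic, i.e. decalcified, weight; their
below-ground parts are excluded by protocol) + fleshy algae. Relative
dominances are fractions of that total; a compartment absent from a core
is a structural zero, while a zero denominator (bare core) makes the
indicator missing for that sample. The above/total ratio is computed on
turtlegrass by default and on the pooled other-seagrass group for
stations where turtlegrass disappeared (a per-station metadata choice,
`dominant_seagrass`).

Community biomass has two defensible definitions — above-ground only,
or above- plus below-ground. The trend classification shipped here uses
above-ground by default (`biomass_definition="above_ground"`), which is
the definition under which the reference trend matrix was produced; the
total definition is one flag away and both are emitted in reports.

## Intra-annual deviation statistic

For each station with at least 10 sampling events (`MIN_EVENTS_FOR_DEVIATION`),
event productivity is the mean of the event's quadrat rates, the general
mean P̄ is the unweighted mean over events, and
ΔP_e = 100 · (P_e − P̄) / P̄. By construction the ΔP of a station average
to zero; the statistic isolates the within-station seasonal signal from
the order-of-magnitude between-station differences. Stations are pooled
by floor(|latitude|) and growth season, and each cell gets a two-sided
one-sample t-test of mean ΔP = 0 (cells with < 2 events or zero variance
are reported as not testable rather than dropped silently). Season
windows: high season May–September for subtropical stations (≥ 23° N,
where warming lags the solar cycle), March–August otherwise.

Day length uses the standard solar-declination approximation
δ = 23.44° · sin(2π(284 + DOY)/365), H = (24/π)·arccos(−tan φ tan δ),
clamped to [0, 24]; no atmospheric refraction, accuracy a few minutes at
tropical latitudes, which is ample for monthly correlations. Monthly
growth–environment correlations are Pearson by default (Spearman behind
a flag); constant series yield missing correlations.

## Trend screen and tests

Eligibility per station × indicator: ≥ 5 distinct sampled years (distinct
years, not elapsed span — monitoring was intermittent at some stations),
≥ 6 distinct sampling events, and > 0 values in ≥ 50 % of samples. The
trend model is OLS of the individual sample values on integer calendar
year — samples, not annual means, are the observations, which weights
years by their sampling effort and is how the reference regressions were
fit; an annual-means mode exists for sensitivity analysis. Degenerate
series (fewer than 3 distinct years, zero variance) are not testable and
called n.

The two-sided slope test is compared against Bonferroni-adjusted levels
with *structural* families: the four core-derived indicators share
α′ = 0.05/4 = 0.0125 and the two quadrat-derived indicators
α′ = 0.05/2 = 0.025, regardless of which indicators have data at a
station — keeping α′ comparable across stations.

Known limitation: OLS on samples treats within-year replicates as
independent. When year-level shared variability is present (it is, in
real beds and in the generator's inter-annual factor), the slope test is
mildly anticonservative. The type-I control test in the suite therefore
characterizes the screen under independent sampling noise; the scenario
specificity measured on networks with inter-annual variability (below)
absorbs the residual inflation. Mixed-effects or autocorrelation-robust
alternatives are deliberately out of scope: the point of the pipeline is
the original low-cost protocol.

## Scenario classification

Expected directions under nutrient enrichment (N) and turbidity (T):
biomass I/D, other-seagrass dominance I/I, fleshy-algae dominance I/I,
above/total ratio I/I, productivity I/D, shoot density –/D. A
significant call matching one scenario only is tagged N or T; matching
both, NT (counting toward both); n or a non-matching direction, no tag.
A station with ≥ 2 same-scenario tags is flagged; when both counts reach
2 the verdict is EITHER rather than a forced choice.

Beds lost to documented non-water-quality causes (turtle or urchin
grazing, storm burial) are a *collapse* annotation supplied by the user,
never inferred: `classify_all(..., collapsed_stations=...)` suppresses
tag generation for them. In the packaged reference matrix, classification
uses the printed consistency tags directly: for non-collapse stations
these equal what the expectation matrix recomputes from the direction
letters (asserted in the suite), while for collapsed beds they encode the
network's expert judgment (the two fully collapsed northern stations
carry declining trends but no scenario tags, and correctly do not flag;
three collapse-marked stations whose printed tags do indicate
water-quality-consistent change before/alongside the collapse flag as
published).

## Synthetic data generator

The generator emulates the protocol's shape: two sampling events per
year placed at the seasonal peak and trough of the station's scheme,
4–6 quadrats and 2–4 cores per event, marking intervals of 7–14 days.
Mean structure is controlled per indicator in closed form: expected
daily productivity is `baseline · (1 + a·s(d)) · trend(t) · I_y`, with
s(d) a unit sinusoid peaking mid high-season, amplitude a forced to 0
below the seasonality-threshold latitude (default 16.8° N), trend(t) a
multiplicative linear-in-time factor per indicator (direction given by
the expectation matrix for the chosen degradation mode), and I_y a
shared per-year lognormal inter-annual factor. Core compartments are
constructed so that the above-ground total, the dominance fractions,
the above/total ratio and shoot density each follow their own trend
factor exactly in expectation. Observations multiply the expectation by
mean-1 lognormal noise (field biomass and productivity data are positive
and right-skewed), parameterized by a coefficient of variation.

Defaults, chosen to be realistic for turtlegrass reef-lagoon beds:
baseline productivity 2.0 g dry m⁻² d⁻¹ (≈ 730 g m⁻² y⁻¹, mid-range of
the order-of-magnitude spread observed across the Caribbean), shoot
density 600 m⁻², above-ground community biomass 120 g dry m⁻² with 12 %
other seagrass / 8 % fleshy algae / 5 % calcareous algae, above/total
ratio 0.22 (turtlegrass invests most biomass below ground), sampling
noise CV 0.3, inter-annual CV 0.1, degradation rate 5 %/yr in the
degradation presets. Per-station seeds derive from
`SeedSequence([master_seed, station_id])`, so network composition never
perturbs an individual station and identical configuration + seed is
byte-identical.

What the generator does *not* emulate: spatial autocorrelation between
stations, observer effects, species-level dynamics within the pooled
other-seagrass group, irregular voluntary sampling calendars, or
mechanistic light/nutrient physiology. Passing recovery tests therefore
demonstrates that the statistical pipeline detects the kinds of change
it screens for at realistic noise levels — not that real stations with
these verdicts experienced those causes.

## Operating point of the recovery check

The scenario-recovery operating point was fixed by a brute-force oracle
run of the full pipeline over the nutrient-degradation preset
(40 stations, 10 years, 2 events/yr) across ten master seeds *before*
freezing the thresholds: sensitivity 0.85–1.0 (mean ≈ 0.94) and
specificity 0.85–1.0 (mean ≈ 0.95). The residual control false-flag
rate (~5 %/station) is the inter-annual pseudo-replication effect noted
above, concentrated in the biomass–productivity pair, which shares the
yearly factor. The suite asserts ≥ 80 % sensitivity and ≥ 90 %
specificity on the default network.

Problem sizes in the suite were chosen to characterize each property
adequately at desk scale: 5 000 replicates of a 6-year no-trend station
for type-I control (Monte-Carlo standard error ≈ 0.0016 at α′ = 0.0125),
one 40-station decade-long network for recovery, and an 8-station
latitudinal gradient over 8 years (16 events per station, comfortably
above the 10-event inclusion rule) for seasonality gating.

## Numerical conventions

Tolerances: ΔP mean-zero identity and noiseless slope recovery at 1e-9;
dominance sum rule at 1e-12; areal/area-invariance checks at 1e-9.
Ties and degenerates: p = α′ exactly is *not* significant; zero-variance
cells/series are "not testable", never p = 0 or 1; missing is propagated
as None (absent record), never as 0, and structural zeros are real data.
All dates ISO-8601, masses g dry weight, areas m²; the CSV writers emit
a fixed UTF-8 '.'-decimal dialect that round-trips bit-exactly.
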