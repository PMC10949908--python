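# Methods

## Model and assumptions

`migrasim` simulates the *initial* displacement of a population under
conflict. The unit of decision is the household: person agents form daily
migration intents individually, but households act as a bloc — when a
household migrates, every member migrates with it, on the same day and with
the same classification (refugee or internally displaced). A person's
location is their household's location for the entire simulation; there is no
destination choice, no return migration, and no onward movement of the
already displaced. These are modeling choices, not omissions: the framework
targets the shock phase of a conflict, when data are scarcest and flows are
dominated by first departures.

The daily loop applies, in order: (1) the impact kernel and attitude sum over
past events, (2) the perceived-impact memory recursion, (3) the logistic
individual probability, (4) intra-household averaging, (5) a Bernoulli
initial household decision, (6) one synchronous peer-threshold pass over the
household network, (7) refugee/IDP classification, and (8) removal of
migrated households. The threshold pass reads *initial* decisions only
(`m'`), so there is no fixed-point iteration within a day, and already
migrated households contribute zero to neighbor sums — removal means removal.

Only events strictly before the current day are observed (an event on day
`t` first influences decisions on day `t+1`). The perceived impact is
initialized at zero: agents carry no pre-war risk perception.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| `tau` | temporal decay exponent | 2.0 | >1 required; day-resolution decay |
| `delta` | spatial decay exponent | 2.0 | >1 required; km-resolution decay |
| `theta` | daily memory retention | 0.5 | in [0,1]; literature-guided, fixed during calibration by default |
| `v` | logistic growth rate | 1.0 | effective rate is `v*b*w`; `b`, `w` are carried scale parameters defaulting to 1 and are never calibrated separately (the `v = z*b*w` folding) |
| `Q` | no-risk migration control | 500 | baseline daily migration probability is `1/(1+Q)` |
| `i_hi`, `i_lo` | peer thresholds | 1000, 0 | counts of initially-deciding neighbor households; defaults neutralize the rule |
| `refugee_prob` | border-crossing probability | 0.6 | the refugee/IDP classifier is a pluggable stand-in; under `martial_law`, households whose only adults are males aged 18-60 are always IDP |
| `decision_lag` | decision-to-crossing delay (days) | 0 | shifts the counted crossing day |
| `dt_floor`, `ds_floor_km` | kernel floors | 1 day, 1 km | prevent unbounded impact at an event's own day/location |
| `event_horizon_days` | attitude-sum truncation | 30 | with `tau > 1` the dropped tail is negligible; keeps the daily cost proportional to recent events |
| `min_impact` | per-contribution floor | 1e-9 | contributions below it count as zero |

Thresholds are interpreted as literal neighbor *counts* (not fractions of
the neighborhood); with the default bounded-degree network this keeps their
scale meaningful across worlds.

## Synthetic population and network

The generator samples household sizes, an age pyramid (inclusive integer
ranges with uniform ages within a range), genders, and locations: households
scatter with isotropic Gaussian dispersion (km, converted to degrees at the
centroid latitude) around weighted regional centroids carrying admin-1 and
admin-2 labels. This reproduces the two features the dynamics care about —
realistic demographic marginals and spatial clustering with region labels —
without shapefiles or census microdata. What it does *not* emulate: real
street-level settlement geometry, household composition correlations (e.g.
elderly couples), within-country heterogeneity of household size, or
migration-relevant covariates like income. Passing tests therefore show that
the *mechanism* behaves correctly on populations with realistic marginals,
not that any particular real region is reproduced.

Risk proneness is assigned at the (age-bin x gender) group level — default
bins <18 / 18-64 / >=65, with children and the elderly at 1.2 — rather than
as per-person noise, since the motivation for heterogeneity is group-level.

The household network links households within a radius (default 1 km) capped
at the k nearest (default 20), then keeps only mutual edges. The
mutual-kNN re-symmetrization preserves the degree cap exactly, which keeps
the peer-threshold counts well-scaled; the union alternative would restore
all radius edges but let degrees exceed the cap. The whole rule is a
stand-in exposed behind a pluggable `rule` argument, as the appropriate
construction is context-dependent.

## Conflict events and scenarios

Events are ingested from ACLED-like CSVs (both the `event_date`/`latitude`
and minimal `date`/`lat` dialects), filtered by default to the three
damaging classes (battles, explosions/remote violence, violence against
civilians; prefix-matched case-insensitively so "Battle" and "battles" both
match), and scored with intensity
`I = w_type * (1 + s*ln(1 + fatalities))` — positive even for zero-fatality
events, monotone in fatalities, with all weights configurable. Counterfactual
scenarios are drawn from an inhomogeneous Poisson sampler: per component,
daily event counts are Poisson at a constant rate with Gaussian spatial
scatter around a center. The sampler consumes user-specified intensities;
fitting a point-process model to produce those intensities is outside the
package's scope, and any externally produced event list can be fed to the
engine directly.

## Calibration

The objective simulates `replicates` trajectories (default 3) under a fixed
replicate seed stream, averages the daily refugee series, applies a centered
7-day moving average to both simulated and observed series, and returns the
RMSE (default; it constrains scale) or `1 - PCC` (scale-free). Reusing the
same replicate seeds across evaluations (common random numbers) makes the
objective a deterministic function of the parameters, which grid line
searches need.

Coordinate descent cycles over free parameters; each line search evaluates a
uniform grid in the parameter's bounds (integer grids for the thresholds)
and takes the argmin, ties to the smallest value; a start terminates when a
full cycle improves the loss by less than `tolerance` (interpreted in loss
units) or after `max_cycles`. Because `v` and `Q` trade off inside the
logistic, the loss surface has a narrow diagonal valley that single-
coordinate moves cannot follow; `n_starts > 1` therefore repeats the descent
from Latin-hypercube points in the bounds box and keeps the best final fit.
The memory parameter `theta` is excluded from the default free set and can
be freed explicitly.

## Numerical choices

- Great-circle distances use the haversine formula on a sphere of radius
  6371.0088 km; neighbor candidates come from a k-d tree on unit-sphere
  chord coordinates, then exact haversine filtering.
- Kernel powers `x**a` are computed as `exp(a*log(x))`: in the installed
  numpy, `exp` and `log` are bitwise identical between vectorized and scalar
  evaluation while `power` is not, and the engine is required to match a
  straight-line scalar reference implementation exactly.
- Randomness: one `numpy` Generator per simulation; each day consumes two
  uniform vectors over all households in ascending household-id order
  (decision draws, then classification draws). Draws for frozen households
  are burned unused, which makes runs bitwise reproducible regardless of who
  has migrated.
- Persons are processed sorted by (household_id, person_id); accumulation
  orders (event order for attitude sums, member order for household means)
  are fixed and documented so results are exactly reproducible.
- Degenerate inputs: empty event tables are valid (null dynamics); empty
  households, probability vectors not summing to 1 (beyond 1e-9), decay
  exponents <=1, and `i_lo > i_hi` are configuration errors; Pearson
  correlation on constant series raises rather than returning NaN.

## The recovery study (worked experiment)

`migrasim.experiments` fixes a desk-scale self-calibration study: 500
households in two clusters (70% urban, sigma 6 km; 30% rural, sigma 15 km)
around an eastern city, an 11-day conflict wave of 10 events/day (mean 4
fatalities) centered on the city, horizon 30 days, truth
`(tau, delta, theta, v, Q, i_hi, i_lo) = (2, 2, 0.5, 1, 300, 6, 0)`. The
"observed" series is the 3-replicate average of the truth simulation at an
independent seed; calibration then frees `(v, Q)` with bounds
`[0.2, 3] x [100, 1500]`, a 15-point grid (the truth lies on the lattice),
4 cycles, and 6 Latin-hypercube starts, starting from `(0.6, 1100)`. The
problem sizes were chosen to give a clearly shaped wave (a few hundred
refugees) while a full study — roughly 350 objective evaluations of three
30-day runs — completes in well under a minute on one CPU. Typical outcomes:
fitted parameters on the valley near the truth, fitted smoothed-series PCC
above 0.97, and fitted loss at or below the loss of the true parameters plus
the 0.5 persons/day slack.

## Known limitations

- The peer network is static; depleted neighborhoods (most neighbors
  migrated) permanently weaken the threshold rule rather than letting agents
  rewire to more distant peers.
- Refugee/IDP classification is a Bernoulli stand-in (optionally
  martial-law-aware); the real split depends on geography and policy.
- Event actors are not distinguished; all retained event types feed the same
  kernel, differing only through configured weights and fatalities.
- The calibration grid search scales exponentially only in the number of
  *simultaneously interacting* parameters; with more than two or three free
  parameters a different optimizer would be warranted.
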