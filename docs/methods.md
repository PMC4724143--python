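# Methods

## The model

The quantity of interest is the share of women of childbearing age (15–49)
who live within a 30-minute drive of the nearest hospital still providing
obstetrics services, as that service is concentrated into fewer hospitals.
The simulation holds everything fixed except *which* hospitals survive:

* Demand is a raster of 1-km² grid cells, each carrying a female 15–49
  population count. A cell's access is evaluated at its centroid.
* Supply is a set of hospitals with monthly delivery volumes,
  obstetrician/midwife FTEs, an administrative membership
  (municipality → medical service area, MSA), and a designation
  (general/regional perinatal medical centre, academic, other).
* Impedance is exact shortest-path driving time over an undirected road
  network; an edge of length ℓ km at class speed v km/h costs ℓ/v·60
  minutes. Cells and hospitals snap to the Euclidean-nearest node with no
  off-network penalty — at 1-km grid resolution over a dense synthetic
  lattice the off-network leg is sub-minute, and the snap tie-break
  (lowest node id) makes results reproducible.
* Access classes are ≤30, 30–60 and >60 minutes, with both boundaries
  inclusive on the near side (exactly 30.0 min counts as covered).
  Unreachable cells are classed >60 and stay in every denominator.

Closure scenarios at target size k: S1 keeps the k highest-volume
hospitals; S2 first reserves one slot per hospital-bearing MSA for that
MSA's highest-volume hospital, then fills by global volume; S3 solves the
maximal covering location problem (MCLP) — choose k facilities maximizing
the population within 30 minutes of at least one of them. A fixed
designation scenario retains the academic + PMC set regardless of k. All
ties break by ascending hospital id.

Reported per (scenario, k): national and per-municipality coverage; the
Gini coefficient of per-municipality coverage fractions (unweighted by
default, with a population-weighted option, since the choice of weighting
is genuinely open — unweighted treats municipalities as the policy units);
and reallocation accounting — deliveries and staff in closed hospitals
("absorbed" by the survivors) and per-hospital averages after
intensification, which depend only on |retained| because national totals
are conserved.

Targets are expressed as national estimates and scaled by a survey
reporting fraction r ∈ (0,1] (default 0.985) with half-up rounding, so
1000/800/600 become 985/788/591; areas that did not report to the source
survey are modelled only through this scalar, not spatially.

## Synthetic geography

No public dataset packages the original inputs (a national facility
survey, census raster and proprietary road network), so the generator
emulates their statistical structure:

* **Populations** follow a Gaussian mixture over `n_urban_clusters`
  centres (σ uniform in 3–10 % of the region's larger side) on a 5 %
  uniform floor, integerized by largest remainder so the total matches
  `total_female_pop` exactly.
* **Municipalities** are contiguous rectangular cell blocks (a divisor
  pair of the municipality count chosen to match the region's aspect
  ratio), grouped into MSAs as runs of consecutive blocks. Real
  boundaries are irregular, but only the partition topology matters here.
* **Hospitals** are placed in cells with probability proportional to
  population (+1 smoothing), preferentially urban like the real system.
  Deliveries/month and staffing are gamma with moment-matched shape/scale
  (defaults 44.1 ± 39.3 deliveries, 5.5 ± 4.6 obstetricians,
  15.3 ± 11.8 midwives FTE) — right-skewed and non-negative, as observed.
  The three variables share a Gaussian-copula latent facility-size factor
  with latent correlation 2·sin(π·ρ/6), so their pairwise Spearman rank
  correlation is ρ = `staff_volume_correlation` (default 0.6, reflecting
  the strong volume–staffing gradient across hospital tiers).
  Designations follow the latent size: the largest facilities are flagged
  general PMC, the next tier regional PMC, then academic; counts default
  to the national 95/279/31-of-1075 composition scaled to `n_hospitals`.
* **Roads** are a unit lattice over cell centroids with per-edge speeds
  drawn from the non-highway classes (default 30/40/50 km/h; 10–80
  allowed), plus random √2-km diagonal shortcuts at the fastest class
  until mean degree reaches `network_density` (default 4.2). The lattice
  guarantees every hospital and populated cell is connected.

Everything is drawn from one `numpy` generator in a fixed order, so a
fixed seed reproduces the geography bit for bit.

What the generator does **not** emulate: coastlines and mountain barriers
(the region is convex and fully traversable), one-way roads and traffic,
heterogeneous cell sizes, and spatial autocorrelation of staffing beyond
the size factor. Passing tests therefore validate the *method* —
selection, routing, accounting, inequity measurement — not any national
figure; headline results from the real system (e.g. 95.0 % baseline
coverage, Gini 0.239 → 0.473) require the original proprietary data and
are treated as structural, not numerical, references.

## Solvers and numerics

* Shortest paths: Dijkstra on a sparse node–node minute matrix
  (`scipy.sparse.csgraph`), one sweep per distinct hospital node;
  parallel edges collapse to the fastest.
* Greedy MCLP: marginal-gain argmax per step; ties to the smallest id;
  nested in k; ≥ 1 − 1/e of the optimum by submodularity.
* Exact MCLP: exhaustive enumeration (guarded to ≤ 25 candidates and a
  bounded subset count) returns the lexicographically smallest optimum;
  the MILP mode (HiGHS via `scipy.optimize.milp`, standard select/cover
  formulation) returns a deterministic optimum but does not enforce
  lexicographic tie-breaking — enforcing it would cost n·k extra solves.
* Gini: Lorenz-curve form on sorted values, exact for ties, validated
  against the pairwise and sorted-rank formulas to 1e−12; undefined (an
  error) when the mean is zero. Inside the pipeline an all-zero
  municipality profile records NaN rather than aborting the whole run.
* Target adjustment uses decimal half-up rounding (banker's rounding
  would map 591.985 incorrectly for reproducing 985/788/591-style
  arithmetic).
* Degenerate inputs: an empty retained set classifies every cell >60 min
  and has undefined per-hospital averages; k above the baseline size
  retains everything with a warning; k below the number of
  hospital-bearing MSAs keeps the top MSA representatives with a warning.

## Problem sizes

Unit and property tests run on hand-built lattices (where drive time
reduces to Manhattan distance, giving an independent oracle) and small
generated regions. The end-to-end "national-scale" configuration used by
the acceptance script and the scale test — 300 hospitals, a 300 × 170 km
region (51 000 cells), 98 MSAs / 490 municipalities, 7.5 M women, targets
279/223/167 — scales the 2011 Japanese system by 300/1075 in facility
count, population and targets; it completes in roughly one to two minutes
on a single CPU.

## Known limitations

Centroid (not area-interpolated) cell classification; no capacity limits
on retained hospitals, so absorbed deliveries are bookkeeping rather than
a feasibility claim; no reopening or new construction; coverage and the
S3 objective share a single 30-minute threshold by design; the Gini is
computed over municipality coverage fractions, the most direct reading of
per-municipality 30-minute access.
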