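# Methods

## Problem and model

`pocplan` plans a regional network of point-of-care testing machines.
Demand points are census output areas (OAs), represented by their
population-weighted centroids; supply points are candidate sites — GP
surgeries and pharmacies — that may host zero or more machines. The
patient journey model assumes every patient first attends their nearest
GP surgery and is referred on for testing, so the cost of assigning OA
*i* to site *j* is the *travel burden*: the extended trip
home → nearest GP *g* → *j* → home minus the base return trip
home → *g* → home,

    b(i, j) = d(i→g) + d(g→j) + d(j→i) − 2·d(i→g).

The nearest GP always has burden 0; the anchor *g* is computed over GP
surgeries regardless of which kinds are candidates, because referral
starts at the GP even in a pharmacy-led deployment.

The decision problem is solved lexicographically as two exact integer
programs. With binary assignment variables x_ij (restricted to pairs
with b(i,j) ≤ T) and integer machine counts y_j:

* Stage 1: minimise Σ y_j subject to Σ_j x_ij = 1 for each OA,
  Σ_i demand_i·x_ij ≤ capacity·y_j for each site, and x_ij ≤ y_j.
* Stage 2: add Σ y_j ≤ M* (the stage-1 optimum) and minimise
  Σ_ij pop_i·b(i,j)·x_ij.

Two sequential solves avoid the big-M weight tuning a single weighted
objective would need. Equality of the machine total with M* is implied
by stage-1 optimality; the constraint is stated as ≤.

### Exemption rule

When the candidate set contains no site within burden T of an OA
(possible only without GP candidates), the model would be infeasible.
Such OAs are *exempt*: the burden limit is lifted and they are
force-assigned to their minimum-burden candidate (ties to the smallest
site id). Exempt OAs still consume capacity and still contribute to the
stage-2 objective and to ATB; they count against PS. Exemption is
generalised to any candidate set — exempt iff min burden > T — which
reduces to the pharmacy-only case in practice, since a GP-inclusive
candidate set always offers burden 0.

A consequence worth stating explicitly: an exempting run solves a
*relaxation*, so machine counts from pharmacy-only scenarios with
exemptions are not comparable to GP-inclusive runs by feasible-set
nesting. M*(both) ≤ M*(gp-only) always holds; M*(both) ≤
M*(pharmacy-only) holds only when the pharmacy-only run exempts nobody,
and the test suite asserts exactly that conditional form. (Empirically,
on clustered synthetic regions the unconditional inequality fails in
most seeds precisely when exemptions fire.)

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| T | m | scenario grid {1, 500, 1000, 2000} | 1 m is the "everyone at their nearest GP" base case, run GP-only since any pharmacy referral incurs extra travel; the others span tolerable walking detours |
| capacity | tests/machine/week | 175 | one machine matching a GP's weekly consultation throughput |
| demand, low/high | tests/person/week | 0.00025 / 0.005 | package conventions spanning low- and high-utilisation regimes (~20× apart); locally estimated incidence should replace them in real studies |
| burden-limit tolerance | m | 1e-6 | absorbs float noise in eligibility and PS counting |

Populations are integers (persons); demand may be fractional (expected
tests/week). Machine counts per site are unbounded non-negative
integers with pooled site capacity machines × 175.

## Distances

Three providers: planar Euclidean (synthetic regions, coordinates in
metres), great-circle haversine with Earth radius 6 371 008.8 m (lon/lat
WGS84 inputs), and precomputed long-format tables for street-network
distances produced by an external router. Tables store *directed* legs
even when generated symmetrically, because walking routes on real
networks can be asymmetric; the burden formula consumes the three legs
as directed. Burdens are never clipped: on a non-metric precomputed
table a negative burden is preserved and a warning logged, keeping the
difference definition faithful.

Nearest-GP ties break to the smallest site id, making reruns
deterministic. Among multiple optimal solutions the MILP may return any;
machine counts are therefore re-derived from the returned assignment
(ceil of site demand over capacity, minimum one machine at any assigned
site), and tests compare objective values rather than assignments except
where the optimum is unique.

## Synthetic regions

The generator emulates two archetypes on a planar square, fully
reproducible from one integer seed:

* **urban** — OAs and sites uniform over a 7 km square (compact city,
  dense sites);
* **rural** — OAs drawn from a mixture of Gaussian "village" clusters
  (default 6) over a 60 km square, with sites scattered near cluster
  centres; between-village gaps produce the long pharmacy detours that
  drive exemptions.

OA populations are lognormal centred near 300 persons (typical census
OA magnitude), floored at 1. What the generator does **not** emulate:
real street networks (straight-line distances understate detours around
rivers or railways), population-weighted centroid estimation error,
patients registered with a non-nearest GP, car or public-transport
travel, and trip-chaining with routine pharmacy visits. Passing tests
therefore demonstrate correctness of the optimisation and metric
machinery under controlled geography, not calibrated predictions for
any real region; real studies should supply routed distance matrices.

## Numerical choices

Both stages are solved with HiGHS branch-and-cut via
`scipy.optimize.milp` with sparse constraint matrices and a fixed
(sorted-id) variable ordering. Machine variables are bounded above by
⌈total demand / capacity⌉ (never binding at the optimum). The
brute-force reference solver enumerates every feasible whole-OA
assignment (caps: 8 OAs, 5 sites, 3 machines/site) and pairs each with
its minimal machine vector — any larger vector is lexicographically
dominated — so it is provably optimal within the caps and serves as the
independent check on ~200 random micro-instances per test run.

Problem sizes used by the test and acceptance runs — 300-OA/45-site
regions for the analytic checks, 20 seeds of 30–40-OA regions for the
monotonicity and rural suites — solve in milliseconds to a few hundred
milliseconds each; they were chosen as the smallest sizes at which the
geographic contrasts of interest are stable across seeds.

## Metrics

* **Mach** = Σ machines.
* **ATB** = Σ pop_i·b_i / Σ pop_i over all patients, exempt included —
  the patient-weighted reading of "average travel burden";
  `weighted=False` gives the per-OA mean as a diagnostic variant.
* **MU** = max over open sites of 100 × assigned weekly demand /
  (machines × capacity).
* **PS** = 100 × population with burden ≤ T (+tolerance) / total
  population.

Display rounding (ATB to the metre, MU to one decimal) is applied only
in rendered tables, never in stored JSON.

## Known limitations

Whole-OA assignment (no fractional splitting of an OA across sites);
deterministic demand (no stochastic or robust variant — capacity is
rarely the binding constraint, geography is); exact MILP solving only,
so very large regions (tens of thousands of OAs) may need decomposition
or a heuristic front end; schematic GeoJSON export rather than rendered
cartography.
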