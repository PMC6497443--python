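# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind `colonystate`, and what the test suite does and does not
establish about real tracking data.

## Nest geometry and wall-aware distances

The nest is two-dimensional: chambers are axis-aligned 65 × 40 mm
rectangles (configurable) joined by 6 mm-wide opening corridors spanning a
2 mm wall gap; the chamber height (6 mm) is ignored because tracking is
from an overhead camera.  The coordinate frame puts the origin at the
entrance midpoint with x increasing into the nest; times are integer
seconds 0 … 14,400.

Two wall-aware metrics are used throughout:

* **Geodesic distance** (ant-to-ant, annulus radii): Euclidean whenever the
  two points share a convex unit (chamber or corridor); otherwise the
  shortest path on a 0.5 mm occupancy grid with 8-connected moves (edge
  lengths h and h√2).  Every cross-unit grid path must cross the centre
  line of some opening corridor, so cross-unit queries are answered exactly
  on the grid metric by `min over portal cells c of d(p,c) + d(c,q)` with
  full-grid Dijkstra maps precomputed from each portal cell — this is what
  makes per-second all-pairs density and annulus computations tractable.
  The 8-connected metric overestimates free-space Euclidean length by up to
  ~8% (the octile bound); this is why the triangle-inequality property test
  carries that relative slack, and why equality with Euclidean distance is
  exact only within a convex unit.
* **Rectilinear entrance distance** (spatial signatures): the shortest path
  to the entrance with moves parallel or perpendicular to the walls,
  computed as a single 4-connected Dijkstra map from the entrance cell.
  Queries return `max(grid value, L1(p, entrance))` so the value can never
  fall below the unconstrained L1 distance (the grid value alone could,
  by up to one step, because of cell-centre snapping).  The entrance
  reference point is the entrance midpoint; it is configurable because the
  choice between the nest-side and outside end of the entrance tunnel is
  genuinely open.

Projection of out-of-nest points uses the closed-form nearest point of a
union of rectangles (the nearest point of the union is the nearest of the
per-rectangle clamps); shapely is used for polygon construction,
validation and areas, not in hot paths.

## Preprocessing

Raw tables may be in camera pixels (then a least-squares affine map fitted
on chamber-corner correspondences is applied) or in mm.  Clock alignment
subtracts one second from every second Hero3-silver video (the camera runs
0.5 s long per video) and adds the stated inter-camera switch-on offsets
cumulatively; segments that end up out of order, or overlapping by more
than the 1 s correction, raise an alignment error.  Tracking gaps flanked
by in-nest observations are filled by per-axis linear interpolation with
projection into the nest; gaps that touch the recording boundary, or abut
an outside (foraging) spell, are not fabricated — those seconds are marked
outside, with a warning.  A 4-h recording yields exactly 14,401 rows per
ant.

## Spatial groups

An ant's spatial signature is the multiset of its per-second entrance
distances over in-nest seconds (raw, autocorrelated samples — the
signature is a description of occupancy, not an i.i.d. sample, and the KS
statistic is used descriptively).  Similarity is `1 − KS`; the KS statistic
is computed by direct CDF evaluation on the pooled support and is invariant
to common rescaling of both signatures.  Louvain community detection
(networkx implementation, seeded) maximises weighted modularity on the
complete similarity graph; detected groups are renumbered 1 … k by
increasing mean entrance distance, and ants outside for the entire
recording join as group 0.

**Beta perturbation.**  Each replicate resamples every edge weight from
`Beta(α, 4)` with `α = 4μ/(1−μ)` so the mean equals the observed similarity
μ (0.001 where μ = 0; μ is capped at 0.999 so α stays finite for
near-identical ants).  The stated shape parameter 4 is read as the second
shape argument; with the mean constraint this reproduces a mean absolute
change in similarity of roughly 10% for mid-range similarities, which is
the documented intent of the procedure.  An ant counts as changed in a
replicate when fewer than half of its companions in the smaller of its two
groups (reference vs replicate; ties resolved toward the reference group)
are present in the larger one.

**Consistency.**  Cross-treatment agreement is the Spearman correlation of
the ordered group labels over ants present in both recordings (case-wise
deletion of ants that died is performed by dropping them from either
partition), with a two-sided permutation p-value (default 40,000
relabelings).

## Local density

Local density of ant i at second t is the number of other in-nest ants
within a 15 mm wall-aware distance.  The colony-mean series is subsampled
every 1500 s (10 points per 4-h recording) and a lag-1 permutation test is
reported as an autocorrelation diagnostic (the test is a package choice —
no specific test is canonical here; a constant series reports p = 1).
The treatment model is a linear mixed model with a fixed high-vs-low
effect and random colony intercepts (statsmodels MixedLM); the Wald
chi-square is the squared coefficient z-statistic on 1 df.  The
random-diffusion null for a nest enlarged by factor A is a
`100 × (1 − 1/A)` % density reduction.

One observed discrepancy: the mean-density series is described in one
place as running to t = 14,000 and elsewhere as 14,401 observation points;
the package uses the full 14,401-point series.

## Interaction rates and assortativity

Per-second initiation counts (length 14,401 per recording; six recordings
stack to 86,406 rows) are fitted by a Poisson log-link GLM with colony,
treatment and colony × treatment effects under sum-to-zero coding, which
yields a grand-mean intercept plus per-level deviations for all but the
last level of each factor; colony-specific treatment effects are compared
pairwise by Wald tests on interaction-term contrasts (no multiplicity
correction by default).  Note that under ±1 deviation coding a log-rate
ratio of `log 2` between two colonies' treatment contrasts appears as an
interaction-term difference of `log 2 / 2`.

The trophallaxis network weights each dyad by its event count
(binarisation is available but event-weighted is the default, since
interactions are counted).  Assortativity is Newman's discrete coefficient
`r = (Σ e_ii − Σ a_i b_i) / (1 − Σ a_i b_i)` on the weighted mixing
matrix.  The jackknife SE removes one unit of edge weight (one event) at a
time; removals within the same group pair give identical replicates, so
the sum over events collapses to a weighted sum over group pairs —
verified in tests against explicit leave-one-edge-out recomputation.  r is
undefined (error) when all edges fall within a single group.

## IHPP trophallaxis regression

For each unordered pair, initiations are a discretised inhomogeneous
Poisson process with λ_t constant within each second: likelihood
`∏ λ_t^{y_t} exp(−λ_t)` over at-risk seconds, i.e. Poisson regression of
the initiation indicator.  λ_t = 0 (the second contributes nothing)
whenever the pair's wall-aware distance exceeds 20 mm.  Covariates are
per-colony intercepts, a treatment indicator, and the numbers of
additional ants whose wall-aware distance from the pair centroid falls in
(0,5], (5,10], (10,15] and (15,20] mm — each additional ant increments
exactly one band, and the band counts sum to the total within 20 mm.  The
centroid is the midpoint of the pair, projected into the nest when it
falls inside a wall.  Colony × band interactions are always reported;
colony × treatment interactions are fitted first and dropped from the
report when none is significant.  Pairs are treated as independent, so no
clustered errors are computed.  Percent rate changes per additional ant
are `100 × (exp(coef + colony interaction) − 1)`.

Risk-set options: by default, seconds during a pair's own ongoing event
remain at risk with y = 0.  Two censoring flags exist: `censor_ongoing`
drops a pair's own ongoing-event seconds, and `censor_busy` drops every
second in which either partner is engaged in *any* ongoing event — the
correct risk set when an ant can share food with only one partner at a
time, and the option used when fitting data produced by the package's own
generator (whose exclusivity rule is exactly that).  Fitting
exclusivity-generated data without busy-censoring biases the intercept and
the near-field coefficients downward once events become frequent.

## SDE movement model

Velocity follows `dv_t = −β (v_t − μ(x_t)) dt + c(x_t) dW_t` per axis with
shared scalar β and shared surfaces; `μ(x) = −c(x) ∇P(x)` so ants drift
downhill on the potential P (the sign convention is chosen so exported
surfaces read as "lower = accelerating downhill").  The second-order
discretisation at step h = 1 s,

    x_t = x_{t−1}(2 − βh) + x_{t−2}(βh − 1) + βh² μ(x_{t−2})
          + N(0, h³ c²(x_{t−2})),

is used both for forward simulation (with projection into the nest each
step) and for estimation, which regresses the per-axis second difference
`x_t − 2x_{t−1} + x_{t−2}` on `−h² v_t` (coefficient β) and a
piecewise-constant drift field per grid cell (default 5 mm cells), with a
squared-discrete-Laplacian roughness penalty on the surfaces chosen by
generalized cross-validation over a log-grid.  The three steps: (1) fit β
and the drift field at uniform motility; (2) estimate `c²(x)` from the
squared step-1 residuals (`E[resid²] = h³c²`), pooled over axes, by
penalized per-cell regression; (3) re-fit step 1 weighted by
`1/(h³ĉ²(x))`.  P is recovered from the drift field by least-squares
integration of `∇P = −μ/ĉ` over grid-cell edges and anchored to mean zero
(P is only identified up to a constant; c is reported on the `h³c²`
parameterisation the discretisation defines).  Cells never visited by an
ant are held near zero drift by a small ridge floor on the penalty;
surfaces there are uninformative.  With flat P and constant c the model is
an integrated Ornstein–Uhlenbeck process whose stationary per-axis
velocity variance `h³c²/h² / (1 − (1 − βh)²)` provides a closed-form check
used in the tests.  Stability of the discretisation requires 0 < βh < 2.

## Synthetic colonies: what the generator emulates

Defaults mirror the study conditions: ~80 ants, 4-h recordings at 1 Hz,
one- or four-chamber nests of 65 × 40 mm chambers with 6 mm openings.
Movement uses the same discretised SDE as the inference module with
β = 0.5 s⁻¹ and c = 1 mm s⁻¹·⁵ (per-axis speeds of order 1 mm/s) and
quadratic potential wells `P = κ|x − home|²/2` of curvature κ = 0.05,
giving a per-axis stationary spread of about 6.5 mm — strong spatial
fidelity (>95% home-chamber occupancy) while ants belonging to one group
still share overlapping signatures.  The default colony plants two groups
(40%/60%) anchored in the entrance and queen chambers, matching the
observed split of aggregates; alternative anchor layouts provide
per-ant fidelity zones, either uniform over the chambers or clustered
around aggregation sites.

Trophallaxis is drawn from the same IHPP the regression fits: in each
at-risk second a pair initiates with probability `1 − exp(−λ_t)`; event
durations are `2 + (Geometric(0.2) − 1)` s (mean 6 s, minimum 2 s — only
the lower bound is empirically constrained); while a pair shares food
neither partner can start another event.  Default coefficients are the
published colony-1 point estimates (intercept −5.80, treatment −0.49,
n5 +0.18, n10 +0.05, n15 −0.41, n20 −0.26).

**Recovery-study design.**  The coefficient-recovery suite simulates one
40-ant, 4-h colony per replicate in the four-chamber nest with aggregated
per-ant fidelity sites (2 sites per chamber, 8 mm scatter) and an
isolated-pair initiation rate of exp(−5.5)/s.  The rate is brighter than
the published intercept by design: at a single-recording scale it makes
the weakest effect (n10 = +0.05) estimable with |z| ≈ 3, so that sign
reproduction across every replicate is an expected property of a correct
implementation rather than a coin flip; the fit uses the busy-censored
risk set to match the generator's exclusivity rule.  These runs establish
generation/inference symmetry — they do not certify behaviour on real
colonies, where movement is not an OU well, pairs are not independent,
and annotation noise exists.

## Problem sizes and determinism

Simulations in the test suite are sized to the analysis they exercise:
full 80-ant, 14,400 s colonies for the robustness procedure; 20 tracks of
14,400 s for SDE recovery; 20 replicates of 40-ant colonies for IHPP
recovery; smaller colonies (10–30 ants, 300–3000 s) for unit-level checks.
All randomness flows through explicit integer seeds (`numpy` Generators;
the pipeline splits one master seed per stage via `SeedSequence`), and
simulation output is bit-reproducible for a fixed seed.

## Known limitations

* The grid geodesic inherits the 8-connected octile overestimate (≤ ~8%)
  on cross-chamber paths; a finer or higher-connectivity grid is a
  configuration change away but was not needed at the 15–20 mm radii used.
* The mixed model and GLMs are thin, documented wrappers over statsmodels;
  no overdispersion or temporal-dependence corrections are applied beyond
  the decorrelation subsampling.
* Boundary projection slightly deflates the fitted motility in cells
  against walls (visible as a low tail in the c surface); estimates in the
  chamber interiors are unaffected.
* The SDE surfaces are identified only where ants actually travel;
  unvisited cells carry the penalty's null behaviour, not information.
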