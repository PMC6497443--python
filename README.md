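# colonystate

Spatial and social analysis of tracked ant colonies: how does a colony's
spatial organisation, local density, food-sharing (trophallaxis) rate and
movement behaviour respond when its nest space changes?

The package implements, as a tested pipeline, the analysis of a
nest-expansion experiment design: colonies of ~80 individually tracked ants
are recorded for 4 h at 1 Hz in a one-chamber (high-density) nest and again
in a four-chamber (low-density) nest of 65 × 40 mm chambers joined by 6 mm
openings.  It is aimed at researchers analysing per-second insect tracking
tables (`ant_id, t_s, x_mm, y_mm`) together with dyadic interaction event
tables (`ant_i, ant_j, start_s, end_s`).

## What it computes

* **Wall-aware geometry** — nests as unions of rectangular chambers and
  opening corridors; geodesic distances that route around walls (occupancy
  grid, 0.5 mm); rectilinear distance to the entrance; affine
  camera-to-nest alignment; projection of out-of-nest points.
* **Preprocessing** — camera clock alignment (including the −1 s per second
  Hero3-silver video correction), linear interpolation of tracking gaps
  with in-nest projection, producing 14,401 per-second rows per ant.
* **Spatial groups** — each ant's *spatial signature* is its distribution
  of entrance distances; pairwise similarity `S(i,j) = 1 − KS(i,j)`
  (Kolmogorov–Smirnov); Louvain community detection partitions the colony,
  groups numbered by mean entrance distance with group 0 for ants that
  never entered the nest.  Robustness via 1000 beta-perturbed networks
  (shape 4, mean = observed similarity) and the smaller-group overlap
  rule; cross-treatment consistency via a Spearman permutation test.
* **Local density** — neighbour counts within a wall-aware 15 mm radius,
  decorrelated by 25 min subsampling, with a mixed model
  (`density ~ treatment + (1 | colony)`) and the random-diffusion null
  `100 × (1 − 1/area_ratio)` %.
* **Interaction rates & networks** — per-second initiation counts modelled
  by a sum-to-zero Poisson GLM (colony × treatment); trophallaxis-network
  assortativity with edge-jackknife standard errors.
* **IHPP event regression** — per-pair trophallaxis initiations as an
  inhomogeneous Poisson process: rate 0 beyond 20 mm pair separation, and
  on at-risk seconds `log λ_t` linear in colony, treatment and the numbers
  of additional ants in the (0,5], (5,10], (10,15], (15,20] mm annuli
  around the pair centroid.
* **SDE movement model** — continuous-time correlated random walk
  `dv_t = −β (v_t − μ(x_t)) dt + c(x_t) dW_t` with drift
  `μ(x) = −c(x) ∇P(x)` down a potential surface `P` and a motility surface
  `c`, fitted by the three-step penalized-spline scheme and simulated
  forward with the same discretisation.
* **Synthetic colonies** — a generator that plants spatial groups (SDE
  potential wells), draws trophallaxis from the same IHPP the inference
  fits, and emits ground truth for every downstream stage.

## Worked example

```python
import numpy as np
from colonystate.geometry import four_chamber_nest
from colonystate.synthetic_data import ColonyScenario, simulate_tracks
from colonystate import spatial_groups as sg

nest = four_chamber_nest()
scenario = ColonyScenario(n_ants=80, nest=nest, seed=3)   # two planted groups
tracks = simulate_tracks(scenario)

signatures = [sg.spatial_signature(tr, nest) for tr in tracks]
network = sg.build_similarity_network(signatures)
partition = sg.detect_groups(network, seed=1)
print(partition.n_groups, sorted(
    (g, len(m)) for g, m in partition.groups().items()))

result = sg.perturb_and_score(network, partition,
                              sg.PerturbationConfig(n_reps=100, seed=7))
print(f"changed fraction: {100 * result.changed_fraction:.2f}%")
```

Output:

```
2 [(1, 32), (2, 48)]
changed fraction: 0.00%
```

The colony splits into the two planted spatial groups (32 ants near the
entrance, 48 in the queen chamber, matching the scenario's 40/60 split),
and no ant changes group under beta-perturbation of the similarity
network — the partition is robust to sizeable corruption of the edge
weights.

The same stages are available from the command line
(`colonystate simulate | groups | density | network | ihpp | sde | run`),
with `colonystate run --config run.yaml` executing the whole pipeline and
writing a reproducibility manifest.

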