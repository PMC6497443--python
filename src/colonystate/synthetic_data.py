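"""Synthetic colonies with known ground truth.

The generator reuses the same discretised SDE as the movement-inference
module (generation/inference symmetry): each ant follows the correlated
random walk with a quadratic potential well anchored at its planted group's
home point, producing spatial fidelity, and trophallaxis initiations are
drawn from the same inhomogeneous Poisson process the regression module
fits, using the same annular covariate coding.

Default conditions mirror the nest-expansion experiment: ~80 ants, 4-hour
recordings at 1 Hz, one-chamber (high-density) or four-chamber
(low-density) nests of 65 x 40 mm chambers joined by 6 mm openings, and
IHPP coefficients at the published point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import NestGeometry, four_chamber_nest, project_into_nest
from .ihpp import LAGS, pair_second_table
from .interaction_network import TrophallaxisEvent
from .preprocess import IN_NEST, OUTSIDE, AntTrack
from .sde_movement import simulate_positions

__all__ = [
    "IHPPCoefs",
    "ColonyScenario",
    "SimulatedColony",
    "simulate_tracks",
    "simulate_trophallaxis",
    "simulate_colony",
]


@dataclass(frozen=True)
class IHPPCoefs:
    """Log-linear IHPP coefficients for trophallaxis initiation.

    Defaults are the published colony-1 point estimates: positive density
    effects close to the pair (n5, n10) and negative effects further out
    (n15, n20); the intercept is the log initiation rate (1/s) of an
    isolated at-risk pair.
    """

    intercept: float = -5.80
    treatment_high: float = -0.49
    n5: float = 0.18
    n10: float = 0.05
    n15: float = -0.41
    n20: float = -0.26

    def linear_predictor(self, table: pd.DataFrame, treatment: str = "low") -> np.ndarray:
        lp = np.full(len(table), self.intercept)
        if treatment == "high":
            lp += self.treatment_high
        for name in ("n5", "n10", "n15", "n20"):
            lp += getattr(self, name) * table[name].to_numpy(dtype=float)
        return lp


@dataclass
class ColonyScenario:
    """Ground-truth description of one synthetic colony recording.

    Movement: shared velocity-autocorrelation ``beta`` (1/s), constant
    motility ``motility`` (mm s^-1.5) and per-group quadratic potential
    wells of curvature ``well_strength`` centred on each group's home
    point, giving a per-axis stationary spread of about 6.5 mm at the
    defaults — enough spatial fidelity that ants keep >=95% occupancy of
    their home chamber while their signatures still overlap within a group.
    """

    n_ants: int = 80
    nest: NestGeometry = field(default_factory=four_chamber_nest)
    group_fractions: tuple = (0.4, 0.6)
    group_assignment: np.ndarray | None = None  # per-ant labels 1..k
    group_home: dict[int, tuple] | None = None
    beta: float = 0.5
    motility: float = 1.0
    well_strength: float = 0.05
    duration: int = 14_400
    n_outside_only: int = 0
    treatment: str = "low"
    colony: str = "sim"
    ihpp_coefs: IHPPCoefs = field(default_factory=IHPPCoefs)
    event_duration_p: float = 0.2
    seed: int = 0

    def resolve_groups(self) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        """Per-ant group labels and home points (defaults if unset)."""
        if self.group_assignment is not None:
            labels = np.asarray(self.group_assignment, dtype=int)
            if len(labels) != self.n_ants:
                raise ValueError("group_assignment must have one label per ant")
        else:
            k = len(self.group_fractions)
            sizes = np.floor(np.asarray(self.group_fractions) * self.n_ants).astype(int)
            sizes[-1] = self.n_ants - sizes[:-1].sum()
            labels = np.repeat(np.arange(1, k + 1), sizes)
        if self.group_home is not None:
            homes = {g: np.asarray(h, dtype=float) for g, h in self.group_home.items()}
        else:
            # first group anchored in the entrance chamber, last group in the
            # queen chamber (farthest), intermediates spread across chambers
            chambers = self.nest.chambers
            uniq = sorted(set(labels))
            idx = np.linspace(0, len(chambers) - 1, len(uniq)).round().astype(int)
            homes = {g: chambers[i].center for g, i in zip(uniq, idx)}
        missing = set(labels) - set(homes)
        if missing:
            raise ValueError(f"no home point for groups {sorted(missing)}")
        for g, h in homes.items():
            if not self.nest.contains(h):
                raise ValueError(f"home of group {g} lies outside the walkable region")
        return labels, homes


def simulate_tracks(scenario: ColonyScenario) -> list[AntTrack]:
    """Simulate per-second tracks for the whole colony (bit-reproducible).

    Each ant starts near its group home with zero velocity and follows the
    discretised SDE with drift mu(x) = -c * kappa * (x - home), i.e. the
    downhill force of the quadratic well P(x) = kappa |x - home|^2 / 2.
    ``n_outside_only`` additional ants are outside for the whole recording
    (they exercise spatial group 0 downstream).
    """
    rng = np.random.default_rng(scenario.seed)
    labels, homes = scenario.resolve_groups()
    home_xy = np.stack([homes[g] for g in labels])
    x0 = home_xy + rng.normal(0.0, 3.0, size=home_xy.shape)
    c, kappa = scenario.motility, scenario.well_strength

    def mu(x):
        return -c * kappa * (x - home_xy)

    pos = simulate_positions(
        scenario.nest,
        scenario.n_ants,
        scenario.duration,
        scenario.beta,
        mu,
        c,
        x0,
        v0=np.zeros_like(x0),
        seed=int(rng.integers(2**31 - 1)),
    )
    tracks = [
        AntTrack(
            ant_id=f"a{i:03d}",
            xy=pos[i],
            presence=np.full(scenario.duration + 1, IN_NEST, dtype=np.int8),
        )
        for i in range(scenario.n_ants)
    ]
    for k in range(scenario.n_outside_only):
        n = scenario.duration + 1
        tracks.append(
            AntTrack(
                ant_id=f"a{scenario.n_ants + k:03d}",
                xy=np.full((n, 2), np.nan),
                presence=np.full(n, OUTSIDE, dtype=np.int8),
            )
        )
    return tracks


def simulate_trophallaxis(
    tracks: list[AntTrack],
    nest: NestGeometry,
    coefs: IHPPCoefs = IHPPCoefs(),
    seed: int = 0,
    treatment: str = "low",
    duration_p: float = 0.2,
    table: pd.DataFrame | None = None,
) -> list[TrophallaxisEvent]:
    """Draw trophallaxis events from the IHPP over at-risk pair-seconds.

    An initiation occurs in an at-risk second with probability
    1 - exp(-lambda_t), lambda_t = exp(linear predictor); pairs further
    than 20 mm apart never initiate.  Event durations are
    2 + (Geometric(duration_p) - 1) seconds, and while a pair shares food
    neither partner can start another event (an ant feeds one partner at a
    time), enforced by a chronological sweep over candidate initiations.
    """
    rng = np.random.default_rng(seed)
    if table is None:
        table = pair_second_table(tracks, nest, lags=LAGS, treatment=treatment)
    lam = np.exp(coefs.linear_predictor(table, treatment=treatment))
    p = 1.0 - np.exp(-lam)
    hit = rng.random(len(table)) < p
    cand = table.loc[hit, ["pair_i", "pair_j", "t"]].copy()
    cand = cand.sort_values(["t", "pair_i", "pair_j"], kind="mergesort")

    duration = max(tr.n_seconds for tr in tracks) - 1
    busy_until: dict[str, int] = {}
    events: list[TrophallaxisEvent] = []
    for ant_i, ant_j, t in cand.itertuples(index=False):
        t = int(t)
        if busy_until.get(ant_i, -1) >= t or busy_until.get(ant_j, -1) >= t:
            continue
        dur = 2 + int(rng.geometric(duration_p)) - 1
        end = min(t + dur, duration)
        if end - t < 2:
            continue  # too close to the end of the recording
        events.append(TrophallaxisEvent(str(ant_i), str(ant_j), t, end))
        busy_until[ant_i] = end
        busy_until[ant_j] = end
    return events


def aggregated_homes(
    nest: NestGeometry,
    n_ants: int,
    seed: int = 0,
    sites_per_chamber: int = 2,
    site_scatter: float = 8.0,
    margin: float = 12.0,
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-ant fidelity anchors clustered around aggregation sites.

    Colonies aggregate rather than spread uniformly; this draws
    ``sites_per_chamber`` aggregation sites per chamber (``margin`` mm off
    the walls) and scatters each ant's personal home point around its site
    with an isotropic ``site_scatter`` mm spread.  Returns per-ant
    one-member groups like :func:`scattered_homes`.
    """
    rng = np.random.default_rng(seed)
    centers = []
    for c in nest.chambers:
        for _ in range(sites_per_chamber):
            centers.append(
                [
                    rng.uniform(c.x0 + margin, c.x1 - margin),
                    rng.uniform(c.y0 + margin, c.y1 - margin),
                ]
            )
    labels = np.arange(1, n_ants + 1)
    per_site = max(1, n_ants // len(centers))
    homes: dict[int, np.ndarray] = {}
    for g in labels:
        cc = np.asarray(centers[min((g - 1) // per_site, len(centers) - 1)])
        h = cc + rng.normal(0.0, site_scatter, 2)
        homes[g] = project_into_nest(h, nest)
    return labels, homes


def scattered_homes(
    nest: NestGeometry, n_ants: int, seed: int = 0, margin: float = 5.0
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Per-ant spatial-fidelity anchors sampled uniformly over the chambers.

    Returns a (group_assignment, group_home) pair giving every ant its own
    one-member group, for scenarios where individual fidelity zones rather
    than a few large aggregates are wanted (e.g. exercising the IHPP
    local-density covariates over a realistic range of neighbour counts).
    Chambers are sampled proportionally to area, keeping ``margin`` mm off
    the walls.
    """
    rng = np.random.default_rng(seed)
    areas = np.array([c.area for c in nest.chambers])
    probs = areas / areas.sum()
    homes: dict[int, np.ndarray] = {}
    for g in range(1, n_ants + 1):
        c = nest.chambers[rng.choice(len(areas), p=probs)]
        homes[g] = np.array(
            [
                rng.uniform(c.x0 + margin, c.x1 - margin),
                rng.uniform(c.y0 + margin, c.y1 - margin),
            ]
        )
    return np.arange(1, n_ants + 1), homes


@dataclass
class SimulatedColony:
    """One synthetic recording with its ground truth."""

    scenario: ColonyScenario
    tracks: list[AntTrack]
    events: list[TrophallaxisEvent]
    true_groups: dict[str, int]  # incl. group 0 for outside-only ants


def simulate_colony(scenario: ColonyScenario) -> SimulatedColony:
    """Tracks + trophallaxis events + ground-truth labels for one scenario."""
    tracks = simulate_tracks(scenario)
    labels, _ = scenario.resolve_groups()
    truth = {tr.ant_id: int(g) for tr, g in zip(tracks, labels)}
    for tr in tracks[scenario.n_ants :]:
        truth[tr.ant_id] = 0
    rng = np.random.default_rng(scenario.seed)
    rng.integers(2**31 - 1)  # burn the track seed
    events = simulate_trophallaxis(
        tracks[: scenario.n_ants],
        scenario.nest,
        coefs=scenario.ihpp_coefs,
        seed=int(rng.integers(2**31 - 1)),
        treatment=scenario.treatment,
        duration_p=scenario.event_duration_p,
    )
    return SimulatedColony(
        scenario=scenario, tracks=tracks, events=events, true_groups=truth
    )


def rescale(scenario: ColonyScenario, **updates) -> ColonyScenario:
    """Convenience: a copy of the scenario with fields replaced."""
    return replace(scenario, **updates)
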