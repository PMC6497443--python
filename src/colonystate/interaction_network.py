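"""Colony-level interaction-rate modelling and trophallaxis-network structure.

Per-second initiation counts are modelled by a Poisson log-link GLM with
colony, treatment and colony x treatment effects under sum-to-zero coding
(a grand-mean intercept with per-level deviations).  The trophallaxis
network weights each dyad by its event count; assortativity with respect to
the spatial partition is Newman's discrete assortativity coefficient on the
weighted mixing matrix, with a jackknife standard error obtained by
removing one unit-weight edge (one event) at a time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FitError
from .preprocess import DURATION
from .spatial_groups import SpatialPartition

__all__ = [
    "TrophallaxisEvent",
    "InteractionCountSeries",
    "AssortativityResult",
    "interaction_count_series",
    "fit_rate_glm",
    "build_network",
    "assortativity",
]


@dataclass(frozen=True)
class TrophallaxisEvent:
    """One food-sharing event between an unordered dyad; at least 2 s long."""

    ant_i: str
    ant_j: str
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start < 2:
            raise ValueError("trophallaxis events are at least two seconds long")

    @property
    def dyad(self) -> tuple[str, str]:
        return tuple(sorted((self.ant_i, self.ant_j)))


@dataclass
class InteractionCountSeries:
    """Number of events initiated each second of one colony-treatment recording."""

    counts: np.ndarray
    colony: str = ""
    treatment: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def interaction_count_series(
    events: list[TrophallaxisEvent],
    duration: int = DURATION,
    colony: str = "",
    treatment: str = "",
) -> InteractionCountSeries:
    """Per-second initiation counts; series length is ``duration + 1``."""
    starts = np.array([e.start for e in events], dtype=int)
    if starts.size and (starts.min() < 0 or starts.max() > duration):
        raise ValueError("event start outside the recording window")
    counts = np.bincount(starts, minlength=duration + 1)
    return InteractionCountSeries(counts=counts, colony=colony, treatment=treatment)


@dataclass
class RateGLMResult:
    """Sum-to-zero Poisson GLM of per-second initiation counts."""

    table: pd.DataFrame  # estimate, se, wald, CI, p per effect level
    pairwise: pd.DataFrame  # colony-by-colony contrasts of interaction terms
    model: object = field(repr=False, default=None)


def fit_rate_glm(series: list[InteractionCountSeries]) -> RateGLMResult:
    """Poisson log-link GLM: counts ~ colony * treatment, sum-to-zero coding.

    Every colony x treatment cell must be present.  The report lists the
    grand-mean intercept and the per-level deviations for all but the last
    level of each factor (the omitted level is minus the sum of the others),
    plus Wald statistics and 95% confidence limits.  ``pairwise`` compares
    the colony-specific treatment effects between colonies by Wald tests on
    linear combinations of the interaction terms.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {"count": s.counts, "colony": s.colony, "treatment": s.treatment}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    colonies = sorted(df["colony"].unique())
    treatments = sorted(df["treatment"].unique())
    cells = df.groupby(["colony", "treatment"]).size()
    if len(cells) < len(colonies) * len(treatments):
        raise FitError("every colony x treatment cell must be present")

    fit = smf.glm(
        "count ~ C(colony, Sum) * C(treatment, Sum)", df, family=sm.families.Poisson()
    ).fit()
    est = fit.params
    se = fit.bse
    wald = (est / se) ** 2
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "wald": wald,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": sps.chi2.sf(wald, df=1),
        }
    )

    # colony-specific interaction coefficients under sum coding; the omitted
    # last colony's deviation is minus the sum of the displayed ones
    inter_names = [
        n for n in est.index if "C(colony, Sum)" in n and "C(treatment, Sum)" in n
    ]
    k = len(est)
    vecs = {}
    for c, name in zip(colonies[:-1], inter_names):
        v = np.zeros(k)
        v[list(est.index).index(name)] = 1.0
        vecs[c] = v
    v_last = np.zeros(k)
    for name in inter_names:
        v_last[list(est.index).index(name)] = -1.0
    vecs[colonies[-1]] = v_last

    rows = []
    for a, b in itertools.combinations(colonies, 2):
        tt = fit.t_test(vecs[a] - vecs[b])
        rows.append(
            {
                "colony_a": a,
                "colony_b": b,
                "difference": float(np.squeeze(tt.effect)),
                "se": float(np.squeeze(tt.sd)),
                "z": float(np.squeeze(tt.tvalue)),
                "p": float(np.squeeze(tt.pvalue)),
            }
        )
    return RateGLMResult(table=table, pairwise=pd.DataFrame(rows), model=fit)


def build_network(
    events: list[TrophallaxisEvent], roster: list[str] | None = None
) -> nx.Graph:
    """Weighted trophallaxis graph; edge weight = number of events per dyad."""
    g = nx.Graph()
    if roster is not None:
        g.add_nodes_from(roster)
    for e in events:
        if e.ant_i == e.ant_j:
            raise ValueError(f"self-loop event for ant {e.ant_i}")
        u, v = e.dyad
        if g.has_edge(u, v):
            g.edges[u, v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g


@dataclass
class AssortativityResult:
    r: float
    se: float

    @property
    def z(self) -> float:
        if self.se == 0:
            return np.inf if self.r != 0 else np.nan
        return self.r / self.se


def _mixing_r(pair_weights: dict[tuple[int, int], float]) -> float:
    """Assortativity from {(group_a, group_b): total weight} (a <= b)."""
    groups = sorted({g for p in pair_weights for g in p})
    gi = {g: i for i, g in enumerate(groups)}
    e = np.zeros((len(groups), len(groups)))
    for (a, b), w in pair_weights.items():
        if a == b:
            e[gi[a], gi[a]] += w
        else:
            e[gi[a], gi[b]] += w / 2.0
            e[gi[b], gi[a]] += w / 2.0
    e /= e.sum()
    a_marg = e.sum(axis=1)
    sum_ab = float(a_marg @ a_marg)
    if np.isclose(sum_ab, 1.0):
        raise FitError("assortativity undefined: all edges in a single group")
    return (float(np.trace(e)) - sum_ab) / (1.0 - sum_ab)


def assortativity(net: nx.Graph, partition: SpatialPartition) -> AssortativityResult:
    """Discrete assortativity of the event network w.r.t. spatial groups.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) on the weighted
    mixing matrix (each event counted once).  The jackknife SE removes one
    unit of edge weight (one event) at a time and recomputes r; removals
    within the same group pair give identical replicates, so the sum over
    events collapses to a sum over group pairs.
    """
    for n in net.nodes:
        if n not in partition.labels:
            raise ValueError(f"node {n} has no spatial-group label")
    pair_weights: dict[tuple[int, int], float] = {}
    for u, v, w in net.edges(data="weight", default=1):
        key = tuple(sorted((partition.labels[u], partition.labels[v])))
        pair_weights[key] = pair_weights.get(key, 0.0) + float(w)
    if not pair_weights:
        raise FitError("assortativity undefined: the network has no edges")
    r = _mixing_r(pair_weights)
    total = sum(pair_weights.values())
    ss = 0.0
    if total > 1:
        for key, w in pair_weights.items():
            reduced = dict(pair_weights)
            if w > 1:
                reduced[key] = w - 1.0
            else:
                del reduced[key]
            try:
                r_i = _mixing_r(reduced)
            except FitError:
                continue  # replicate degenerate; contributes nothing
            ss += w * (r_i - r) ** 2  # w unit edges share this replicate value
    return AssortativityResult(r=r, se=float(np.sqrt(ss)))
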