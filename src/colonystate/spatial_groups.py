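"""Spatial-group detection from movement signatures.

Each ant's spatial signature is the distribution of its wall-aware distance
to the nest entrance over every in-nest second.  Pairwise similarity is
S(i, j) = 1 - KS(i, j), the complement of the Kolmogorov-Smirnov statistic
between the two signatures (invariant to common rescaling).  Louvain
community detection on the resulting complete weighted network partitions
the colony into spatial groups, which are then numbered 1 ... k by
increasing mean distance to the entrance; ants outside the nest for the
whole recording form group 0.

Robustness is quantified by re-detecting groups on perturbed networks whose
edge weights are resampled from beta distributions centred on the observed
similarities, and consistency across treatments by a Spearman permutation
test on the ordered group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms.community import louvain_communities, modularity
from scipy import stats

from .errors import FitError
from .geometry import NestGeometry
from .preprocess import AntTrack

__all__ = [
    "SpatialSignature",
    "SpatialPartition",
    "PerturbationConfig",
    "PerturbationResult",
    "spatial_signature",
    "ks_similarity",
    "build_similarity_network",
    "detect_groups",
    "spatial_partition",
    "perturb_and_score",
    "group_consistency",
]


@dataclass
class SpatialSignature:
    """Multiset of entrance distances (mm), one per in-nest second."""

    ant_id: str
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size and self.samples[0] < 0:
            raise ValueError("entrance distances must be non-negative")

    @property
    def empty(self) -> bool:
        return self.samples.size == 0

    @property
    def mean(self) -> float:
        return float(self.samples.mean()) if self.samples.size else np.nan


def spatial_signature(track: AntTrack, nest: NestGeometry) -> SpatialSignature:
    """Entrance-distance samples for every in-nest second of one track."""
    mask = track.in_nest
    if not mask.any():
        return SpatialSignature(track.ant_id, np.empty(0))
    engine = nest.grid_engine()
    return SpatialSignature(track.ant_id, engine.entrance_distances(track.xy[mask]))


def _ks_sorted(a: np.ndarray, b: np.ndarray) -> float:
    """KS statistic between two sorted sample arrays."""
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_similarity(a: SpatialSignature, b: SpatialSignature) -> float:
    """S = 1 - KS between two non-empty signatures, in [0, 1]."""
    if a.empty or b.empty:
        raise FitError(
            "similarity is undefined for an empty signature; "
            "outside-only ants belong to group 0"
        )
    return 1.0 - _ks_sorted(a.samples, b.samples)


def build_similarity_network(signatures: list[SpatialSignature]) -> nx.Graph:
    """Complete weighted similarity graph over ants with non-empty signatures.

    Node attribute ``mean_distance`` carries each ant's mean entrance
    distance, used downstream to order the detected groups.
    """
    sigs = [s for s in signatures if not s.empty]
    if len(sigs) < 2:
        raise ValueError("at least 2 non-empty signatures are required")
    g = nx.Graph()
    for s in sigs:
        g.add_node(s.ant_id, mean_distance=s.mean)
    for i, a in enumerate(sigs):
        for b in sigs[i + 1 :]:
            g.add_edge(a.ant_id, b.ant_id, weight=1.0 - _ks_sorted(a.samples, b.samples))
    return g


@dataclass
class SpatialPartition:
    """Ant -> spatial-group label; 0 is the outside-only group.

    Groups 1 ... k are numbered by increasing mean entrance distance, so
    group 1 sits closest to the entrance.
    """

    labels: dict[str, int]
    modularity: float | None = None

    def __post_init__(self):
        present = sorted(set(self.labels.values()))
        expect = list(range(0, len(present))) if 0 in present else list(
            range(1, len(present) + 1)
        )
        if present != expect:
            raise ValueError(f"group labels must be contiguous, got {present}")

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> frozenset:
        return frozenset(a for a, g in self.labels.items() if g == label)

    def groups(self) -> dict[int, frozenset]:
        return {g: self.members(g) for g in sorted(set(self.labels.values()))}


def detect_groups(net: nx.Graph, seed: int | None = 0) -> SpatialPartition:
    """Louvain modularity maximisation on the similarity network.

    Detected communities are relabelled 1 ... k by increasing mean of the
    member ants' ``mean_distance`` node attribute.
    """
    if net.number_of_nodes() == 1:
        return SpatialPartition(labels={next(iter(net)): 1}, modularity=None)
    comms = louvain_communities(net, weight="weight", seed=seed)
    q = modularity(net, comms, weight="weight")
    means = []
    for c in comms:
        md = [net.nodes[a].get("mean_distance", np.nan) for a in c]
        means.append(np.nanmean(md) if np.any(np.isfinite(md)) else np.inf)
    order = np.argsort(means, kind="stable")
    labels: dict[str, int] = {}
    for rank, ci in enumerate(order, start=1):
        for a in comms[ci]:
            labels[a] = rank
    return SpatialPartition(labels=labels, modularity=q)


def spatial_partition(
    tracks: list[AntTrack], nest: NestGeometry, seed: int | None = 0
) -> SpatialPartition:
    """Full colony partition: signatures -> network -> Louvain -> group 0.

    Ants with empty signatures (outside for the entire recording) are
    excluded from the network and appended as group 0.
    """
    sigs = [spatial_signature(tr, nest) for tr in tracks]
    outside = [s.ant_id for s in sigs if s.empty]
    net = build_similarity_network([s for s in sigs if not s.empty])
    part = detect_groups(net, seed=seed)
    labels = dict(part.labels)
    for a in outside:
        labels[a] = 0
    return SpatialPartition(labels=labels, modularity=part.modularity)


@dataclass(frozen=True)
class PerturbationConfig:
    """Settings for the beta-perturbation robustness procedure.

    Each replicate resamples every edge weight from Beta(alpha, beta_shape)
    with alpha chosen so the mean equals the observed similarity (or
    ``zero_similarity_mean`` where the similarity is 0); beta_shape = 4
    corresponds to a mean change in similarity of about 10%.
    """

    n_reps: int = 1000
    beta_shape: float = 4.0
    zero_similarity_mean: float = 0.001
    seed: int | None = 0

    def __post_init__(self):
        if self.beta_shape <= 0:
            raise ValueError("beta_shape must be positive")


@dataclass
class PerturbationResult:
    changed_fraction: float  # mean over replicates
    max_changed_fraction: float
    per_replicate: np.ndarray = field(repr=False)


def _ant_changed(ant, ref_group: frozenset, rep_group: frozenset) -> bool:
    """Group-change rule: fewer than half of the ant's companions in the
    smaller of its two groups are present in the larger one.

    Size ties are resolved toward the reference group (it plays the role of
    the smaller group)."""
    if len(ref_group) <= len(rep_group):
        small, large = ref_group, rep_group
    else:
        small, large = rep_group, ref_group
    companions = small - {ant}
    if not companions:
        return False
    return len(companions & large) < len(companions) / 2.0


def perturb_and_score(
    net: nx.Graph,
    reference: SpatialPartition,
    cfg: PerturbationConfig = PerturbationConfig(),
) -> PerturbationResult:
    """Fraction of ants changing group under beta-perturbed networks."""
    if cfg.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    edges = list(net.edges())
    mu = np.array([net.edges[e]["weight"] for e in edges])
    mu = np.where(mu <= 0, cfg.zero_similarity_mean, mu)
    mu = np.minimum(mu, 0.999)  # keep alpha finite for (near-)identical ants
    alpha = cfg.beta_shape * mu / (1.0 - mu)

    ants = [a for a in net.nodes if a in reference.labels]
    ref_groups = {a: reference.members(reference.labels[a]) for a in ants}
    work = net.copy()
    fractions = np.empty(cfg.n_reps)
    for r in range(cfg.n_reps):
        w = rng.beta(alpha, cfg.beta_shape)
        for (u, v), wi in zip(edges, w):
            work.edges[u, v]["weight"] = wi
        rep = detect_groups(work, seed=int(rng.integers(2**31 - 1)))
        rep_groups = rep.groups()
        changed = sum(
            _ant_changed(a, ref_groups[a], rep_groups[rep.labels[a]]) for a in ants
        )
        fractions[r] = changed / len(ants)
    return PerturbationResult(
        changed_fraction=float(fractions.mean()),
        max_changed_fraction=float(fractions.max()),
        per_replicate=fractions,
    )


def group_consistency(
    high: SpatialPartition,
    low: SpatialPartition,
    n_perm: int = 40_000,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Spearman correlation of group labels across treatments + permutation p.

    Only ants present in both partitions are used (case-wise deletion of
    ants that died between treatments is the caller's responsibility and
    amounts to dropping them from either partition).  The two-sided p-value
    comes from ``n_perm`` random relabelings.
    """
    shared = sorted(set(high.labels) & set(low.labels))
    if len(shared) < 3:
        raise FitError("fewer than 3 ants shared between treatments")
    a = np.array([high.labels[s] for s in shared], dtype=float)
    b = np.array([low.labels[s] for s in shared], dtype=float)
    rho = float(stats.spearmanr(a, b).statistic)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra = (ra - ra.mean()) / ra.std()
    rb = (rb - rb.mean()) / rb.std()
    rng = np.random.default_rng(seed)
    n = len(shared)
    count = 0
    chunk = 2000
    done = 0
    observed = abs(np.mean(ra * rb))
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)
        r_perm = (rb[perm] * ra).mean(axis=1)
        count += int((np.abs(r_perm) >= observed - 1e-12).sum())
        done += m
    p = (count + 1) / (n_perm + 1)
    return rho, float(p)
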