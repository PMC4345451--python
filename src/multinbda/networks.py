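"""Association networks from co-observation data.

Individuals detected at the same location in the same sampling time block
form a *gathering event*; dyadic association strength is the simple ratio
index (SRI) over sampling periods, interpreted as the proportion of time two
individuals spend together given that at least one of them was observed.
Networks can be split into attribute-defined layers (e.g. conspecific vs.
heterospecific edges) and summarised with standard descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ObservationStream",
    "GatheringEvent",
    "AssociationNetwork",
    "NetworkMetrics",
    "EmptyStreamError",
    "detect_gathering_events",
    "compute_sri_network",
    "split_network_by_attribute",
    "network_metrics",
]


class EmptyStreamError(ValueError):
    """Raised when an observation stream contains no records."""


@dataclass(frozen=True)
class ObservationStream:
    """A stream of (individual, location, time_block) detection records.

    ``time_block`` is the integer index of a fixed-width sampling window
    (15 s for RFID feeder loggers); duplicates of the same triple carry no
    extra information and are collapsed on access.
    """

    records: tuple[tuple[str, str, int], ...]

    def __init__(self, records: Iterable[tuple[str, str, int]]):
        recs = tuple((str(i), str(l), int(b)) for i, l, b in records)
        for _, _, b in recs:
            if b < 0:
                raise ValueError(f"time_block must be >= 0, got {b}")
        object.__setattr__(self, "records", recs)

    def deduplicated(self) -> tuple[tuple[str, str, int], ...]:
        return tuple(dict.fromkeys(self.records))

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GatheringEvent:
    """Individuals co-detected at one location in one time block."""

    location_id: str
    time_block: int
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError("a gathering event must have at least one member")


@dataclass
class AssociationNetwork:
    """Symmetric weighted association network over labelled individuals.

    ``weights[i, j]`` is the SRI (or any association index in [0, 1]) between
    ``node_ids[i]`` and ``node_ids[j]``; ``n_obs`` counts the gathering
    events each individual appeared in (the residency covariate source).
    """

    node_ids: list[str]
    weights: np.ndarray
    n_obs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.node_ids = [str(i) for i in self.node_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {n} node ids"
            )
        if self.n_obs is None:
            self.n_obs = np.zeros(n, dtype=int)
        self.n_obs = np.asarray(self.n_obs)
        if self.n_obs.shape != (n,):
            raise ValueError("n_obs must have one entry per node")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("association weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("association weights must have zero diagonal")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("association weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])


def detect_gathering_events(stream: ObservationStream) -> list[GatheringEvent]:
    """Group detections into gathering events by (location, time_block).

    Two individuals belong to the same event iff they share both the
    location and the sampling time block. Duplicate records collapse.
    """
    records = stream.deduplicated()
    if not records:
        raise EmptyStreamError("observation stream is empty")
    groups: dict[tuple[str, int], set[str]] = {}
    for ind, loc, block in records:
        groups.setdefault((loc, block), set()).add(ind)
    return [
        GatheringEvent(location_id=loc, time_block=block, members=frozenset(members))
        for (loc, block), members in sorted(groups.items())
    ]


def compute_sri_network(events: Sequence[GatheringEvent]) -> AssociationNetwork:
    """Simple-ratio-index network from a list of gathering events.

    For each dyad (A, B) the sampling periods (time blocks) in which at
    least one of them was observed are classified as: seen together (x),
    A alone (yA), B alone (yB), or both seen but in different simultaneous
    events (yAB).  SRI = x / (x + yA + yB + yAB).  A dyad with an empty
    denominator gets weight 0.  ``n_obs`` counts gathering events.
    """
    if not events:
        raise EmptyStreamError("no gathering events provided")
    ids = sorted({m for e in events for m in e.members})
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)

    by_block: dict[int, list[GatheringEvent]] = {}
    for e in events:
        by_block.setdefault(e.time_block, []).append(e)

    together = np.zeros((n, n))
    both_present = np.zeros((n, n))
    n_blocks = np.zeros(n)
    n_obs = np.zeros(n, dtype=int)

    for e in events:
        for m in e.members:
            n_obs[idx[m]] += 1

    for _, evs in by_block.items():
        present = np.zeros(n, dtype=bool)
        tog = np.zeros((n, n), dtype=bool)
        for e in evs:
            mem = np.fromiter((idx[m] for m in e.members), dtype=int)
            present[mem] = True
            tog[np.ix_(mem, mem)] = True
        together += tog
        both_present += np.outer(present, present)
        n_blocks += present

    # denominator = blocks with A + blocks with B - blocks with both
    # (x + yA + yB + yAB written without double counting)
    denom = n_blocks[:, None] + n_blocks[None, :] - both_present
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(denom > 0, together / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(weights, 0.0)
    weights = 0.5 * (weights + weights.T)  # exact symmetry against fp noise
    return AssociationNetwork(node_ids=ids, weights=weights, n_obs=n_obs)


def split_network_by_attribute(
    net: AssociationNetwork, attribute: Mapping[str, str]
) -> tuple[AssociationNetwork, AssociationNetwork]:
    """Split a network into same-category and cross-category layers.

    Returns ``(intra, inter)`` where the intra layer keeps an edge iff both
    endpoints share the attribute value and the inter layer is its exact
    complement; the two layers sum element-wise to the input. Node order and
    observation counts are preserved in both layers.
    """
    missing = [i for i in net.node_ids if i not in attribute]
    if missing:
        raise KeyError(f"nodes missing attribute value: {missing}")
    cats = np.array([attribute[i] for i in net.node_ids], dtype=object)
    same = cats[:, None] == cats[None, :]
    intra_w = np.where(same, net.weights, 0.0)
    inter_w = np.where(~same, net.weights, 0.0)
    np.fill_diagonal(intra_w, 0.0)
    intra = AssociationNetwork(list(net.node_ids), intra_w, net.n_obs.copy())
    inter = AssociationNetwork(list(net.node_ids), inter_w, net.n_obs.copy())
    return intra, inter


@dataclass
class NetworkMetrics:
    """Descriptive network statistics with their conventions spelled out."""

    mean_weighted_degree: float  # mean over nodes of strength / (n - 1)
    mean_binary_degree: float  # mean over nodes of (# edges with w > 0) / (n - 1)
    edge_density: float  # proportion of dyads with w > 0
    degree_assortativity: float | None  # Pearson r of endpoint binary degrees
    strength_assortativity: float | None  # Pearson r of endpoint strengths
    assortativity_defined: bool
    eigenvector_centrality: np.ndarray | None  # max-normalised Perron vector
    conventions: str = (
        "degrees normalised by (n-1); assortativity over directed edge endpoint "
        "pairs of the thresholded (w>0) graph; centrality is the dominant "
        "eigenvector of the weight matrix scaled to max 1"
    )


def _endpoint_assortativity(values: np.ndarray, adj: np.ndarray) -> float | None:
    """Pearson correlation of ``values`` across directed edge endpoints."""
    ii, jj = np.nonzero(adj)
    if len(ii) < 2:
        return None
    x, y = values[ii], values[jj]
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def network_metrics(net: AssociationNetwork) -> NetworkMetrics:
    """Weighted/binary degree, edge density, assortativity, centrality."""
    w = net.weights
    n = net.n_nodes
    binary = (w > 0).astype(float)
    if n > 1:
        strength = w.sum(axis=1)
        bdeg = binary.sum(axis=1)
        mean_wd = float(np.mean(strength / (n - 1)))
        mean_bd = float(np.mean(bdeg / (n - 1)))
        density = float(binary.sum() / (n * (n - 1)))
    else:
        strength = np.zeros(n)
        bdeg = np.zeros(n)
        mean_wd = mean_bd = density = 0.0

    deg_assort = _endpoint_assortativity(bdeg, binary)
    str_assort = _endpoint_assortativity(strength, binary)

    if np.any(w > 0):
        evals, evecs = np.linalg.eigh(w)
        v = np.abs(evecs[:, np.argmax(evals)])
        centrality = v / v.max()
    else:
        centrality = None

    return NetworkMetrics(
        mean_weighted_degree=mean_wd,
        mean_binary_degree=mean_bd,
        edge_density=density,
        degree_assortativity=deg_assort,
        strength_assortativity=str_assort,
        assortativity_defined=deg_assort is not None,
        eigenvector_centrality=centrality,
    )
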