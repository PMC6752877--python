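"""Weighted undirected network metrics: density, clustering, modularity, assortativity.

All metrics operate on thresholded connectivity networks and retain edge
weights — density uses binary edge presence (the fraction of realized unique
pairs), clustering is the Onnela geometric-mean triangle form, modularity is
Newman's weighted Q maximized by seeded Louvain restarts, and assortativity
is the Pearson correlation of endpoint node strengths over the edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import ThresholdedNetwork

__all__ = [
    "TopologyMetrics",
    "network_density",
    "clustering_coefficient",
    "modularity",
    "modularity_q",
    "assortativity",
    "topology_report",
]

logger = logging.getLogger(__name__)


@dataclass
class TopologyMetrics:
    """Bundle of the four topology metrics for one thresholded network.

    ``modularity_q`` is None when the network has no edges (Q undefined);
    ``assortativity_r`` is NaN when endpoint-strength variance is zero.
    ``flags`` collects the degeneracies encountered.
    """

    density: float
    clustering_per_node: np.ndarray
    clustering_mean: float
    modularity_q: float | None
    partition: np.ndarray | None
    n_communities: int | None
    assortativity_r: float
    condition: str = "baseline"
    div: int = 0
    config: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _check_net(net: ThresholdedNetwork) -> np.ndarray:
    w = net.weights
    if w.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    return w


def network_density(net: ThresholdedNetwork) -> float:
    """Fraction of realized unique pairs: nonzero pairs / (n(n−1)/2)."""
    w = _check_net(net)
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    return float(np.count_nonzero(w[iu]) / iu[0].size)


def clustering_coefficient(net: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering coefficient per node, plus the mean.

    Weights are first scaled by the global maximum weight; node i's
    coefficient is the sum over triangles through i of the geometric mean of
    the three scaled weights, times 2/(k_i(k_i−1)) with k_i the binary
    degree.  Nodes with k_i < 2 get 0.  On 0/1 weights this reduces to the
    binary triangle fraction.  Negative weights violate the contract.
    """
    w = _check_net(net)
    if np.any(w < 0):
        raise ValueError("clustering requires nonnegative weights")
    wmax = w.max()
    if wmax == 0:
        zeros = np.zeros(w.shape[0])
        return zeros, 0.0
    cube = np.cbrt(w / wmax)
    num = np.diagonal(cube @ cube @ cube)  # 2 × (geometric-mean triangle sum)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return c, float(c.mean())


def modularity_q(
    weights: np.ndarray, labels: np.ndarray, gamma: float = 1.0
) -> float:
    """Newman's weighted modularity of a given partition.

    Q = (1/2m) Σ_ij [w_ij − γ s_i s_j / (2m)] δ(c_i, c_j), with s the node
    strengths and m the total edge weight.
    """
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(labels)
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for an edgeless network")
    s = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((w - gamma * np.outer(s, s) / two_m) * same).sum() / two_m)


def modularity(
    net: ThresholdedNetwork,
    gamma: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Best-Q Louvain partition over seeded restarts.

    Runs Louvain community detection ``restarts`` times with seeds
    ``seed, seed+1, …`` and keeps the partition with the highest weighted
    modularity at resolution ``gamma``.  Deterministic given ``seed``.
    Raises on an edgeless network (Q undefined).
    """
    w = _check_net(net)
    if np.any(w < 0):
        raise ValueError("modularity requires nonnegative weights")
    if w.sum() <= 0:
        raise ValueError("modularity undefined for an edgeless network")
    g = nx.from_numpy_array(w)
    best_labels: np.ndarray | None = None
    best_q = -np.inf
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=gamma, seed=seed + r
        )
        labels = np.empty(w.shape[0], dtype=int)
        for ci, members in enumerate(comms):
            labels[list(members)] = ci
        q = modularity_q(w, labels, gamma=gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, float(best_q)


def assortativity(net: ThresholdedNetwork, variant: str = "strength") -> float:
    """Pearson correlation of endpoint node strengths over the edge list.

    Each undirected edge contributes both orientations, so the statistic is
    symmetric.  ``variant="strength"`` (default) correlates weighted node
    strengths; ``variant="degree"`` uses binary degrees for sensitivity
    checks.  Returns NaN when endpoint values have zero variance (e.g. a
    regular graph), where the correlation is undefined.
    """
    if variant not in ("strength", "degree"):
        raise ValueError("variant must be 'strength' or 'degree'")
    w = _check_net(net)
    iu = np.triu_indices(w.shape[0], 1)
    present = w[iu] != 0
    if np.count_nonzero(present) < 2:
        raise ValueError("assortativity needs at least 2 edges")
    s = w.sum(axis=1) if variant == "strength" else (w > 0).sum(axis=1).astype(float)
    ei, ej = iu[0][present], iu[1][present]
    x = np.concatenate([s[ei], s[ej]])
    y = np.concatenate([s[ej], s[ei]])
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def topology_report(
    net: ThresholdedNetwork,
    gamma: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
    assortativity_variant: str = "strength",
) -> TopologyMetrics:
    """Compute all four metrics on one thresholded network.

    Negative edge weights surviving the threshold (possible at large p on
    signed correlation matrices) are clipped to 0 before clustering and
    modularity, whose weighted forms require nonnegativity; the clipping is
    logged and flagged.  Density is computed before clipping.  A network left
    edgeless reports Q as missing rather than raising, so DIV sweeps do not
    abort.
    """
    flags: list[str] = []
    density = network_density(net)
    w = net.weights
    if np.any(w < 0):
        n_neg = int(np.count_nonzero(w[np.triu_indices(w.shape[0], 1)] < 0))
        logger.info("clipping %d negative-weight edges to 0 for weighted metrics", n_neg)
        flags.append(f"clipped_{n_neg}_negative_edges")
        net = ThresholdedNetwork(
            weights=np.clip(w, 0.0, None),
            threshold=net.threshold,
            neuron_ids=net.neuron_ids,
            condition=net.condition,
            div=net.div,
        )
    c_node, c_mean = clustering_coefficient(net)
    if net.weights.sum() > 0:
        partition, q = modularity(net, gamma=gamma, restarts=restarts, seed=seed)
        n_comm = int(np.unique(partition).size)
    else:
        partition, q, n_comm = None, None, None
        flags.append("modularity_undefined_edgeless")
    try:
        r = assortativity(net, variant=assortativity_variant)
    except ValueError:
        r = float("nan")
        flags.append("assortativity_too_few_edges")
    if np.isnan(r) and "assortativity_too_few_edges" not in flags:
        flags.append("assortativity_undefined_zero_variance")
    return TopologyMetrics(
        density=density,
        clustering_per_node=c_node,
        clustering_mean=c_mean,
        modularity_q=q,
        partition=partition,
        n_communities=n_comm,
        assortativity_r=r,
        condition=net.condition,
        div=net.div,
        config={
            "gamma": gamma,
            "restarts": restarts,
            "seed": seed,
            "assortativity_variant": assortativity_variant,
            "threshold": net.threshold,
        },
        flags=flags,
    )
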