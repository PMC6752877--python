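"""Spearman functional-connectivity matrices and thresholding.

Functional connectivity between two neurons is the Spearman rank correlation
of their calcium traces over an entire condition window.  The resulting
symmetric matrix is turned into a weighted network either by a proportional
threshold (keep the strongest fraction p of unique pairs — the study's
default is p = 0.15) or by an absolute correlation cutoff swept from 0.05 to
1.00 in 0.05 steps for densiometric curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import TraceSet

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "functional_connectivity",
    "proportional_threshold",
    "absolute_threshold",
    "density_sweep",
    "SWEEP_THRESHOLDS",
]

#: Absolute-threshold sweep grid: 0.05, 0.10, …, 1.00.
SWEEP_THRESHOLDS = np.round(np.arange(1, 21) * 0.05, 2)


@dataclass
class ConnectivityMatrix:
    """Symmetric Spearman-ρ matrix for one condition; self-pairs zeroed."""

    rho: np.ndarray
    condition: str = "baseline"
    div: int = 0
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        n = self.rho.shape[0]
        if self.rho.ndim != 2 or self.rho.shape[1] != n:
            raise ValueError("rho must be square")
        if not np.allclose(self.rho, self.rho.T, atol=1e-9):
            raise ValueError("rho must be symmetric")
        if np.any(np.abs(np.diag(self.rho)) > 0):
            raise ValueError("diagonal must be zero")
        off = self.rho[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        if self.neuron_ids is None:
            self.neuron_ids = np.array([f"n{i:04d}" for i in range(n)])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape[0] != n:
                raise ValueError("neuron_ids length must match matrix size")

    @property
    def n_neurons(self) -> int:
        return self.rho.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_neurons
        return n * (n - 1) // 2


@dataclass
class ThresholdedNetwork:
    """Weighted network kept after thresholding a connectivity matrix.

    Retained edges carry their original ρ values; everything else is 0.
    ``threshold`` records how the network was produced, e.g.
    ``{"mode": "proportional", "p": 0.15}``.
    """

    weights: np.ndarray
    threshold: dict
    neuron_ids: np.ndarray | None = None
    condition: str = "baseline"
    div: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape[1] != n:
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(self.weights)) > 0):
            raise ValueError("diagonal must be zero")
        if self.neuron_ids is None:
            self.neuron_ids = np.array([f"n{i:04d}" for i in range(n)])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_neurons, 1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Retained edges as (i, j, weight) rows, i < j."""
        iu = np.triu_indices(self.n_neurons, 1)
        keep = self.weights[iu] != 0
        return pd.DataFrame(
            {"i": iu[0][keep], "j": iu[1][keep], "weight": self.weights[iu][keep]}
        )


def functional_connectivity(traces: TraceSet) -> ConnectivityMatrix:
    """Pairwise Spearman ρ over the full condition window.

    Implemented as Pearson correlation of average-ranked traces (ties get
    average ranks), which is the standard Spearman estimator.  The matrix is
    exactly symmetrized and its diagonal forced to zero.  A constant
    (zero-variance) trace makes ρ undefined for all its pairs; those entries
    are set to 0 and a warning names the offending neurons.
    """
    if traces.n_frames < 3:
        raise ValueError("need at least 3 frames for rank correlation")
    if traces.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    ranks = rankdata(traces.values, axis=1, method="average")
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        ids = ", ".join(str(traces.neuron_ids[i]) for i in np.flatnonzero(constant))
        warnings.warn(
            f"constant trace(s) make Spearman ρ undefined; setting their pairs "
            f"to 0 for neuron(s): {ids}",
            UserWarning,
            stacklevel=2,
        )
        # corrcoef would emit divide warnings and NaNs for these rows
        ranks = ranks.copy()
        ranks[constant] = np.arange(traces.n_frames)  # placeholder, rows zeroed below
    rho = np.corrcoef(ranks)
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return ConnectivityMatrix(
        rho=rho,
        condition=traces.condition,
        div=traces.div,
        neuron_ids=traces.neuron_ids,
    )


def proportional_threshold(
    c: ConnectivityMatrix, p: float = 0.15, rank_by: str = "signed"
) -> ThresholdedNetwork:
    """Keep the strongest fraction ``p`` of unique pairs as weighted edges.

    The n(n−1)/2 unique off-diagonal entries are ranked descending —
    "strongest" means largest signed ρ by default (``rank_by="abs"`` ranks by
    magnitude instead) — and the top ``floor(p·E)`` are retained with their ρ
    values.  Ties at the cutoff break deterministically by (i, j)
    lexicographic order, so density equals floor(p·E)/E exactly.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if rank_by not in ("signed", "abs"):
        raise ValueError("rank_by must be 'signed' or 'abs'")
    n = c.n_neurons
    ii, jj = np.triu_indices(n, 1)
    vals = c.rho[ii, jj]
    key = np.abs(vals) if rank_by == "abs" else vals
    order = np.lexsort((jj, ii, -key))  # descending value, then (i, j)
    k = int(np.floor(p * vals.size))
    keep = order[:k]
    w = np.zeros_like(c.rho)
    w[ii[keep], jj[keep]] = vals[keep]
    w = w + w.T
    return ThresholdedNetwork(
        weights=w,
        threshold={"mode": "proportional", "p": p, "rank_by": rank_by},
        neuron_ids=c.neuron_ids,
        condition=c.condition,
        div=c.div,
    )


def absolute_threshold(c: ConnectivityMatrix, t: float) -> ThresholdedNetwork:
    """Keep edges with ρ ≥ t (signed comparison), t ∈ (0, 1]."""
    if not 0.0 < t <= 1.0:
        raise ValueError(f"t must lie in (0, 1], got {t}")
    w = np.where(c.rho >= t, c.rho, 0.0)
    np.fill_diagonal(w, 0.0)
    return ThresholdedNetwork(
        weights=w,
        threshold={"mode": "absolute", "t": t},
        neuron_ids=c.neuron_ids,
        condition=c.condition,
        div=c.div,
    )


def density_sweep(c: ConnectivityMatrix) -> pd.DataFrame:
    """Density of the absolute-thresholded network at t = 0.05, 0.10, …, 1.00.

    Returns a 20-row DataFrame with columns ``threshold`` and ``density``;
    density is non-increasing in t by construction.
    """
    n = c.n_neurons
    iu = np.triu_indices(n, 1)
    vals = c.rho[iu]
    e = vals.size
    rows = [
        {"threshold": float(t), "density": float(np.count_nonzero(vals >= t) / e)}
        for t in SWEEP_THRESHOLDS
    ]
    return pd.DataFrame(rows)
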