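"""Baseline-vs-treatment comparison statistics.

Two families of analyses: (1) the per-pair unity-deviation distribution —
each neuron pair's (ρ_baseline, ρ_treatment) point is reduced to its signed
distance from the y = x line, and the pooled distribution is summarized by
its moments (skewness g1, excess kurtosis g2) and normality/median tests;
(2) simple linear regression of a per-recording metric (mean connectivity,
assortativity, …) on culture age in days in vitro.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix

__all__ = [
    "PairDeviationSet",
    "DeviationStats",
    "DivTrend",
    "unity_deviation",
    "deviation_stats",
    "div_regression",
    "mean_connectivity",
]


@dataclass
class PairDeviationSet:
    """Per-pair (ρ_base, ρ_treat) with signed unity deviations.

    Positive d favors the treatment condition; negative d favors baseline.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    rho_base: np.ndarray
    rho_treat: np.ndarray
    d: np.ndarray
    scale: str = "perpendicular"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.d)):
            raise ValueError("deviations must be finite")

    @property
    def n_pairs(self) -> int:
        return self.d.size

    @staticmethod
    def pool(sets: list["PairDeviationSet"]) -> "PairDeviationSet":
        """Pool pairs across recordings (pair indices kept per-recording)."""
        if not sets:
            raise ValueError("nothing to pool")
        scale = sets[0].scale
        if any(s.scale != scale for s in sets):
            raise ValueError("cannot pool deviation sets with different scales")
        return PairDeviationSet(
            pair_i=np.concatenate([s.pair_i for s in sets]),
            pair_j=np.concatenate([s.pair_j for s in sets]),
            rho_base=np.concatenate([s.rho_base for s in sets]),
            rho_treat=np.concatenate([s.rho_treat for s in sets]),
            d=np.concatenate([s.d for s in sets]),
            scale=scale,
        )


@dataclass
class DeviationStats:
    """Moment and test summary of a unity-deviation distribution.

    ``g1``/``g2`` are the population (biased) Fisher–Pearson skewness and
    excess kurtosis — a normal distribution has g2 = 0.  ``ks_p`` is an
    approximate Kolmogorov–Smirnov p-value against a normal with the sample's
    mean and SD (parameters are estimated, so the p-value is optimistic in
    the Lilliefors sense); ``wilcoxon_p`` is a signed-rank test of median 0.
    """

    n: int
    mean: float
    g1: float
    g2: float
    ks_p: float
    wilcoxon_p: float
    flags: list[str] = field(default_factory=list)


@dataclass
class DivTrend:
    """Ordinary least-squares trend of a metric across culture age."""

    metric: str
    condition: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def unity_deviation(
    base: ConnectivityMatrix,
    treat: ConnectivityMatrix,
    scale: str = "perpendicular",
) -> PairDeviationSet:
    """Signed distance of each pair's (ρ_base, ρ_treat) from the unity line.

    ``scale="perpendicular"`` (default) gives the geometric point-to-line
    distance (ρ_treat − ρ_base)/√2; ``scale="raw"`` gives the plain
    difference.  Shape statistics (g1, g2, KS, Wilcoxon) are invariant to
    this positive rescaling, so the choice cannot change any reported test.
    """
    if base.n_neurons != treat.n_neurons or np.any(base.neuron_ids != treat.neuron_ids):
        raise ValueError("baseline and treatment matrices must share neuron_ids")
    if scale not in ("perpendicular", "raw"):
        raise ValueError("scale must be 'perpendicular' or 'raw'")
    iu = np.triu_indices(base.n_neurons, 1)
    rb = base.rho[iu]
    rt = treat.rho[iu]
    diff = rt - rb
    d = diff / np.sqrt(2.0) if scale == "perpendicular" else diff
    return PairDeviationSet(
        pair_i=iu[0], pair_j=iu[1], rho_base=rb, rho_treat=rt, d=d, scale=scale
    )


def deviation_stats(dset: PairDeviationSet | np.ndarray) -> DeviationStats:
    """Moments and normality/median tests for a pooled deviation sample.

    Skewness g1 = m3/m2^(3/2) and excess kurtosis g2 = m4/m2² − 3 use
    population moment estimators (normal reference: 0).  KS tests d against
    Normal(mean(d), sd(d)); Wilcoxon signed-rank (normal approximation)
    tests median(d) = 0.  Requires at least 8 pairs; a zero-variance sample
    gets NaN statistics with a flag instead of raising.
    """
    d = dset.d if isinstance(dset, PairDeviationSet) else np.asarray(dset, dtype=float)
    n = d.size
    if n < 8:
        raise ValueError("need at least 8 pairs for distribution statistics")
    mean = float(d.mean())
    sd = float(d.std())  # population SD
    if sd == 0:
        return DeviationStats(
            n=n, mean=mean, g1=float("nan"), g2=float("nan"),
            ks_p=float("nan"), wilcoxon_p=float("nan"),
            flags=["zero_variance"],
        )
    g1 = float(stats.skew(d, bias=True))
    g2 = float(stats.kurtosis(d, fisher=True, bias=True))
    ks_p = float(stats.kstest(d, "norm", args=(mean, sd)).pvalue)
    if np.all(d == 0):  # unreachable with sd>0, kept for clarity
        wilcoxon_p = float("nan")
    else:
        wilcoxon_p = float(
            stats.wilcoxon(d, zero_method="wilcox", method="approx").pvalue
        )
    return DeviationStats(n=n, mean=mean, g1=g1, g2=g2, ks_p=ks_p, wilcoxon_p=wilcoxon_p)


def div_regression(
    div: np.ndarray, values: np.ndarray, metric: str = "", condition: str = ""
) -> DivTrend:
    """Simple linear regression of a metric on culture age (days in vitro).

    Returns the slope per day, intercept, r², and the two-sided p-value for
    slope ≠ 0.  Needs at least 3 distinct DIV values.
    """
    div = np.asarray(div, dtype=float)
    values = np.asarray(values, dtype=float)
    if div.shape != values.shape:
        raise ValueError("div and values must align")
    if np.unique(div).size < 3:
        raise ValueError("need at least 3 distinct DIV values for a trend")
    if np.ptp(values) == 0:
        # constant metric: flat trend, no variance explained, no evidence
        return DivTrend(
            metric=metric,
            condition=condition,
            slope=0.0,
            intercept=float(values[0]),
            r_squared=0.0,
            p_value=1.0,
            n_points=div.size,
        )
    res = stats.linregress(div, values)
    return DivTrend(
        metric=metric,
        condition=condition,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=div.size,
    )


def mean_connectivity(c: ConnectivityMatrix) -> float:
    """Mean of the n(n−1)/2 unique off-diagonal ρ values."""
    if c.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    iu = np.triu_indices(c.n_neurons, 1)
    return float(c.rho[iu].mean())
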