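"""Synthetic mixed dopaminergic/GABAergic culture: spikes → GCaMP6f traces → movies.

The study's raw recordings are unpublished, so every pipeline stage is
verified against data from this generative model instead.  Latent spiking is
produced by a multiple-interaction process (MIP): each module owns a Poisson
"mother" train and members copy each mother spike independently, which gives
Poisson marginals with a closed-form pairwise spike-count correlation equal
to the copy probability.  Calcium fluorescence is the spike train convolved
with a difference-of-exponentials GCaMP6f kernel, plus Gaussian noise.
Pharmacology is a rate multiplier on D2-expressing neurons only: < 1 models
methamphetamine-evoked dopamine acting on D2 receptors (suppression), ≥ 1
models the same challenge under sulpiride blockade.  Culture ageing is a
per-day geometric decay of the within-module copy probability, which lowers
mean pairwise correlation with DIV.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import TraceSet

__all__ = [
    "SimSpec",
    "SpikeTrains",
    "CONDITIONS",
    "simulate_spikes",
    "spikes_to_fluorescence",
    "simulate_traces",
    "render_movie",
    "generate_planted_network",
]

#: Recognized condition labels and their index in seed derivation.
CONDITIONS = ("baseline", "meth", "meth+sulpiride")

#: Reference culture age (days in vitro) at which the within-module copy
#: probability equals its configured value; ages beyond it decay geometrically.
DIV_REF = 9


@dataclass
class SimSpec:
    """Full parameterization of a synthetic culture.

    Defaults follow the study's acquisition (10 Hz, 2-minute condition
    windows) and composition (~12% dopaminergic, remainder GABAergic with D2
    receptors); the kernel constants are literature-typical for GCaMP6f.

    Parameters
    ----------
    n_neurons:
        Number of segmented neurons.
    frac_da:
        Fraction of dopaminergic neurons (rest GABAergic).
    frac_d2:
        Probability that a GABAergic neuron expresses D2 receptors.
        Dopaminergic neurons are always D2+ (autoreceptors).
    n_modules:
        Number of correlated modules; neurons are assigned round-robin.
    within_module_share:
        MIP copy probability — equals the within-module spike-count
        correlation at DIV_REF.
    base_rate:
        Marginal spontaneous firing rate per neuron, spikes/s.
    background_rate:
        Additional independent Poisson rate per neuron, spikes/s.
    drug_factor:
        Rate multiplier on D2+ neurons in the "meth" window.
    sulpiride_factor:
        Rate multiplier on D2+ neurons in the "meth+sulpiride" window
        (≥ 1: blockade removes suppression and disinhibits the network).
    div_decay:
        Per-day multiplicative decay of within_module_share for div > DIV_REF.
    div:
        Culture age in days in vitro.
    """

    n_neurons: int = 100
    frac_da: float = 0.12
    frac_d2: float = 1.0
    n_modules: int = 4
    within_module_share: float = 0.35
    base_rate: float = 1.0
    background_rate: float = 0.0
    duration_s: float = 120.0
    dt_s: float = 0.01
    frame_rate_hz: float = 10.0
    tau_rise_s: float = 0.1
    tau_decay_s: float = 0.6
    amp_per_spike: float = 0.4
    f0: float = 50.0
    noise_sd: float = 1.0
    drug_factor: float = 0.5
    sulpiride_factor: float = 1.3
    div_decay: float = 1.0
    div: int = DIV_REF
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_da", "frac_d2", "within_module_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be positive")
        if self.base_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not (self.tau_decay_s > self.tau_rise_s > 0):
            raise ValueError("need tau_decay_s > tau_rise_s > 0")
        if self.dt_s <= 0 or self.dt_s > 1.0 / self.frame_rate_hz:
            raise ValueError("dt_s must lie in (0, 1/frame_rate_hz]")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")
        n_frames = self.duration_s * self.frame_rate_hz
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration_s · frame_rate_hz must be an integer frame count")
        if not 0.0 < self.div_decay <= 1.5:
            raise ValueError("div_decay must be a positive per-day factor")
        if self.drug_factor < 0 or self.sulpiride_factor < 0:
            raise ValueError("drug factors must be nonnegative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def share_effective(self) -> float:
        """Within-module copy probability after DIV-dependent decay."""
        return float(
            np.clip(
                self.within_module_share * self.div_decay ** (self.div - DIV_REF),
                0.0,
                1.0,
            )
        )

    def replace(self, **kwargs) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SpikeTrains:
    """Latent per-neuron spike times (sorted, seconds) with cell labels."""

    times: list[np.ndarray]
    condition: str
    duration_s: float
    cell_type: np.ndarray  # "DA" / "GABA"
    d2: np.ndarray  # bool
    module: np.ndarray  # int

    @property
    def n_neurons(self) -> int:
        return len(self.times)

    def counts(self, bin_s: float) -> np.ndarray:
        """Neuron×bin spike-count matrix with the given bin width."""
        edges = np.arange(0.0, self.duration_s + bin_s / 2, bin_s)
        return np.stack([np.histogram(t, bins=edges)[0] for t in self.times])


def _cell_labels(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell types, D2 flags and module memberships, deterministic given seed."""
    rng = np.random.default_rng([spec.seed, 101])
    is_da = rng.random(spec.n_neurons) < spec.frac_da
    cell_type = np.where(is_da, "DA", "GABA")
    # DA neurons carry D2 autoreceptors; GABA neurons express D2 with frac_d2.
    d2 = is_da | (rng.random(spec.n_neurons) < spec.frac_d2)
    module = np.arange(spec.n_neurons) % spec.n_modules
    return cell_type, d2, module


def _poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def simulate_spikes(spec: SimSpec, condition: str = "baseline") -> SpikeTrains:
    """Generate correlated spike trains for one condition window.

    Each module's mother process runs at ``base_rate / share`` so that after
    thinning with copy probability ``share`` every member keeps a marginal
    rate of ``base_rate``; the shared copies give a within-module spike-count
    correlation of ``share``.  In the "meth" window the rates of D2+ neurons
    are multiplied by ``drug_factor`` (thinning if < 1, an added independent
    train if > 1); "meth+sulpiride" uses ``sulpiride_factor`` instead.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    cell_type, d2, module = _cell_labels(spec)
    share = spec.share_effective
    if spec.base_rate == 0 and spec.background_rate == 0:
        warnings.warn(
            "degenerate simulation: zero firing rate produces no activity to analyze",
            UserWarning,
            stacklevel=2,
        )
    cond_id = CONDITIONS.index(condition)

    # Condition-specific rate multiplier for D2-expressing neurons.
    if condition == "meth":
        factor = np.where(d2, spec.drug_factor, 1.0)
    elif condition == "meth+sulpiride":
        factor = np.where(d2, spec.sulpiride_factor, 1.0)
    else:
        factor = np.ones(spec.n_neurons)

    # Child streams per module and per neuron keep the draw for neuron i
    # independent of how many neurons precede it.
    mother_rngs = [
        np.random.default_rng([spec.seed, cond_id, 201, m]) for m in range(spec.n_modules)
    ]
    mothers = [
        _poisson_train(r, spec.base_rate / share if share > 0 else 0.0, spec.duration_s)
        for r in mother_rngs
    ]

    times: list[np.ndarray] = []
    for i in range(spec.n_neurons):
        rng = np.random.default_rng([spec.seed, cond_id, 301, i])
        if share > 0:
            mother = mothers[module[i]]
            keep = rng.random(mother.size) < share
            train = mother[keep]
        else:
            train = _poisson_train(rng, spec.base_rate, spec.duration_s)
        bg = _poisson_train(rng, spec.background_rate, spec.duration_s)
        train = np.sort(np.concatenate([train, bg]))
        f = factor[i]
        if f < 1.0:
            train = train[rng.random(train.size) < f]
        elif f > 1.0:
            extra_rate = (f - 1.0) * (spec.base_rate + spec.background_rate)
            extra = _poisson_train(rng, extra_rate, spec.duration_s)
            train = np.sort(np.concatenate([train, extra]))
        times.append(train)

    return SpikeTrains(
        times=times,
        condition=condition,
        duration_s=spec.duration_s,
        cell_type=cell_type,
        d2=d2,
        module=module,
    )


def _gcamp_kernel_peak(tau_rise: float, tau_decay: float) -> float:
    """Peak value of exp(-t/τd) − exp(-t/τr), used to normalize to unit peak."""
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    return float(np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise))


def spikes_to_fluorescence(trains: SpikeTrains, spec: SimSpec) -> TraceSet:
    """Forward GCaMP6f model: F(t) = f0·(1 + amp·(k ∗ s)(t)) + ε(t).

    The kernel k is a difference of exponentials with the configured rise and
    decay constants, normalized to unit peak so that ``amp_per_spike`` is the
    ΔF/F increment of an isolated spike.  Traces are sampled at
    ``frame_rate_hz``; ε is i.i.d. Gaussian with SD ``noise_sd`` in raw
    fluorescence units (the default, 1.0, is 2% of the default f0).
    """
    n_frames = spec.n_frames
    t = np.arange(n_frames) / spec.frame_rate_hz
    peak = _gcamp_kernel_peak(spec.tau_rise_s, spec.tau_decay_s)
    cond_id = CONDITIONS.index(trains.condition)
    rng = np.random.default_rng([spec.seed, cond_id, 401])
    values = np.empty((trains.n_neurons, n_frames))
    for i, spikes in enumerate(trains.times):
        if spikes.size:
            dt = t[None, :] - spikes[:, None]  # (spikes, frames)
            active = dt >= 0
            resp = np.where(
                active,
                np.exp(-np.where(active, dt, 0.0) / spec.tau_decay_s)
                - np.exp(-np.where(active, dt, 0.0) / spec.tau_rise_s),
                0.0,
            ).sum(axis=0) / peak
        else:
            resp = np.zeros(n_frames)
        noise = rng.normal(0.0, spec.noise_sd, size=n_frames) if spec.noise_sd > 0 else 0.0
        values[i] = spec.f0 * (1.0 + spec.amp_per_spike * resp) + noise
    return TraceSet(
        values=values,
        frame_rate_hz=spec.frame_rate_hz,
        condition=trains.condition,
        div=spec.div,
        is_dff=False,
    )


def simulate_traces(spec: SimSpec, condition: str = "baseline") -> TraceSet:
    """Convenience: simulate_spikes then spikes_to_fluorescence."""
    return spikes_to_fluorescence(simulate_spikes(spec, condition), spec)


def _disk_layout(n: int, frame_shape: tuple[int, int], radius: int) -> np.ndarray:
    """Grid layout of ROI centroids guaranteeing non-overlap."""
    h, w = frame_shape
    pitch = int(np.ceil(2.5 * radius)) + 1
    cols = max((w - 2 * radius) // pitch, 1)
    rows = int(np.ceil(n / cols))
    if 2 * radius + rows * pitch > h + pitch:
        raise ValueError(f"frame {frame_shape} too small for {n} ROIs of radius {radius}")
    cents = []
    for i in range(n):
        r, c = divmod(i, cols)
        cents.append((radius + 1 + c * pitch, radius + 1 + r * pitch))
    return np.asarray(cents, dtype=float)


def render_movie(
    traces: TraceSet,
    centroids: np.ndarray | None = None,
    radius: int = 4,
    frame_shape: tuple[int, int] = (128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as an 8-bit movie of Gaussian somas plus an ROI label mask.

    Each neuron is a Gaussian blob (σ = radius/2, truncated at the ROI disk)
    whose brightness scales with its fluorescence; the whole movie shares one
    linear 8-bit quantization so relative dynamics survive.  Returns
    ``(stack, mask)`` with ``stack`` uint8 of shape (frames, H, W) and
    ``mask`` the integer label image (0 background, label i+1 = neuron i).
    Overlapping ROIs make the ground truth ambiguous and are rejected.
    """
    h, w = frame_shape
    n = traces.n_neurons
    if centroids is None:
        centroids = _disk_layout(n, frame_shape, radius)
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape != (n, 2):
        raise ValueError("centroids must be (n_neurons, 2) x,y pairs")
    if np.any(centroids[:, 0] < radius) or np.any(centroids[:, 0] > w - 1 - radius):
        raise ValueError("ROI centroid outside frame (x)")
    if np.any(centroids[:, 1] < radius) or np.any(centroids[:, 1] > h - 1 - radius):
        raise ValueError("ROI centroid outside frame (y)")
    if n > 1:
        d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) <= (2 * radius) ** 2:
            raise ValueError("overlapping ROIs: ground truth would be ambiguous")

    yy, xx = np.mgrid[0:h, 0:w]
    sigma = radius / 2.0
    mask = np.zeros((h, w), dtype=np.uint16)
    footprints = np.zeros((n, h, w))
    for i, (cx, cy) in enumerate(centroids):
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        disk = r2 <= radius**2
        mask[disk] = i + 1
        footprints[i][disk] = np.exp(-r2[disk] / (2 * sigma**2))

    # (frames, H, W) = traces' values projected through the spatial footprints.
    movie = np.tensordot(traces.values.T, footprints, axes=(1, 0))
    vmax = movie.max()
    if vmax <= 0:
        stack = np.zeros(movie.shape, dtype=np.uint8)
    else:
        stack = np.round(255.0 * movie / vmax).astype(np.uint8)
    return stack, mask


def generate_planted_network(
    n: int,
    structure: str,
    seed: int = 0,
    n_blocks: int = 3,
) -> np.ndarray:
    """Weighted symmetric matrix with planted topology, for metric recovery tests.

    ``structure`` is one of:

    - ``"assortative"`` — a dense strongly-weighted core clique plus weakly
      weighted peripheral pairs, no core–periphery edges: every edge joins
      endpoints of similar strength, so strength assortativity is positive.
    - ``"disassortative"`` — a pure hub-and-spoke star with unit weights;
      every edge joins the hub (strength n−1) to a leaf (strength 1), giving
      assortativity exactly −1.
    - ``"modular"`` — ``n_blocks`` dense blocks with uniform(0.5, 1) weights
      and no between-block edges.

    The result has zero diagonal and weights in [0, 1].
    """
    if n < 8:
        raise ValueError("planted networks need n >= 8")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    if structure == "assortative":
        core = n // 2
        iu = np.triu_indices(core, 1)
        w[:core, :core][iu] = rng.uniform(0.7, 1.0, size=iu[0].size)
        # periphery: disjoint weak pairs
        for a in range(core, n - 1, 2):
            w[a, a + 1] = rng.uniform(0.05, 0.15)
    elif structure == "disassortative":
        w[0, 1:] = 1.0
    elif structure == "modular":
        if n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        labels = np.arange(n) % n_blocks
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.5, 1.0, size=iu[0].size)
        sel = same[iu]
        w[iu[0][sel], iu[1][sel]] = vals[sel]
    else:
        raise ValueError(
            f"unknown structure {structure!r}; expected assortative, disassortative or modular"
        )
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return w
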