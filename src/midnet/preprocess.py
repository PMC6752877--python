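"""Fluorescence preprocessing: trace extraction, ΔF/F normalization, integrated activity.

Raw recordings arrive either as neuron×frame CSV tables exported from manual
ROI segmentation, or as multi-page grayscale TIFF stacks plus an integer ROI
label mask.  This module turns them into ΔF/F trace sets and per-neuron
integrated-activity summaries, one condition window at a time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceSet",
    "ActivitySummary",
    "extract_traces",
    "compute_f0",
    "normalize_dff",
    "integrate_activity",
    "below_unity_fraction",
]

#: Positivity floor for baseline fluorescence F0; dividing by anything smaller
#: would blow up ΔF/F numerically.
F0_EPS = 1e-6


@dataclass
class TraceSet:
    """Neuron×frame fluorescence matrix for a single condition window.

    ``values[i, t]`` is neuron *i* at frame *t* — raw fluorescence (arbitrary
    units, strictly positive) when ``is_dff`` is False, ΔF/F otherwise.
    """

    values: np.ndarray
    frame_rate_hz: float
    condition: str = "baseline"
    div: int = 0
    neuron_ids: np.ndarray | None = None
    centroids: np.ndarray | None = None
    is_dff: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D neuron×frame matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.array(
                [f"n{i:04d}" for i in range(self.values.shape[0])]
            )
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape[0] != self.values.shape[0]:
                raise ValueError("neuron_ids length must match number of rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def replace(self, **kwargs) -> "TraceSet":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ActivitySummary:
    """Per-neuron integrated ΔF/F (unit: ΔF/F·s) for one condition window."""

    neuron_ids: np.ndarray
    integral: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.integral = np.asarray(self.integral, dtype=float)
        if self.neuron_ids.shape != self.integral.shape:
            raise ValueError("neuron_ids and integral must align")


def extract_traces(
    stack: np.ndarray,
    masks: np.ndarray,
    frame_rate_hz: float,
    condition: str = "baseline",
    div: int = 0,
) -> TraceSet:
    """Average pixel intensity over each ROI, per frame.

    ``stack`` is a (frames, H, W) grayscale movie; ``masks`` is an (H, W)
    integer label image where 0 is background and labels 1..L mark neuronal
    somas.  Neurons are returned in ascending label order.  A label in
    1..max(masks) with zero pixels is a hard error — it signals a mismatched
    mask.
    """
    stack = np.asarray(stack)
    masks = np.asarray(masks)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    if masks.shape != stack.shape[1:]:
        raise ValueError(
            f"mask shape {masks.shape} does not match frame shape {stack.shape[1:]}"
        )
    if masks.min() < 0:
        raise ValueError("mask labels must be nonnegative integers")
    n_labels = int(masks.max())
    if n_labels == 0:
        raise ValueError("mask contains no ROIs")
    frames = stack.reshape(stack.shape[0], -1).astype(float)
    flat = masks.ravel()
    traces = np.empty((n_labels, stack.shape[0]))
    centroids = np.empty((n_labels, 2))
    yy, xx = np.mgrid[0 : masks.shape[0], 0 : masks.shape[1]]
    for lab in range(1, n_labels + 1):
        sel = flat == lab
        if not sel.any():
            raise ValueError(f"ROI label {lab} has zero pixels")
        traces[lab - 1] = frames[:, sel].mean(axis=1)
        centroids[lab - 1] = (xx.ravel()[sel].mean(), yy.ravel()[sel].mean())
    return TraceSet(
        values=traces,
        frame_rate_hz=frame_rate_hz,
        condition=condition,
        div=div,
        centroids=centroids,
        is_dff=False,
    )


def compute_f0(
    raw: TraceSet,
    f0_window: tuple[int, int],
    method: str = "mean",
    percentile: float = 10.0,
) -> np.ndarray:
    """Per-neuron baseline fluorescence F0 over a half-open frame window.

    ``method="mean"`` (default) gives the exact invariant that the ΔF/F mean
    over the baseline window is zero; ``method="percentile"`` is the common
    robust alternative for drifting baselines.
    """
    start, end = f0_window
    if not (0 <= start < end <= raw.n_frames):
        raise ValueError(f"f0_window {f0_window} outside trace length {raw.n_frames}")
    win = raw.values[:, start:end]
    if method == "mean":
        f0 = win.mean(axis=1)
    elif method == "percentile":
        f0 = np.percentile(win, percentile, axis=1)
    else:
        raise ValueError(f"unknown F0 method {method!r}")
    bad = np.flatnonzero(f0 <= F0_EPS)
    if bad.size:
        ids = ", ".join(str(raw.neuron_ids[i]) for i in bad[:10])
        raise ValueError(
            f"baseline fluorescence F0 <= {F0_EPS} for neuron(s) {ids}; "
            "ΔF/F would be undefined"
        )
    return f0


def normalize_dff(
    raw: TraceSet,
    f0_window: tuple[int, int] | None = None,
    f0: np.ndarray | None = None,
    method: str = "mean",
    percentile: float = 10.0,
) -> TraceSet:
    """Normalize raw fluorescence to ΔF/F = (F − F0)/F0.

    Exactly one of ``f0_window`` (computed from this trace set) or a
    precomputed ``f0`` vector must be given.  Passing the baseline window's F0
    when normalizing the treatment window references both conditions to the
    same baseline, so drug suppression shows up as reduced ΔF/F.
    """
    if raw.is_dff:
        raise ValueError("trace set is already ΔF/F")
    if (f0_window is None) == (f0 is None):
        raise ValueError("provide exactly one of f0_window or f0")
    if f0 is None:
        f0 = compute_f0(raw, f0_window, method=method, percentile=percentile)
    else:
        f0 = np.asarray(f0, dtype=float)
        if f0.shape != (raw.n_neurons,):
            raise ValueError("f0 must have one value per neuron")
        if np.any(f0 <= F0_EPS):
            raise ValueError(f"f0 must exceed the positivity floor {F0_EPS}")
    dff = (raw.values - f0[:, None]) / f0[:, None]
    return raw.replace(values=dff, is_dff=True)


def integrate_activity(
    dff: TraceSet,
    window: tuple[int, int] | None = None,
    rectify: bool = False,
) -> ActivitySummary:
    """Trapezoidal integral of ΔF/F over a frame window, in ΔF/F·seconds.

    The integral is signed — negative excursions subtract — unless
    ``rectify`` is set, which integrates ``|ΔF/F|`` instead.  The window is
    half-open ``[start, end)`` in frames and must span at least 2 frames.
    """
    if window is None:
        window = (0, dff.n_frames)
    start, end = window
    if not (0 <= start < end <= dff.n_frames):
        raise ValueError(f"window {window} outside trace length {dff.n_frames}")
    if end - start < 2:
        raise ValueError("integration window must span at least 2 frames")
    seg = dff.values[:, start:end]
    if rectify:
        seg = np.abs(seg)
    integral = np.trapezoid(seg, dx=1.0 / dff.frame_rate_hz, axis=1)
    return ActivitySummary(
        neuron_ids=dff.neuron_ids, integral=integral, condition=dff.condition
    )


def below_unity_fraction(
    base: ActivitySummary, treat: ActivitySummary
) -> tuple[float, np.ndarray]:
    """Fraction of neurons whose treatment integral falls below baseline.

    This is the scatter-below-the-unity-line summary: a value above 0.5 means
    the treatment suppressed most neurons.  Ties count as not-below.  Returns
    the fraction and the per-neuron boolean flags (ordered as ``base``).
    """
    if base.neuron_ids.shape != treat.neuron_ids.shape or np.any(
        base.neuron_ids != treat.neuron_ids
    ):
        raise ValueError("activity summaries are not paired by neuron_id")
    flags = treat.integral < base.integral
    return float(flags.mean()), flags
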