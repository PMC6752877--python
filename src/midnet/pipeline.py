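"""Pipeline orchestration, configuration, and CSV/TIFF plumbing.

The pipeline runs in file-based stages — simulate → preprocess → connect →
topology → compare — each reading the previous stage's outputs from the
output directory, so running the stages individually (CLI subcommands) is
byte-identical to running them all at once.

Configuration is a YAML file; two input modes are supported:

- simulation mode: a ``sim`` block (SimSpec fields) plus ``divs`` generates
  paired baseline/treatment recordings for each culture age;
- file mode: a ``recordings`` list pointing at existing trace CSVs
  (one baseline and one treatment file per recording, plus div).

Trace CSV dialect: first column ``neuron_id``, then one column per frame
named ``f0000, f0001, …``; floats at 17 significant digits so round-trips
are exact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import (
    PairDeviationSet,
    deviation_stats,
    div_regression,
    mean_connectivity,
    unity_deviation,
)
from .connectivity import (
    ConnectivityMatrix,
    absolute_threshold,
    density_sweep,
    functional_connectivity,
    proportional_threshold,
)
from .preprocess import (
    TraceSet,
    below_unity_fraction,
    compute_f0,
    integrate_activity,
    normalize_dff,
)
from .simulate import SimSpec, render_movie, simulate_spikes, spikes_to_fluorescence
from .topology import topology_report

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_simulate",
    "stage_preprocess",
    "stage_connect",
    "stage_topology",
    "stage_compare",
    "read_traces_csv",
    "write_traces_csv",
    "read_adjacency_csv",
    "write_adjacency_csv",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# CSV plumbing


def write_traces_csv(path: str | Path, traces: TraceSet) -> None:
    df = pd.DataFrame(
        traces.values,
        index=pd.Index(traces.neuron_ids, name="neuron_id"),
        columns=[f"f{i:04d}" for i in range(traces.n_frames)],
    )
    df.to_csv(path, float_format=FLOAT_FMT)


def read_traces_csv(
    path: str | Path,
    frame_rate_hz: float,
    condition: str = "baseline",
    div: int = 0,
    is_dff: bool = False,
) -> TraceSet:
    df = pd.read_csv(path, index_col="neuron_id", float_precision="round_trip")
    return TraceSet(
        values=df.to_numpy(dtype=float),
        frame_rate_hz=frame_rate_hz,
        condition=condition,
        div=div,
        neuron_ids=df.index.to_numpy(dtype=str),
        is_dff=is_dff,
    )


def write_adjacency_csv(path: str | Path, c: ConnectivityMatrix) -> None:
    df = pd.DataFrame(
        c.rho,
        index=pd.Index(c.neuron_ids, name="neuron_id"),
        columns=c.neuron_ids,
    )
    df.to_csv(path, float_format=FLOAT_FMT)


def read_adjacency_csv(
    path: str | Path, condition: str = "baseline", div: int = 0
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col="neuron_id", float_precision="round_trip")
    return ConnectivityMatrix(
        rho=df.to_numpy(dtype=float),
        condition=condition,
        div=div,
        neuron_ids=df.index.to_numpy(dtype=str),
    )


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for the YAML)."""

    outdir: Path
    sim: SimSpec | None = None
    divs: list[int] = field(default_factory=lambda: [11])
    treatment: str = "meth"
    recordings: list[dict] = field(default_factory=list)
    frame_rate_hz: float = 10.0
    f0_window: tuple[int, int] | None = None
    f0_method: str = "mean"
    rectify_integrals: bool = False
    threshold_mode: str = "proportional"
    threshold_p: float = 0.15
    threshold_rank_by: str = "signed"
    gamma: float = 1.0
    restarts: int = 10
    topology_seed: int = 0
    assortativity_variant: str = "strength"
    deviation_scale: str = "perpendicular"
    render_movies: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None and not self.recordings:
            raise ValueError("config needs either a 'sim' block or 'recordings'")
        if self.sim is not None and self.recordings:
            raise ValueError("config cannot mix simulation and file inputs")
        if self.treatment not in ("meth", "meth+sulpiride"):
            raise ValueError("treatment must be 'meth' or 'meth+sulpiride'")
        if self.threshold_mode not in ("proportional", "sweep"):
            raise ValueError("threshold_mode must be 'proportional' or 'sweep'")
        if not 0.0 < self.threshold_p <= 1.0:
            raise ValueError("threshold p must lie in (0, 1]")
        if not self.divs:
            raise ValueError("divs must be non-empty")
        for rec in self.recordings:
            for key in ("baseline", "treatment", "div"):
                if key not in rec:
                    raise ValueError(f"recording entry missing {key!r}: {rec}")
            for key in ("baseline", "treatment"):
                if not Path(rec[key]).exists():
                    raise ValueError(f"input file not found: {rec[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("sim", None)
        if sim is not None:
            sim = SimSpec(**sim)
        f0_window = raw.pop("f0_window", None)
        if f0_window is not None:
            f0_window = (int(f0_window[0]), int(f0_window[1]))
        thr = raw.pop("threshold", None) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            sim=sim,
            f0_window=f0_window,
            threshold_mode=thr.get("mode", "proportional"),
            threshold_p=thr.get("p", 0.15),
            threshold_rank_by=thr.get("rank_by", "signed"),
            **raw,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        if self.f0_window is not None:
            d["f0_window"] = list(self.f0_window)
        return d

    @property
    def conditions(self) -> tuple[str, str]:
        return ("baseline", self.treatment)

    def frame_rate(self) -> float:
        return self.sim.frame_rate_hz if self.sim is not None else self.frame_rate_hz

    def div_list(self) -> list[int]:
        if self.sim is not None:
            return list(self.divs)
        return sorted({int(rec["div"]) for rec in self.recordings})


def _sim_for_div(cfg: PipelineConfig, div: int) -> SimSpec:
    # deterministic per-DIV child seed, kept below 2**31
    child = (cfg.sim.seed * 100003 + 7919 * div) % (2**31)
    return cfg.sim.replace(div=div, seed=child)


# ---------------------------------------------------------------------------
# Stages


def _stage(name: str):
    def deco(fn):
        def wrapped(cfg: PipelineConfig, *args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(cfg, *args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate raw traces (and labels, optionally movies) per DIV and condition."""
    if cfg.sim is None:
        return  # file mode: nothing to simulate
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    for div in cfg.divs:
        spec = _sim_for_div(cfg, div)
        labels = None
        for cond in cfg.conditions:
            trains = simulate_spikes(spec, cond)
            traces = spikes_to_fluorescence(trains, spec)
            write_traces_csv(out / f"traces_raw_{_slug(cond)}_div{div:02d}.csv", traces)
            if labels is None:
                labels = pd.DataFrame(
                    {
                        "neuron_id": traces.neuron_ids,
                        "cell_type": trains.cell_type,
                        "d2_flag": trains.d2.astype(int),
                        "module": trains.module,
                    }
                )
                labels.to_csv(out / f"labels_div{div:02d}.csv", index=False)
            if cfg.render_movies:
                import tifffile

                stack, mask = render_movie(traces)
                tifffile.imwrite(
                    out / f"movie_{_slug(cond)}_div{div:02d}.tiff", stack
                )
                tifffile.imwrite(out / f"masks_div{div:02d}.tiff", mask)


def _slug(condition: str) -> str:
    return condition.replace("+", "_")


def _raw_trace_path(cfg: PipelineConfig, cond: str, div: int) -> Path:
    if cfg.sim is not None:
        return cfg.outdir / f"traces_raw_{_slug(cond)}_div{div:02d}.csv"
    for rec in cfg.recordings:
        if int(rec["div"]) == div:
            key = "baseline" if cond == "baseline" else "treatment"
            return Path(rec[key])
    raise FileNotFoundError(f"no recording for div {div}")


@_stage("preprocess")
def stage_preprocess(cfg: PipelineConfig) -> None:
    """ΔF/F-normalize both condition windows against the baseline F0; integrate."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    activity_rows = []
    for div in cfg.div_list():
        base_raw = read_traces_csv(
            _raw_trace_path(cfg, "baseline", div), cfg.frame_rate(), "baseline", div
        )
        treat_raw = read_traces_csv(
            _raw_trace_path(cfg, cfg.treatment, div), cfg.frame_rate(), cfg.treatment, div
        )
        window = cfg.f0_window or (0, base_raw.n_frames)
        f0 = compute_f0(base_raw, window, method=cfg.f0_method)
        for raw in (base_raw, treat_raw):
            dff = normalize_dff(raw, f0=f0)
            write_traces_csv(out / f"dff_{_slug(raw.condition)}_div{div:02d}.csv", dff)
            summary = integrate_activity(dff, rectify=cfg.rectify_integrals)
            for nid, integral in zip(summary.neuron_ids, summary.integral):
                activity_rows.append(
                    {
                        "div": div,
                        "neuron_id": nid,
                        "condition": raw.condition,
                        "integral": integral,
                    }
                )
    pd.DataFrame(activity_rows).to_csv(
        out / "activity.csv", index=False, float_format=FLOAT_FMT
    )


@_stage("connect")
def stage_connect(cfg: PipelineConfig) -> None:
    """Spearman connectivity per DIV and condition, plus the density sweep."""
    out = cfg.outdir
    for div in cfg.div_list():
        for cond in cfg.conditions:
            dff = read_traces_csv(
                out / f"dff_{_slug(cond)}_div{div:02d}.csv",
                cfg.frame_rate(),
                cond,
                div,
                is_dff=True,
            )
            c = functional_connectivity(dff)
            write_adjacency_csv(out / f"adjacency_{_slug(cond)}_div{div:02d}.csv", c)
            sweep = density_sweep(c)
            sweep.to_csv(
                out / f"density_sweep_{_slug(cond)}_div{div:02d}.csv",
                index=False,
                float_format=FLOAT_FMT,
            )


def _threshold(cfg: PipelineConfig, c: ConnectivityMatrix):
    if cfg.threshold_mode == "proportional":
        return proportional_threshold(c, cfg.threshold_p, rank_by=cfg.threshold_rank_by)
    # sweep mode still needs one network for topology; use the default p
    return proportional_threshold(c, cfg.threshold_p, rank_by=cfg.threshold_rank_by)


@_stage("topology")
def stage_topology(cfg: PipelineConfig) -> None:
    """Threshold each adjacency matrix and compute the four topology metrics."""
    out = cfg.outdir
    rows = []
    for div in cfg.div_list():
        for cond in cfg.conditions:
            c = read_adjacency_csv(
                out / f"adjacency_{_slug(cond)}_div{div:02d}.csv", cond, div
            )
            net = _threshold(cfg, c)
            net.edge_list().to_csv(
                out / f"edges_{_slug(cond)}_div{div:02d}.csv",
                index=False,
                float_format=FLOAT_FMT,
            )
            rep = topology_report(
                net,
                gamma=cfg.gamma,
                restarts=cfg.restarts,
                seed=cfg.topology_seed,
                assortativity_variant=cfg.assortativity_variant,
            )
            if rep.partition is not None:
                pd.DataFrame(
                    {"neuron_id": c.neuron_ids, "community": rep.partition}
                ).to_csv(out / f"partition_{_slug(cond)}_div{div:02d}.csv", index=False)
            rows.append(
                {
                    "div": div,
                    "condition": cond,
                    "p": cfg.threshold_p,
                    "density": rep.density,
                    "clustering_mean": rep.clustering_mean,
                    "modularity_q": rep.modularity_q,
                    "n_communities": rep.n_communities,
                    "assortativity_r": rep.assortativity_r,
                    "flags": ";".join(rep.flags),
                }
            )
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False, float_format=FLOAT_FMT)


@_stage("compare")
def stage_compare(cfg: PipelineConfig) -> None:
    """Unity deviations (pooled), their summary stats, and across-DIV trends."""
    out = cfg.outdir
    divs = cfg.div_list()
    dev_sets = []
    mean_rho = {cond: [] for cond in cfg.conditions}
    for div in divs:
        base = read_adjacency_csv(
            out / f"adjacency_baseline_div{div:02d}.csv", "baseline", div
        )
        treat = read_adjacency_csv(
            out / f"adjacency_{_slug(cfg.treatment)}_div{div:02d}.csv",
            cfg.treatment,
            div,
        )
        dev_sets.append(unity_deviation(base, treat, scale=cfg.deviation_scale))
        mean_rho["baseline"].append(mean_connectivity(base))
        mean_rho[cfg.treatment].append(mean_connectivity(treat))
    pooled = PairDeviationSet.pool(dev_sets)
    dev_df = pd.DataFrame(
        {
            "div": np.concatenate(
                [np.full(s.n_pairs, d) for s, d in zip(dev_sets, divs)]
            ),
            "pair_i": pooled.pair_i,
            "pair_j": pooled.pair_j,
            "rho_base": pooled.rho_base,
            "rho_treat": pooled.rho_treat,
            "d": pooled.d,
        }
    )
    dev_df.to_csv(out / "deviations.csv", index=False, float_format=FLOAT_FMT)
    dstats = deviation_stats(pooled)
    with open(out / "deviation_summary.json", "w") as fh:
        json.dump(
            {
                "n": dstats.n,
                "mean": dstats.mean,
                "skewness_g1": dstats.g1,
                "excess_kurtosis_g2": dstats.g2,
                "ks_p": dstats.ks_p,
                "wilcoxon_p": dstats.wilcoxon_p,
                "scale": cfg.deviation_scale,
                "flags": dstats.flags,
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    # activity below-unity summary per DIV
    act = pd.read_csv(out / "activity.csv")
    unity_rows = []
    for div in divs:
        sub = act[act["div"] == div]
        base_i = sub[sub["condition"] == "baseline"].set_index("neuron_id")["integral"]
        treat_i = sub[sub["condition"] == cfg.treatment].set_index("neuron_id")["integral"]
        frac = float((treat_i.loc[base_i.index] < base_i).mean())
        unity_rows.append({"div": div, "below_unity_fraction": frac})
    pd.DataFrame(unity_rows).to_csv(
        out / "below_unity.csv", index=False, float_format=FLOAT_FMT
    )

    # across-DIV trends (mean connectivity + topology metrics) per condition
    trend_rows = []
    if len(set(divs)) >= 3:
        metrics = pd.read_csv(out / "metrics.csv")
        for cond in cfg.conditions:
            tr = div_regression(
                np.array(divs, dtype=float),
                np.array(mean_rho[cond]),
                metric="mean_connectivity",
                condition=cond,
            )
            trend_rows.append(tr)
            sub = metrics[metrics["condition"] == cond].sort_values("div")
            for col in ("density", "clustering_mean", "modularity_q", "assortativity_r"):
                vals = sub[col].to_numpy(dtype=float)
                ok = np.isfinite(vals)
                if np.unique(sub["div"].to_numpy()[ok]).size >= 3:
                    trend_rows.append(
                        div_regression(
                            sub["div"].to_numpy(dtype=float)[ok],
                            vals[ok],
                            metric=col,
                            condition=cond,
                        )
                    )
    pd.DataFrame(
        [
            {
                "metric": t.metric,
                "condition": t.condition,
                "slope": t.slope,
                "intercept": t.intercept,
                "r2": t.r_squared,
                "p": t.p_value,
                "n_points": t.n_points,
            }
            for t in trend_rows
        ],
        columns=["metric", "condition", "slope", "intercept", "r2", "p", "n_points"],
    ).to_csv(out / "trends.csv", index=False, float_format=FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and write a run manifest; returns file index."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg)
    stage_preprocess(cfg)
    stage_connect(cfg)
    stage_topology(cfg)
    stage_compare(cfg)
    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "midnet_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": {
            "sim": cfg.sim.seed if cfg.sim is not None else None,
            "topology": cfg.topology_seed,
        },
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files = sorted(str(p.name) for p in cfg.outdir.iterdir() if p.is_file())
    return {"outdir": str(cfg.outdir), "files": files}
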