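"""Simulation campaigns over R x S input grids and circuit variants.

The modelling results rest on systematic sweeps: respiratory (R) and
sensory (S) peak input rates varied over an inclusive grid, crossed with
circuit variants, input modes, GC inhibition levels, column counts and
respiration rates.  This module enumerates such campaigns
deterministically, runs them (optionally in parallel) with per-run seeds
derived from a base seed so results are independent of execution order,
and summarises the stimulated-vs-control polar metrics per run.

Shipped campaign specifications under ``respigate/campaigns/`` reproduce
the published sweep sizes (38x38 = 1444 R,S combinations and their
variant products) without running anything; desk-scale presets are
provided for actually running on one machine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from .bulb_network import InputSpec, NetworkConfig, build_network, polar_analysis, simulate

__all__ = [
    "GridSpec",
    "RunPoint",
    "enumerate_grid",
    "run_campaign",
    "summarize",
    "load_grid_spec",
    "paper_campaign",
    "list_campaigns",
]


def _expand(values):
    """A list as-is, or an inclusive {start, stop, step} range."""
    if isinstance(values, dict):
        start, stop, step = values["start"], values["stop"], values["step"]
        n = int(round((stop - start) / step))
        out = [start + i * step for i in range(n + 1)]
        if out[-1] > stop + 1e-9:
            out.pop()
        return out
    return list(values)


@dataclass
class GridSpec:
    """A campaign: the Cartesian product of every axis below.

    Axes follow the sweep design: R and S in Hz (inclusive endpoints),
    circuit variants, input modes, GC multipliers, connected-column
    counts, respiration rates, and lateral inhibitory weights.
    ``seeds`` replicates each parameter point; run-count bookkeeping
    (``n_points``) refers to unique parameter points, matching how sweep
    sizes are quoted.
    """

    R_values: list
    S_values: list
    variants: list = field(default_factory=lambda: ["PG"])
    modes: list = field(default_factory=lambda: ["primary"])
    gc_levels: list = field(default_factory=lambda: [4.0])
    n_columns_list: list = field(default_factory=lambda: [1])
    resp_rates: list = field(default_factory=lambda: [2.5])
    inhib_weights: list = field(default_factory=lambda: [1.0])
    cycles_per_run: int = 40
    seeds: list = field(default_factory=lambda: [0, 1, 2])

    def __post_init__(self):
        self.R_values = _expand(self.R_values)
        self.S_values = _expand(self.S_values)
        for name in ("variants", "modes", "gc_levels", "n_columns_list",
                     "resp_rates", "inhib_weights", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if not self.R_values or not self.S_values:
            raise ValueError("R_values and S_values must be non-empty")

    @property
    def n_points(self) -> int:
        return (len(self.R_values) * len(self.S_values) * len(self.variants)
                * len(self.modes) * len(self.gc_levels)
                * len(self.n_columns_list) * len(self.resp_rates)
                * len(self.inhib_weights))

    @property
    def n_runs(self) -> int:
        return self.n_points * len(self.seeds)


@dataclass
class RunPoint:
    """One parameter point of a campaign (deterministic enumeration order)."""

    index: int
    R: float
    S: float
    variant: str
    mode: str
    gc_level: float
    n_columns: int
    resp_rate: float
    inhib_weight: float

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(variant=self.variant, mode=self.mode,
                             n_columns=self.n_columns,
                             gc_multiplier=self.gc_level,
                             secondary_inhib_weight=self.inhib_weight)

    def input_spec(self) -> InputSpec:
        return InputSpec(R=self.R, S=self.S, resp_rate=self.resp_rate)


def enumerate_grid(spec: GridSpec):
    """All parameter points in deterministic (row-major) order."""
    points = [
        RunPoint(i, R, S, variant, mode, gc, ncol, rr, iw)
        for i, (variant, mode, gc, ncol, rr, iw, R, S) in enumerate(
            itertools.product(spec.variants, spec.modes, spec.gc_levels,
                              spec.n_columns_list, spec.resp_rates,
                              spec.inhib_weights, spec.R_values, spec.S_values))
    ]
    if not points:
        raise ValueError("empty grid")
    assert len(points) == spec.n_points
    return points


def _run_seed(base_seed: int, point_index: int, seed_index: int) -> int:
    """Deterministic per-run seed, independent of execution order."""
    ss = np.random.SeedSequence((int(base_seed), int(point_index), int(seed_index)))
    return int(ss.generate_state(1)[0] % 2**31)


def _run_one(point: RunPoint, seed_index: int, base_seed: int,
             cycles: int, n_bins: int) -> dict:
    row = {"point_index": point.index, "seed_index": seed_index,
           "R": point.R, "S": point.S, "variant": point.variant,
           "mode": point.mode, "gc_level": point.gc_level,
           "n_columns": point.n_columns, "resp_rate": point.resp_rate,
           "inhib_weight": point.inhib_weight, "error": ""}
    try:
        net = build_network(point.network_config())
        pair = simulate(net, point.input_spec(), n_cycles=cycles,
                        seed=_run_seed(base_seed, point.index, seed_index))
        res = polar_analysis(pair, n_bins=n_bins)
        cs, cc = res["stim"], res["ctrl"]
        row.update({
            "delta_centroid": res["delta_centroid"],
            "ctrl_rayleigh_p": res["ctrl_rayleigh_p"],
            "coupled": bool(res["coupled"]),
            "stim_centroid_angle": cs.angle, "ctrl_centroid_angle": cc.angle,
            "stim_centroid_magnitude": cs.magnitude,
            "ctrl_centroid_magnitude": cc.magnitude,
            "stim_max_rate": cs.peak_rate, "ctrl_max_rate": cc.peak_rate,
            "delta_max_rate": cs.peak_rate - cc.peak_rate,
            "stim_mean_rate": cs.mean_rate, "ctrl_mean_rate": cc.mean_rate,
            "stim_polar_area": cs.polar_area, "ctrl_polar_area": cc.polar_area,
        })
    except Exception as exc:   # failed run recorded; campaign continues
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


METRIC_COLUMNS = [
    "delta_centroid", "ctrl_rayleigh_p", "stim_centroid_angle", "ctrl_centroid_angle",
    "stim_centroid_magnitude", "ctrl_centroid_magnitude",
    "stim_max_rate", "ctrl_max_rate", "delta_max_rate",
    "stim_mean_rate", "ctrl_mean_rate", "stim_polar_area", "ctrl_polar_area",
]


def run_campaign(spec: GridSpec, base_seed: int = 0, workers: int = 1,
                 n_bins: int = 12, partial: pd.DataFrame = None) -> pd.DataFrame:
    """Execute every (point, seed) run exactly once; one result row per run.

    Per-run seeds derive deterministically from ``(base_seed,
    point_index, seed_index)``, so the result is identical for any
    worker count or execution order.  Passing a ``partial`` result
    resumes: runs already present (and error-free) are kept, the rest
    executed.
    """
    points = enumerate_grid(spec)
    todo = [(p, si) for p in points for si in range(len(spec.seeds))]
    kept = None
    if partial is not None and len(partial):
        ok = partial[partial["error"] == ""]
        done = set(zip(ok["point_index"], ok["seed_index"]))
        kept = ok
        todo = [(p, si) for p, si in todo if (p.index, si) not in done]
    rows = Parallel(n_jobs=workers)(
        delayed(_run_one)(p, si, base_seed, spec.cycles_per_run, n_bins)
        for p, si in todo)
    df = pd.DataFrame(rows)
    if kept is not None:
        df = pd.concat([kept, df], ignore_index=True)
    df = df.sort_values(["point_index", "seed_index"]).reset_index(drop=True)
    return df


def summarize(result: pd.DataFrame, reference_shift: float = 0.75) -> dict:
    """Per-variant tables of centroid shift and peak rate vs (R, S).

    Seeds are averaged per parameter point; the flagged region marks
    points where the mean |delta centroid| reaches ``reference_shift``
    radians (0.75 rad, the magnitude of the mean in vivo shift).
    """
    ok = result[result["error"] == ""]
    if not len(ok):
        raise ValueError("no successful runs to summarize")
    keys = ["variant", "mode", "gc_level", "n_columns", "resp_rate",
            "inhib_weight", "R", "S"]
    agg = ok.groupby(keys, as_index=False)[METRIC_COLUMNS].mean()
    agg["flagged"] = agg["delta_centroid"].abs() >= reference_shift
    tables = {}
    for variant, sub in agg.groupby("variant"):
        tables[variant] = {
            "delta_centroid": sub.pivot_table(index="R", columns="S",
                                              values="delta_centroid"),
            "max_rate": sub.pivot_table(index="R", columns="S",
                                        values="stim_max_rate"),
        }
    return {"per_point": agg, "tables": tables,
            "flagged_region": agg[agg["flagged"]][keys],
            "n_failed": int((result["error"] != "").sum())}


def load_grid_spec(path) -> GridSpec:
    """Read a campaign specification from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GridSpec(**raw)


def list_campaigns():
    """Names of the campaign specs shipped with the package."""
    base = resources.files("respigate") / "campaigns"
    return sorted(p.name[:-5] for p in base.iterdir() if p.name.endswith(".yaml"))


def paper_campaign(name: str) -> GridSpec:
    """Load a shipped campaign spec by name (see :func:`list_campaigns`)."""
    base = resources.files("respigate") / "campaigns"
    path = base / f"{name}.yaml"
    raw = yaml.safe_load(path.read_text())
    return GridSpec(**raw)
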