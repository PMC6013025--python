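"""Pre-configured experiment suites and replicate handling.

Each suite reproduces one figure-style design: a factorial of medium,
antibiotic level, resistance cost, detoxification level, seeding
arrangement, inoculum size/ratio, or antibiotic timing, run over
replicate seeds and summarised as tidy tables.

Two scales are provided.  ``full`` is the reference design (258 um
domain, 120 cells per lineage, 36 h, 3 replicates).  ``reduced`` keeps
the same factorial structure on a 130 um domain with 40 cells per
lineage over 24 h and 2 replicates, which preserves the sign structure
of the outcomes while running on a laptop in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationConfig, SimulationResult, run_simulation
from .metrics import antibiotic_response, ecological_outcome
from .model import ConfigurationError
from .solver import DomainGeometry

__all__ = [
    "ExperimentConfig", "SCALES", "scaled_config", "replicate_seeds",
    "run_replicates", "suite_fig1", "suite_fig2_cost", "suite_fig3_detox",
    "suite_fig4_spatial", "suite_s3_inoculum", "suite_s4_initial",
    "suite_s8_timing", "SUITES", "run_suite",
]

#: default antibiotic levels: none, low toxicity, high toxicity (g/L)
ANTIBIOTIC_LEVELS = (0.0, 0.05, 0.2)

MEDIA = ("interference_competition", "exploitation_competition",
         "non_crossfeeding", "crossfeeding")

SCALES: dict[str, dict] = {
    "full": dict(
        geometry=DomainGeometry(width=258.0, height=258.0, grid_spacing=2.0,
                                boundary_layer=40.0),
        n_per_species=120, duration_h=36.0, dt_h=0.02, replicates=3),
    "reduced": dict(
        geometry=DomainGeometry(width=130.0, height=160.0, grid_spacing=2.0,
                                boundary_layer=40.0),
        n_per_species=40, duration_h=24.0, dt_h=0.05, replicates=2),
    # smoke-test scale: exercises every code path in seconds; outcomes at
    # this scale are qualitative only
    "tiny": dict(
        geometry=DomainGeometry(width=40.0, height=100.0, grid_spacing=2.0,
                                boundary_layer=10.0),
        n_per_species=8, duration_h=6.0, dt_h=0.1, replicates=1),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """A simulation design plus its replication protocol."""

    base: SimulationConfig
    replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic, distinct per-replicate seeds below 2**31."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def scaled_config(scale: str = "reduced", **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` at a named scale with field overrides.

    The fractional reading of the resistance cost ("0.1 = 10% cost") and
    the absolute one (1/h) coincide at the default mu_max = 1/h.
    """
    if scale not in SCALES:
        raise ConfigurationError(f"unknown scale {scale!r}")
    preset = SCALES[scale]
    cfg = SimulationConfig(
        geometry=preset["geometry"],
        n_R=preset["n_per_species"], n_S=preset["n_per_species"],
        duration_h=preset["duration_h"], dt_h=preset["dt_h"])
    return replace(cfg, **overrides)


def run_replicates(config: ExperimentConfig
                   ) -> tuple[list[SimulationResult], pd.DataFrame]:
    """Run the design over its replicate seeds; returns runs + mean series.

    The mean series averages every numeric metric column over replicates
    at matching timepoints.
    """
    seeds = replicate_seeds(config.base_seed, config.replicates)
    results = []
    frames = []
    for rep, seed in enumerate(seeds):
        res = run_simulation(replace(config.base, seed=seed))
        results.append(res)
        df = res.metrics.copy()
        df.insert(0, "replicate", rep)
        frames.append(df)
    stacked = pd.concat(frames, ignore_index=True)
    mean = (stacked.drop(columns="replicate")
            .groupby("time_h", as_index=False).mean())
    return results, mean


# ---------------------------------------------------------------------------
# suite machinery

def _final_time(cfg: SimulationConfig) -> float:
    return cfg.dt_h * round(cfg.duration_h / cfg.dt_h)


def _mean_final_counts(mean: pd.DataFrame) -> tuple[float, float]:
    last = mean.iloc[-1]
    return float(last["count_R"]), float(last["count_S"])


class _RunCache:
    """Runs each distinct condition once per suite."""

    def __init__(self, base: SimulationConfig, replicates: int,
                 base_seed: int):
        self.base = base
        self.replicates = replicates
        self.base_seed = base_seed
        self._cache: dict[tuple, tuple] = {}

    def mean(self, **overrides) -> pd.DataFrame:
        key = tuple(sorted(overrides.items()))
        if key not in self._cache:
            cfg = ExperimentConfig(base=replace(self.base, **overrides),
                                   replicates=self.replicates,
                                   base_seed=self.base_seed)
            self._cache[key] = run_replicates(cfg)
        return self._cache[key][1]

    def series(self, **overrides) -> "_Series":
        return _Series(replace(self.base, **overrides),
                       self.mean(**overrides))


@dataclass
class _Series:
    """Mean replicate series tagged with its configuration."""

    config: SimulationConfig
    metrics: pd.DataFrame


def suite_fig1(scale: str = "reduced",
               antibiotic_levels: Sequence[float] = ANTIBIOTIC_LEVELS,
               media: Sequence[str] = MEDIA,
               seed: int = 0, replicates: int | None = None,
               outdir: str | Path | None = None) -> pd.DataFrame:
    """Headline factorial: 4 media x antibiotic levels x {co, monoR, monoS}.

    For every medium and antibiotic level the table reports final counts,
    the coculture-minus-monoculture differences, and the antibiotic
    response statistics with their labels.
    """
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    base = scaled_config(scale)
    n = base.n_R
    rows = []
    for medium in media:
        cache = _RunCache(replace(base, medium=medium), reps, seed)
        t = _final_time(base)
        zero_co = cache.series(antibiotic_bulk=0.0)
        for A in antibiotic_levels:
            co = cache.series(antibiotic_bulk=A)
            monoR = cache.series(antibiotic_bulk=A, n_S=0)
            monoS = cache.series(antibiotic_bulk=A, n_R=0)
            eco = ecological_outcome(co, monoR, monoS, t)
            resp = antibiotic_response(co, zero_co, monoS, t)
            R_co, S_co = _mean_final_counts(co.metrics)
            R_mono, _ = _mean_final_counts(monoR.metrics)
            _, S_mono = _mean_final_counts(monoS.metrics)
            rows.append({
                "medium": medium, "antibiotic": A, "time_h": t,
                "R_co": R_co, "S_co": S_co,
                "R_mono": R_mono, "S_mono": S_mono,
                "delta_R": eco.delta_R_coculture_effect,
                "delta_S": eco.delta_S_coculture_effect,
                "interaction": eco.classification,
                "release_statistic": resp.release_statistic,
                "cross_protection_statistic":
                    resp.cross_protection_statistic,
                "response": resp.classification,
            })
    table = pd.DataFrame(rows)
    if outdir is not None:
        _persist(outdir, "fig1", {"scale": scale, "seed": seed,
                                  "replicates": reps,
                                  "antibiotic_levels": list(antibiotic_levels),
                                  "media": list(media)}, table)
    return table


def _factorial_suite(name: str, base: SimulationConfig, reps: int, seed: int,
                     factors: Mapping[str, Sequence], outdir=None,
                     keep_series: bool = False) -> pd.DataFrame:
    """Run the Cartesian product of config-field factors, coculture only."""
    from itertools import product

    cache = _RunCache(base, reps, seed)
    keys = list(factors)
    rows = []
    for combo in product(*(factors[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        mean = cache.mean(**overrides)
        if keep_series:
            for _, rec in mean.iterrows():
                rows.append({**overrides, **rec.to_dict()})
        else:
            last = mean.iloc[-1]
            rows.append({**overrides, **last.to_dict()})
    table = pd.DataFrame(rows)
    if outdir is not None:
        _persist(outdir, name, {"seed": seed, "replicates": reps,
                                **{k: list(v) for k, v in factors.items()}},
                 table)
    return table


def suite_fig2_cost(costs: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
                    scale: str = "reduced",
                    antibiotic_levels: Sequence[float] = ANTIBIOTIC_LEVELS,
                    media: Sequence[str] = MEDIA,
                    seed: int = 0, replicates: int | None = None,
                    outdir=None) -> pd.DataFrame:
    """Cost-of-resistance sweep: coculture outcomes across media and A."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    frames = []
    for medium in media:
        base = scaled_config(scale, medium=medium)
        df = _factorial_suite("fig2", base, reps, seed,
                              {"cost": list(costs),
                               "antibiotic_bulk": list(antibiotic_levels)})
        df.insert(0, "medium", medium)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        _persist(outdir, "fig2", {"scale": scale, "seed": seed,
                                  "costs": list(costs)}, table)
    return table


def suite_fig3_detox(alphas: Sequence[float] = (0.0, 1.0),
                     scale: str = "reduced",
                     antibiotic_bulk: float = 0.2,
                     seed: int = 0, replicates: int | None = None,
                     outdir=None) -> pd.DataFrame:
    """Detoxification time series in the cross-feeding medium (coculture)."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    base = scaled_config(scale, medium="crossfeeding",
                         antibiotic_bulk=antibiotic_bulk)
    table = _factorial_suite("fig3", base, reps, seed,
                             {"alpha": list(alphas)}, keep_series=True)
    if outdir is not None:
        _persist(outdir, "fig3", {"scale": scale, "seed": seed,
                                  "alphas": list(alphas)}, table)
    return table


def suite_fig4_spatial(arrangements: Sequence[str] = ("random", "segregated"),
                       alphas: Sequence[float] = (0.0, 1.0),
                       scale: str = "reduced",
                       antibiotic_bulk: float = 0.2,
                       seed: int = 0, replicates: int | None = None,
                       outdir=None) -> pd.DataFrame:
    """Seeding arrangement x detoxification, with segregation trajectories."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    base = scaled_config(scale, medium="crossfeeding",
                         antibiotic_bulk=antibiotic_bulk)
    table = _factorial_suite("fig4", base, reps, seed,
                             {"arrangement": list(arrangements),
                              "alpha": list(alphas)}, keep_series=True)
    if outdir is not None:
        _persist(outdir, "fig4", {"scale": scale, "seed": seed}, table)
    return table


def suite_s3_inoculum(sizes: Sequence[int] = (60, 120, 960),
                      scale: str = "reduced", media: Sequence[str] = MEDIA,
                      antibiotic_levels: Sequence[float] = ANTIBIOTIC_LEVELS,
                      seed: int = 0, replicates: int | None = None,
                      outdir=None) -> pd.DataFrame:
    """Inoculum-size sweep; sizes are cells *per lineage* (1:1 seeding)."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    frames = []
    for medium in media:
        base = scaled_config(scale, medium=medium)
        df = _factorial_suite(
            "s3", base, reps, seed,
            {"n_R": list(sizes), "n_S": list(sizes),
             "antibiotic_bulk": list(antibiotic_levels)})
        df = df[df["n_R"] == df["n_S"]].reset_index(drop=True)
        df.insert(0, "medium", medium)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        _persist(outdir, "s3", {"scale": scale, "seed": seed,
                                "sizes": list(sizes)}, table)
    return table


def suite_s4_initial(proportions_S: Sequence[float] = (0.05, 0.5, 0.95),
                     arrangements: Sequence[str] = ("random", "segregated"),
                     scale: str = "reduced",
                     media: Sequence[str] = ("interference_competition",
                                             "crossfeeding"),
                     antibiotic_levels: Sequence[float] = ANTIBIOTIC_LEVELS,
                     seed: int = 0, replicates: int | None = None,
                     outdir=None) -> pd.DataFrame:
    """Initial proportion x mixing sweep at fixed total inoculum."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    total = 2 * SCALES[scale]["n_per_species"]
    frames = []
    for medium in media:
        base = scaled_config(scale, medium=medium)
        counts = [(total - int(round(p * total)), int(round(p * total)))
                  for p in proportions_S]
        rows = []
        cache = _RunCache(base, reps, seed)
        for (nR, nS), p in zip(counts, proportions_S):
            for arrangement in arrangements:
                for A in antibiotic_levels:
                    mean = cache.mean(n_R=nR, n_S=nS,
                                      arrangement=arrangement,
                                      antibiotic_bulk=A)
                    last = mean.iloc[-1]
                    rows.append({"medium": medium, "p_S": p,
                                 "arrangement": arrangement, "antibiotic": A,
                                 **last.to_dict()})
        frames.append(pd.DataFrame(rows))
    table = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        _persist(outdir, "s4", {"scale": scale, "seed": seed}, table)
    return table


def suite_s8_timing(start_times: Sequence[float] = (0.0, 4.0, 12.0, 24.0),
                    scale: str = "reduced", media: Sequence[str] = MEDIA,
                    antibiotic_bulk: float = 0.2,
                    seed: int = 0, replicates: int | None = None,
                    outdir=None) -> pd.DataFrame:
    """Antibiotic added at different stages of colony growth."""
    preset = SCALES[scale]
    reps = replicates if replicates is not None else preset["replicates"]
    frames = []
    for medium in media:
        base = scaled_config(scale, medium=medium,
                             antibiotic_bulk=antibiotic_bulk)
        df = _factorial_suite("s8", base, reps, seed,
                              {"antibiotic_start_time": list(start_times)})
        df.insert(0, "medium", medium)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        _persist(outdir, "s8", {"scale": scale, "seed": seed,
                                "start_times": list(start_times)}, table)
    return table


SUITES = {
    "fig1": suite_fig1,
    "fig2": suite_fig2_cost,
    "fig3": suite_fig3_detox,
    "fig4": suite_fig4_spatial,
    "s3": suite_s3_inoculum,
    "s4": suite_s4_initial,
    "s8": suite_s8_timing,
}


def run_suite(name: str, scale: str = "reduced", seed: int = 0,
              outdir=None, **kwargs) -> pd.DataFrame:
    if name not in SUITES:
        raise ConfigurationError(
            f"unknown suite {name!r}; available: {sorted(SUITES)}")
    return SUITES[name](scale=scale, seed=seed, outdir=outdir, **kwargs)


def _persist(outdir, name: str, config: dict, table: pd.DataFrame) -> None:
    path = Path(outdir) / name
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    table.to_csv(path / "metrics.csv", index=False)
    with open(path / "summary.json", "w") as fh:
        json.dump({"suite": name, "n_rows": int(len(table)),
                   "columns": list(table.columns)}, fh, indent=2)
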