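"""End-to-end condition runner and the six-cell comparison grid.

A *condition* is one fully specified analysis: an input record (synthetic
or from file), optional notch preprocessing, a phase backend, a locking
criterion and a band ladder.  ``run_condition`` executes the staged
pipeline and returns per-band interval distributions and scaling verdicts;
``run_grid`` evaluates a set of conditions (by default the 2x3 grid
{wavelet, hilbert} x {human, empty room + line, empty room + line +
notch}) and collects results with enough provenance to re-run
bit-identically.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .errors import ConfigurationError, PipelineStageError
from .lockintervals import (
    IntervalSet,
    LockCriterion,
    LogBinnedDistribution,
    extract_intervals,
    log_binned_distribution,
    phase_difference,
    pool_intervals,
    resolve_smoothing_window,
)
from .phase_extract import BandLadder, default_ladder, extract_phase
from .preprocess import NotchSpec, default_notch, notch_filter
from .record import TimeSeriesRecord, load_record
from .scalingfit import DEFAULT_MIN_TAIL, ScalingVerdict, compare_models
from .synthgen import GeneratorConfig, empty_room_config, generate, human_config

log = logging.getLogger("plscan.pipeline")

__all__ = [
    "ConditionSpec",
    "BandResult",
    "ConditionResult",
    "GridResult",
    "run_condition",
    "run_grid",
    "default_grid_specs",
    "MAX_EXHAUSTIVE_CHANNELS",
    "MAX_SAMPLED_PAIRS",
]

MAX_EXHAUSTIVE_CHANNELS = 32
MAX_SAMPLED_PAIRS = 496
#: xmin is never allowed below this many sample periods (discreteness guard).
XMIN_FLOOR_SAMPLES = 3


@dataclass
class ConditionSpec:
    """One cell of the analysis grid."""

    name: str
    method: str  # wavelet | hilbert
    generator: GeneratorConfig | None = None
    input_path: str | None = None
    notch: NotchSpec | None = None
    criterion: LockCriterion = field(default_factory=LockCriterion)
    ladder: BandLadder | None = None  # None -> default ladder for the record's fs
    bins_per_decade: int = 10
    min_tail: int = DEFAULT_MIN_TAIL
    pair_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"wavelet", "hilbert"}:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if (self.generator is None) == (self.input_path is None):
            raise ConfigurationError(
                "exactly one of generator / input_path must be given"
            )


@dataclass
class BandResult:
    band_name: str
    distribution: LogBinnedDistribution
    verdict: ScalingVerdict
    pooled: IntervalSet
    total_locked_s: float
    n_intervals: int
    smoothing_window: int

    def to_dict(self, include_distribution: bool = True) -> dict:
        d: dict[str, Any] = {
            "band": self.band_name,
            "total_locked_s": self.total_locked_s,
            "n_intervals": self.n_intervals,
            "n_censored": int(self.pooled.censored.sum()),
            "mean_duration_s": (float(self.pooled.durations.mean())
                                if len(self.pooled) else None),
            "smoothing_window": self.smoothing_window,
            "scaling": self.verdict.to_dict(),
        }
        if include_distribution and not self.distribution.empty:
            d["distribution"] = {
                "edges_s": self.distribution.edges.tolist(),
                "density": self.distribution.density.tolist(),
                "counts": self.distribution.counts.tolist(),
                "n": self.distribution.n,
                "mean_duration_s": self.distribution.mean_duration,
            }
        return d


@dataclass
class ConditionResult:
    name: str
    bands: dict[str, BandResult]
    provenance: dict[str, Any]

    def to_dict(self, include_distribution: bool = True) -> dict:
        return {
            "name": self.name,
            "provenance": self.provenance,
            "bands": {k: v.to_dict(include_distribution) for k, v in self.bands.items()},
        }


@dataclass
class GridResult:
    cells: dict[str, Any]  # name -> {"status": ..., "result"/"error": ...}
    provenance: dict[str, Any]

    def to_dict(self, include_distribution: bool = True) -> dict:
        out: dict[str, Any] = {"provenance": self.provenance, "cells": {}}
        for name, cell in self.cells.items():
            if cell["status"] == "ok":
                out["cells"][name] = {
                    "status": "ok",
                    "result": cell["result"].to_dict(include_distribution),
                }
            else:
                out["cells"][name] = {"status": "failed", "error": cell["error"],
                                      "stage": cell.get("stage")}
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(**kwargs), indent=2, sort_keys=True)


def _channel_pairs(labels: Sequence[str], seed: int) -> list[tuple[int, int]]:
    """All unordered pairs, or a seeded random subset for very wide arrays."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    if n > MAX_EXHAUSTIVE_CHANNELS and len(pairs) > MAX_SAMPLED_PAIRS:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=MAX_SAMPLED_PAIRS, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs


def _stage(name: str):
    """Decorator-free stage wrapper attaching stage identity to failures."""
    class _Ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage=%s wall_s=%.3f", name, dt)
                return False
            if isinstance(exc, PipelineStageError):
                return False
            raise PipelineStageError(name, exc) from exc

    return _Ctx()


def run_condition(spec: ConditionSpec) -> ConditionResult:
    """Execute one condition: load/generate -> notch -> phase -> intervals ->
    per-band distribution and scaling verdict."""
    with _stage("input"):
        if spec.generator is not None:
            record = generate(spec.generator)
        else:
            record = load_record(spec.input_path)

    with _stage("notch"):
        if spec.notch is not None:
            record = notch_filter(record, spec.notch)

    ladder = spec.ladder if spec.ladder is not None else default_ladder(record.fs)

    with _stage("phase"):
        stack = extract_phase(record, spec.method, ladder)

    pairs = _channel_pairs(record.labels, spec.pair_seed)
    xmin_floor = XMIN_FLOOR_SAMPLES / record.fs

    bands: dict[str, BandResult] = {}
    with _stage("intervals"):
        for bi, band in enumerate(ladder):
            window = resolve_smoothing_window(spec.criterion, spec.method,
                                              record.fs, band)
            crit = spec.criterion.with_window(window)
            sets = []
            for i, j in pairs:
                dphi = phase_difference(stack.phases[bi, i], stack.phases[bi, j])
                valid = stack.valid[bi, i] & stack.valid[bi, j]
                sets.append(extract_intervals(
                    dphi, valid, record.fs, crit,
                    pair=(record.labels[i], record.labels[j]), band=band,
                ))
            pooled = pool_intervals(sets, by="band")
            dist = log_binned_distribution(pooled, spec.bins_per_decade)
            verdict = compare_models(
                pooled.durations, xmin="auto", xmin_floor=xmin_floor,
                min_tail=spec.min_tail, band=band,
            )
            bands[band.name] = BandResult(
                band_name=band.name,
                distribution=dist,
                verdict=verdict,
                pooled=pooled,
                total_locked_s=pooled.total_locked,
                n_intervals=len(pooled),
                smoothing_window=window,
            )

    provenance = {
        "version": __version__,
        "method": spec.method,
        "notch": None if spec.notch is None else {
            "f0": spec.notch.f0, "n_harmonics": spec.notch.n_harmonics,
            "quality": spec.notch.quality,
        },
        "criterion": {
            "threshold": spec.criterion.threshold,
            "smoothing_window": spec.criterion.smoothing_window,
            "min_duration": spec.criterion.min_duration,
            "include_censored": spec.criterion.include_censored,
        },
        "ladder": [{"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi} for b in ladder],
        "input": (record.meta.get("generator") if spec.generator is not None
                  else {"path": spec.input_path}),
        "n_pairs": len(pairs),
    }
    return ConditionResult(name=spec.name, bands=bands, provenance=provenance)


def run_grid(specs: Sequence[ConditionSpec]) -> GridResult:
    """Run every condition; failed cells are recorded, not fatal."""
    if not specs:
        raise ConfigurationError("grid needs at least one condition")
    cells: dict[str, Any] = {}
    for spec in specs:
        try:
            cells[spec.name] = {"status": "ok", "result": run_condition(spec)}
        except PipelineStageError as e:
            log.error("cell=%s failed at stage=%s: %r", spec.name, e.stage, e.original)
            cells[spec.name] = {"status": "failed", "stage": e.stage,
                                "error": repr(e.original)}
        except Exception as e:  # pragma: no cover - defensive
            log.error("cell=%s failed: %r", spec.name, e)
            cells[spec.name] = {"status": "failed", "stage": None, "error": repr(e)}
    return GridResult(
        cells=cells,
        provenance={
            "version": __version__,
            "conditions": [s.name for s in specs],
            "note": ("synthetic records stand in for the original recordings; "
                     "all 'human' cells use the coupled 1/f generator preset"),
        },
    )


def default_grid_specs(
    seed: int = 0,
    duration: float = 300.0,
    fs: float = 600.0,
    n_channels: int = 4,
    line_f0: float = 50.0,
    criterion: LockCriterion | None = None,
) -> list[ConditionSpec]:
    """The six default cells: {wavelet, hilbert} x
    {human, empty room + line, empty room + line + notch}."""
    crit = criterion if criterion is not None else LockCriterion()
    human = human_config(duration=duration, fs=fs, n_channels=n_channels, seed=seed)
    empty = empty_room_config(line_f0=line_f0, duration=duration, fs=fs,
                              n_channels=n_channels, seed=seed + 1)
    specs = []
    for method in ("wavelet", "hilbert"):
        specs.append(ConditionSpec(
            name=f"human_{method}", method=method, generator=human, criterion=crit))
        specs.append(ConditionSpec(
            name=f"empty_line_{method}", method=method, generator=empty, criterion=crit))
        specs.append(ConditionSpec(
            name=f"empty_notched_{method}", method=method, generator=empty,
            notch=default_notch(line_f0), criterion=crit))
    return specs
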