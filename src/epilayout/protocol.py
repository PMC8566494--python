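"""Bounding-box sweep protocol and design selection rules.

The search region is a wrist-anchored window spanning the full forearm
width from the wrist crease (v = 0) up to height h, intersected with the
forearm outline.  The window grows in fixed increments (1 mm reproduces the
printed protocol; coarser increments scale the sweep down) and the
optimizer runs once per window with a seed derived deterministically from
(base seed, window height), so windows are independent yet reproducible.

Two designs are then selected from the recorded list:

* AREA-OPTIMIZED - the design at the smallest window whose modality-cost
  aggregate is below 1 (the first window where any signal is predicted at
  all), trading quality for footprint;
* QUALITY-OPTIMIZED - the smallest-hull design among those whose modality
  aggregate is at most 0.05 (predicted quality >= 0.95).

A single upward sweep serves both selections; the rules only consult the
recorded designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .anatomy import ForearmModel
from .costs import LowerBounds, Weights
from .errors import InfeasibleRegionError, SelectionError
from .optimize import Design, OptimizerConfig, anneal

__all__ = [
    "SweepEntry",
    "SweepResult",
    "window_seed",
    "bounding_box_sweep",
    "select_area_optimized",
    "select_quality_optimized",
]

log = logging.getLogger(__name__)

QUALITY_FLOOR = 0.95


@dataclass(frozen=True)
class SweepEntry:
    """One sweep window: its height and either a design or an
    infeasibility marker."""

    height: float
    design: Design | None

    @property
    def feasible(self) -> bool:
        return self.design is not None


@dataclass(frozen=True)
class SweepResult:
    entries: tuple[SweepEntry, ...]
    increment: float
    direction: str
    base_seed: int

    @property
    def feasible_entries(self) -> tuple[SweepEntry, ...]:
        return tuple(e for e in self.entries if e.feasible)


def window_seed(base_seed: int, height: float) -> int:
    """Deterministic per-window seed below 2^31, derived from the base seed
    and the window height."""
    ss = np.random.SeedSequence([int(base_seed), int(round(height * 16))])
    return int(ss.generate_state(1)[0] % (2**31))


def _window_polygon(model: ForearmModel, height: float):
    half = model.max_width / 2.0 + 1.0
    return ((-half, 0.0), (half, 0.0), (half, height), (-half, height))


def bounding_box_sweep(model: ForearmModel, weights: Weights,
                       config: OptimizerConfig | None = None,
                       muscles: Sequence[str] = (),
                       modalities: Iterable[str] = ("emg",),
                       bounds: LowerBounds | None = None,
                       increment: float = 1.0,
                       direction: str = "up",
                       min_height: float | None = None) -> SweepResult:
    """Optimize within wrist-anchored windows of increasing height.

    Windows run from ``min_height`` (default: one increment) to the full
    forearm length in ``increment`` steps; infeasible windows are recorded
    as markers, not errors.  ``direction="down"`` records the same windows
    in decreasing order (fidelity flag; selection rules are order-free).
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    config = config or OptimizerConfig()
    start = increment if min_height is None else min_height
    heights = []
    h = start
    while h < model.length - 1e-9:
        heights.append(round(h, 9))
        h += increment
    heights.append(model.length)
    if direction == "down":
        heights = heights[::-1]

    entries = []
    for h in heights:
        window = _window_polygon(model, h)
        cfg = OptimizerConfig(
            t0=config.t0, gamma=config.gamma, candidates=config.candidates,
            moves_per_temp=config.moves_per_temp, step=config.step,
            seed=window_seed(config.seed, h), min_spacing=config.min_spacing,
            scheme=config.scheme, max_init_attempts=config.max_init_attempts,
            track_history=config.track_history)
        try:
            design = anneal(model, weights, muscles=muscles,
                            modalities=modalities, bounds=bounds,
                            shape=window, config=cfg, window_height=h)
        except InfeasibleRegionError:
            log.info("window h=%.1f mm infeasible", h)
            entries.append(SweepEntry(height=h, design=None))
            continue
        entries.append(SweepEntry(height=h, design=design))
    return SweepResult(entries=tuple(entries), increment=increment,
                       direction=direction, base_seed=config.seed)


def select_area_optimized(sweep: SweepResult) -> Design:
    """The design at the smallest window whose modality-cost aggregate is
    below 1; ties broken by smaller hull area."""
    candidates = [e for e in sweep.feasible_entries
                  if e.design.cost.aggregate < 1.0]
    if not candidates:
        raise SelectionError("no sweep window achieved a modality aggregate below 1")
    best = min(candidates, key=lambda e: (e.height, e.design.cost.hull_area))
    return best.design


def select_quality_optimized(sweep: SweepResult,
                             quality_floor: float = QUALITY_FLOOR) -> Design:
    """Among designs with predicted quality >= ``quality_floor`` (modality
    aggregate <= 1 - floor), the one with the smallest hull area; ties
    broken by smaller window height."""
    ceiling = 1.0 - quality_floor
    candidates = [e for e in sweep.feasible_entries
                  if e.design.cost.aggregate <= ceiling + 1e-12]
    if not candidates:
        raise SelectionError(
            f"no sweep design reached predicted quality >= {quality_floor}")
    best = min(candidates, key=lambda e: (e.design.cost.hull_area, e.height))
    return best.design
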