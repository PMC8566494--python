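"""Simulated-annealing search over electrode placements.

The layout design task is a constrained geometric packing problem: place
the measurement electrodes inside a region (the forearm outline, optionally
intersected with a user shape or sweep window) subject to a 12 mm minimum
centre-to-centre spacing, minimizing the global objective.  Starting from a
random valid layout, each step translates one uniformly chosen electrode by
a random vector; invalid proposals are rejected outright and only valid
ones are scored.  Worse solutions are accepted with probability
``exp(-dO / T)`` under geometric cooling, and the best layout seen is
returned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .anatomy import ForearmModel
from .costs import (
    CostBreakdown,
    Electrode,
    Layout,
    LowerBounds,
    Weights,
    _reference_electrodes,
    baseline_area as _baseline_area,
    global_objective,
    measurement_roster,
)
from .errors import ConfigError, DomainError, InfeasibleRegionError

__all__ = [
    "MIN_SPACING",
    "OptimizerConfig",
    "Design",
    "validate_layout",
    "random_initial_layout",
    "propose_neighbor",
    "accept",
    "anneal",
]

log = logging.getLogger(__name__)

#: Minimum pairwise centre-to-centre distance between measurement
#: electrodes (mm).  Larger than any r1 + r2 here, so it also enforces
#: non-overlap.
MIN_SPACING = 12.0


@dataclass(frozen=True)
class OptimizerConfig:
    """Annealing schedule and constraint parameters.

    ``candidates`` is the number of scored (valid) layouts per run; the
    printed protocol uses 15,490.  ``moves_per_temp`` defaults to
    ``ceil(candidates / 150)`` so any budget traverses the same temperature
    range T0 -> ~T0 * gamma^150.

    The proposal kernel is a mixture: with probability ``p_relocate`` one
    electrode is re-placed uniformly in the search region, with
    ``p_pair_relocate`` a whole functional pair is re-placed jointly
    (uniform first member, second member at a uniform direction and a
    spacing drawn from the useful inter-electrode range), and otherwise one
    electrode takes a local step of magnitude uniform on (0, ``step``].
    The jump moves are essential: the modality costs are flat (cost 1)
    until *both* electrodes of a pair reach their target region, so purely
    local moves leave pairs stranded on the plateau.
    """

    t0: float = 0.1
    gamma: float = 0.95
    candidates: int = 15490
    moves_per_temp: int | None = None
    step: float = 10.0
    p_relocate: float = 0.15
    p_pair_relocate: float = 0.35
    seed: int = 0
    min_spacing: float = MIN_SPACING
    scheme: str = "weights"
    max_init_attempts: int = 10_000
    track_history: bool = False

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ConfigError("initial temperature must be positive")
        if not 0 < self.gamma < 1:
            raise ConfigError("cooling factor must be in (0, 1)")
        if self.candidates < 1:
            raise ConfigError("candidates must be >= 1")
        if self.step < 0:
            raise ConfigError("step must be >= 0")
        if self.min_spacing <= 0:
            raise ConfigError("min spacing must be positive")
        if self.scheme not in ("weights", "bounds", "hybrid"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if not 0 <= self.p_relocate <= 1 or not 0 <= self.p_pair_relocate <= 1 \
                or self.p_relocate + self.p_pair_relocate > 1:
            raise ConfigError("move-mixture probabilities must be in [0, 1] and sum to <= 1")

    @property
    def effective_moves_per_temp(self) -> int:
        if self.moves_per_temp is not None:
            return self.moves_per_temp
        return max(1, math.ceil(self.candidates / 150))


@dataclass(frozen=True)
class Design:
    """An optimized (or scored) layout plus everything needed to reproduce
    and re-score it."""

    layout: Layout
    cost: CostBreakdown
    weights: Weights
    bounds: LowerBounds | None
    config: OptimizerConfig
    muscles: tuple[str, ...]
    modalities: tuple[str, ...]
    measurements: tuple[float, float, float, float]
    template_fingerprint: str
    shape: tuple[tuple[float, float], ...] | None = None
    window_height: float | None = None
    history: tuple[float, ...] = field(default=(), compare=False)


def _pairwise_ok(centers: np.ndarray, radii: np.ndarray, min_spacing: float,
                 ) -> list[tuple[int, int, float]]:
    bad = []
    n = len(centers)
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(centers[i], centers[j])
            need = max(min_spacing, radii[i] + radii[j])
            if d < need:
                bad.append((i, j, d))
    return bad


def validate_layout(layout: Layout, regions: Sequence,
                    min_spacing: float = MIN_SPACING,
                    ) -> tuple[bool, list[str]]:
    """Check spacing and containment for the measurement electrodes.

    ``regions`` is a list of polygons; every measurement electrode centre
    must lie inside all of them (e.g. a sweep window *and* the forearm
    outline).  Reference electrodes are exempt.  Returns (ok, violations).
    """
    from .geometry import point_in_polygon

    meas = layout.measurement
    centers = np.array([e.center for e in meas], dtype=float)
    radii = np.array([e.radius for e in meas], dtype=float)
    violations: list[str] = []
    for i, j, d in _pairwise_ok(centers, radii, min_spacing):
        violations.append(
            f"spacing: electrodes {i} and {j} are {d:.2f} mm apart "
            f"(minimum {max(min_spacing, radii[i] + radii[j]):.2f} mm)")
    for i, e in enumerate(meas):
        for region in regions:
            if not point_in_polygon(e.center, region):
                violations.append(f"containment: electrode {i} centre {e.center} outside region")
                break
    return (not violations), violations


def _region_bbox(regions: Sequence) -> tuple[float, float, float, float]:
    first = np.asarray(regions[0], dtype=float)
    lo = first.min(axis=0)
    hi = first.max(axis=0)
    for region in regions[1:]:
        arr = np.asarray(region, dtype=float)
        lo = np.maximum(lo, arr.min(axis=0))
        hi = np.minimum(hi, arr.max(axis=0))
    return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])


def random_initial_layout(roster: Sequence[Electrode], regions: Sequence,
                          rng: np.random.Generator,
                          min_spacing: float = MIN_SPACING,
                          max_attempts: int = 10_000,
                          references: Sequence[Electrode] = (),
                          ) -> Layout:
    """Uniform rejection sampling of a valid layout inside the region
    intersection.  Deterministic for a given generator state.  Raises
    :class:`InfeasibleRegionError` after ``max_attempts`` failed layout
    attempts (tight windows in the sweep protocol land here).
    """
    from .geometry import point_in_polygon

    x0, y0, x1, y1 = _region_bbox(regions)
    if x1 <= x0 or y1 <= y0:
        raise InfeasibleRegionError("region bounding boxes do not intersect")
    tries_per_electrode = 60
    for _ in range(max_attempts):
        placed: list[Electrode] = []
        ok = True
        for proto in roster:
            for _ in range(tries_per_electrode):
                c = (float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1)))
                if not all(point_in_polygon(c, region) for region in regions):
                    continue
                if any(math.dist(c, p.center) < max(min_spacing, proto.radius + p.radius)
                       for p in placed):
                    continue
                placed.append(proto.moved_to(c))
                break
            else:
                ok = False
                break
        if ok:
            return Layout(tuple(placed) + tuple(references))
    raise InfeasibleRegionError(
        f"no valid layout with {len(roster)} electrodes found in "
        f"{max_attempts} attempts")


def propose_neighbor(layout: Layout, rng: np.random.Generator, step: float,
                     ) -> tuple[Layout, int]:
    """Translate one uniformly chosen measurement electrode by a vector with
    uniform direction and magnitude uniform on (0, step].  The proposal is
    returned regardless of validity (validity is enforced by rejection in
    :func:`anneal`).  Also returns the moved index."""
    meas = layout.measurement
    idx = int(rng.integers(len(meas)))
    angle = rng.uniform(0.0, 2.0 * math.pi)
    mag = (1.0 - rng.random()) * step  # uniform on (0, step]
    e = meas[idx]
    new_center = (e.center[0] + mag * math.cos(angle),
                  e.center[1] + mag * math.sin(angle))
    return layout.replace(idx, e.moved_to(new_center)), idx


def accept(delta_o: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: draw c ~ U(0,1) and accept iff c <= exp(-dO/T).
    Improvements (dO <= 0) are always accepted."""
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    c = rng.random()
    if delta_o <= 0:
        return True
    return c <= math.exp(-delta_o / temperature)


def _move_valid(layout: Layout, moved: Sequence[int], regions: Sequence,
                min_spacing: float) -> bool:
    """Validity of a move: only the moved electrodes need rechecking
    against the others and the regions."""
    from .geometry import point_in_polygon

    meas = layout.measurement
    moved = tuple(moved)
    for idx in moved:
        e = meas[idx]
        if not all(point_in_polygon(e.center, region) for region in regions):
            return False
        for j, other in enumerate(meas):
            if j == idx or (j in moved and j < idx):
                continue
            if math.dist(e.center, other.center) < max(min_spacing, e.radius + other.radius):
                return False
    return True


def _pair_groups(layout: Layout) -> list[tuple[int, int]]:
    """Indices of functional electrode pairs among the measurement set."""
    groups: dict[tuple[str, str | None], list[int]] = {}
    for i, e in enumerate(layout.measurement):
        groups.setdefault((e.modality, e.muscle), []).append(i)
    return [tuple(idx) for idx in groups.values() if len(idx) == 2]  # type: ignore[misc]


def _propose_move(layout: Layout, rng: np.random.Generator,
                  config: OptimizerConfig, bbox: tuple[float, float, float, float],
                  pairs: list[tuple[int, int]],
                  ) -> tuple[Layout, tuple[int, ...]]:
    """One draw from the move mixture.  Draw order is fixed for
    reproducibility: mixture uniform, then the move's own coordinates."""
    x0, y0, x1, y1 = bbox
    u = rng.random()
    meas = layout.measurement
    if u < config.p_pair_relocate and pairs:
        i, j = pairs[int(rng.integers(len(pairs)))]
        a = (float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1)))
        angle = rng.uniform(0.0, 2.0 * math.pi)
        lo = max(config.min_spacing, meas[i].radius + meas[j].radius)
        d = rng.uniform(lo, 60.0)
        b = (a[0] + d * math.cos(angle), a[1] + d * math.sin(angle))
        moved = layout.replace(i, meas[i].moved_to(a))
        moved = moved.replace(j, meas[j].moved_to(b))
        return moved, (i, j)
    if u < config.p_pair_relocate + config.p_relocate:
        idx = int(rng.integers(len(meas)))
        c = (float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1)))
        return layout.replace(idx, meas[idx].moved_to(c)), (idx,)
    proposal, idx = propose_neighbor(layout, rng, config.step)
    return proposal, (idx,)


def anneal(model: ForearmModel, weights: Weights,
           muscles: Sequence[str] = (),
           modalities: Iterable[str] = ("emg",),
           bounds: LowerBounds | None = None,
           shape: Sequence | None = None,
           config: OptimizerConfig | None = None,
           window_height: float | None = None) -> Design:
    """Run simulated annealing and return the best design found.

    ``shape`` optionally restricts placement to a closed polygon (mm);
    electrodes must additionally stay inside the forearm outline.  The run
    is bit-reproducible for a given ``config.seed``: all randomness flows
    from one generator in a fixed draw order (initial layout, then per move:
    electrode index, direction, magnitude, acceptance uniform).
    """
    config = config or OptimizerConfig()
    modalities = tuple(sorted(frozenset(modalities)))
    muscles = tuple(muscles)
    rng = np.random.default_rng(config.seed)
    regions: list = [model.outline]
    if shape is not None:
        regions.append(tuple((float(p[0]), float(p[1])) for p in shape))
    roster = measurement_roster(muscles, modalities)
    references = _reference_electrodes(modalities, model)
    base_area = _baseline_area(model, muscles, modalities)

    current = random_initial_layout(
        roster, regions, rng, min_spacing=config.min_spacing,
        max_attempts=config.max_init_attempts, references=references)
    score = lambda lay: global_objective(
        lay, model, weights, bounds=bounds, baseline_area=base_area,
        scheme=config.scheme)
    cur_cost = score(current)
    best, best_cost = current, cur_cost

    bbox = _region_bbox(regions)
    pairs = _pair_groups(current)
    history = [cur_cost.objective] if config.track_history else None
    temperature = config.t0
    moves_per_temp = config.effective_moves_per_temp
    evals = 1
    proposals = 0
    proposal_cap = 50 * config.candidates
    moves_at_temp = 0
    while evals < config.candidates and proposals < proposal_cap:
        proposals += 1
        proposal, moved = _propose_move(current, rng, config, bbox, pairs)
        if not _move_valid(proposal, moved, regions, config.min_spacing):
            continue
        new_cost = score(proposal)
        evals += 1
        if accept(new_cost.objective - cur_cost.objective, temperature, rng):
            current, cur_cost = proposal, new_cost
        if new_cost.objective < best_cost.objective:
            best, best_cost = proposal, new_cost
        if history is not None:
            history.append(cur_cost.objective)
        moves_at_temp += 1
        if moves_at_temp >= moves_per_temp:
            temperature *= config.gamma
            moves_at_temp = 0
    if proposals >= proposal_cap:
        log.warning("proposal cap reached after %d valid evaluations", evals)

    return Design(
        layout=best, cost=best_cost, weights=weights, bounds=bounds,
        config=config, muscles=muscles, modalities=modalities,
        measurements=model.measurements.as_tuple(),
        template_fingerprint=model.template_fingerprint,
        shape=regions[1] if shape is not None else None,
        window_height=window_height,
        history=tuple(history) if history is not None else (),
    )
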