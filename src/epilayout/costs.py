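"""Predictive cost model for multi-modal electrode layouts.

Every modality cost is normalized to [0, 1], 0 = best predicted signal
quality, 1 = worst, so that heterogeneous signal-quality literature (EMG
amplitude, skin conductance, ECG SNR) combines into one objective:

* EMG (per muscle): pre-checks (<= 1 cm from the muscle line, no electrode
  disk inside an innervation zone), then ``alpha * omega(theta) +
  (1 - alpha) * nu(d)`` where ``omega`` penalizes misalignment with the
  muscle line and ``nu`` penalizes bad inter-electrode distances.  The EMG
  aggregate is the unweighted mean over selected muscles; modality weights
  are applied exactly once, in the global objective.
* EDA: the number of sweat glands covered between the pair,
  ``N_s = (pi r^2 + 2 r d) * D_s``, relative to the maximum coverable at the
  recommended 6 cm spacing; fewer than 140 glands (or spacing beyond 6 cm)
  is non-functional and costs 1.
* ECG: a discrete candidate-pair model; the placed pair is matched to the
  nearest candidate keypoint pair and costs ``1 - SNR/SNR_max``, or 1 when
  no candidate is within the capture radius.
* Area: convex-hull footprint of the measurement electrode disks,
  normalized by the footprint of the rule-based baseline layout.

Optional per-modality quality bounds enter as exponential penalties
``P_k = p * (exp(max(O_k - l_k, 0)) - 1)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .anatomy import ForearmModel, MuscleGeometry
from .errors import ConfigError, DomainError, RoleError, TemplateError
from .errors import DegenerateGeometryError
from .geometry import (
    convex_hull,
    convex_hull_area,
    pair_angle_to_line,
    point_polygon_distance,
    point_segment_distance,
    polygon_area,
)

__all__ = [
    "EMG_ELECTRODE_RADIUS",
    "EDA_ELECTRODE_RADIUS",
    "MIN_GLANDS",
    "EDA_RECOMMENDED_DISTANCE",
    "MUSCLE_LINE_MAX_OFFSET",
    "ECG_CAPTURE_RADIUS",
    "Electrode",
    "Layout",
    "Weights",
    "LowerBounds",
    "CostBreakdown",
    "omega",
    "nu",
    "emg_muscle_cost",
    "emg_total",
    "eda_gland_count",
    "eda_cost",
    "ecg_cost",
    "layout_hull_area",
    "area_cost",
    "lower_bound_penalty",
    "combine_objective",
    "global_objective",
    "measurement_roster",
    "build_baseline_layout",
    "baseline_area",
]

log = logging.getLogger(__name__)

#: EMG and ECG electrodes have a 50 mm^2 sensing surface.
EMG_ELECTRODE_RADIUS = math.sqrt(50.0 / math.pi)  # ~3.989 mm
#: EDA electrodes have a 0.78 cm^2 (~80 mm^2) surface; r = 0.5 cm exactly.
EDA_ELECTRODE_RADIUS = 5.0
#: Minimum sweat glands between the EDA pair for a functional measurement.
MIN_GLANDS = 140.0
#: Recommended EDA inter-electrode distance (mm).
EDA_RECOMMENDED_DISTANCE = 60.0
#: Electrodes farther than 1 cm from the muscle line score 1.
MUSCLE_LINE_MAX_OFFSET = 10.0
#: Per-electrode capture radius for matching a placed ECG pair to a
#: candidate keypoint pair (mm).
ECG_CAPTURE_RADIUS = 20.0

MODALITIES = ("emg", "eda", "ecg")


@dataclass(frozen=True)
class Electrode:
    """A positioned electrode disk.

    ``modality`` is one of ``emg`` / ``eda`` / ``ecg``; ``muscle`` is set for
    EMG electrodes; ``member`` distinguishes the two electrodes of a pair.
    Reference electrodes sit off the forearm and are excluded from spacing,
    containment and the area hull.
    """

    center: tuple[float, float]
    radius: float
    modality: str
    member: str = "A"
    muscle: str | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigError("electrode radius must be positive")
        if self.modality not in MODALITIES:
            raise RoleError(f"unknown modality {self.modality!r}")
        if self.modality == "emg" and not self.is_reference and self.muscle is None:
            raise RoleError("EMG measurement electrode needs a muscle id")

    def moved_to(self, center: tuple[float, float]) -> "Electrode":
        return Electrode(center=(float(center[0]), float(center[1])),
                         radius=self.radius, modality=self.modality,
                         member=self.member, muscle=self.muscle,
                         is_reference=self.is_reference)


@dataclass(frozen=True)
class Layout:
    """An electrode set partitioned into per-modality subsets.

    Measurement electrodes: two per selected muscle (EMG), two for EDA, two
    for ECG.  At most two reference electrodes (one shared EMG reference,
    one ECG reference) ride along but take no part in geometry.
    """

    electrodes: tuple[Electrode, ...]

    @property
    def measurement(self) -> tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if not e.is_reference)

    @property
    def references(self) -> tuple[Electrode, ...]:
        return tuple(e for e in self.electrodes if e.is_reference)

    def emg_pair(self, muscle: str) -> tuple[Electrode, Electrode]:
        pair = tuple(e for e in self.measurement
                     if e.modality == "emg" and e.muscle == muscle)
        if len(pair) != 2:
            raise RoleError(f"expected 2 EMG electrodes for muscle {muscle}, got {len(pair)}")
        return pair  # type: ignore[return-value]

    def modality_pair(self, modality: str) -> tuple[Electrode, Electrode]:
        pair = tuple(e for e in self.measurement if e.modality == modality)
        if len(pair) != 2:
            raise RoleError(f"expected 2 {modality} electrodes, got {len(pair)}")
        return pair  # type: ignore[return-value]

    @property
    def muscles(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.measurement:
            if e.modality == "emg" and e.muscle not in seen:
                seen.append(e.muscle)  # type: ignore[arg-type]
        return tuple(seen)

    @property
    def modalities(self) -> frozenset[str]:
        return frozenset(e.modality for e in self.measurement)

    def replace(self, index: int, electrode: Electrode) -> "Layout":
        meas = list(self.measurement)
        meas[index] = electrode
        return Layout(electrodes=tuple(meas) + self.references)


@dataclass(frozen=True)
class Weights:
    """Modality priorities.  ``emg + eda + ecg`` must be 1 over the enabled
    modalities in the weight-based scheme; ``area`` is the small-area
    priority; ``alpha`` balances alignment vs. spacing inside the EMG term."""

    emg: float = 0.0
    eda: float = 0.0
    ecg: float = 0.0
    area: float = 0.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if any(w < 0 for w in (self.emg, self.eda, self.ecg, self.area)):
            raise ConfigError("weights must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must be in [0, 1]")

    def modality_weight(self, modality: str) -> float:
        return {"emg": self.emg, "eda": self.eda, "ecg": self.ecg}[modality]


@dataclass(frozen=True)
class LowerBounds:
    """Per-modality cost ceilings l_k with penalty softness p.

    ``l_k`` is the largest acceptable cost for modality k ("lower bound" on
    quality); exceeding it incurs an exponential penalty scaled by ``p``.
    """

    emg: float = 1.0
    eda: float = 1.0
    ecg: float = 1.0
    softness: float = 1.0

    def __post_init__(self) -> None:
        for name in ("emg", "eda", "ecg"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"bound for {name} must be in [0, 1]")
        if self.softness < 0:
            raise ConfigError("softness must be >= 0")

    def bound(self, modality: str) -> float:
        return {"emg": self.emg, "eda": self.eda, "ecg": self.ecg}[modality]


@dataclass(frozen=True)
class CostBreakdown:
    """Full objective decomposition for one layout."""

    muscle_costs: Mapping[str, float]
    emg: float | None
    eda: float | None
    ecg: float | None
    hull_area: float
    baseline_area: float | None
    area_ratio: float
    penalties: Mapping[str, float]
    objective: float
    quality: float

    @property
    def aggregate(self) -> float:
        """Modality-cost aggregate (the optimizer score without the area
        term); the complement of the reported quality."""
        return 1.0 - self.quality


# ---------------------------------------------------------------------------
# elementary cost curves

def omega(theta: float) -> float:
    """Orientation cost for the angle (degrees) between an electrode pair
    and its muscle line: ``0.0057 th + 0.000181 th^2`` up to 60 deg, then 1
    (signal drops drastically for misalignments beyond 60 deg)."""
    if not 0.0 <= theta <= 90.0:
        raise DomainError(f"theta must be in [0, 90] degrees, got {theta}")
    if theta > 60.0:
        return 1.0
    val = 0.0057 * theta + 0.000181 * theta * theta
    return min(1.0, max(0.0, val))


def nu(d: float) -> float:
    """Inter-electrode-distance cost for an EMG pair (d in mm).

    Quadratic taper on (5, 25], zero on the good plateau (25, 60], 1 beyond
    60 mm.  Below 5 mm the curve is undefined in the source data; such pairs
    cost 1 (conservative; unreachable under the 12 mm spacing constraint).
    """
    if d <= 0 or not np.isfinite(d):
        raise DomainError(f"distance must be positive, got {d}")
    if d <= 5.0:
        return 1.0
    if d <= 25.0:
        return max(0.0, 1.0125 - 0.0586 * d + 0.0007 * d * d)
    if d <= 60.0:
        return 0.0
    return 1.0


# ---------------------------------------------------------------------------
# modality costs

def _disk_intersects_polygon(center, radius: float, polygon) -> bool:
    return point_polygon_distance(center, polygon) <= radius


def emg_muscle_cost(pair: Sequence[Electrode], muscle: MuscleGeometry,
                    alpha: float = 0.5) -> float:
    """Cost of one EMG pair against its muscle line.

    1 if either centre is more than 1 cm off the muscle line, or either
    electrode disk overlaps an innervation zone; otherwise the alpha-weighted
    mix of the orientation and distance costs.
    """
    e1, e2 = pair
    for e in (e1, e2):
        if e.modality != "emg" or e.is_reference:
            raise RoleError("emg_muscle_cost needs EMG measurement electrodes")
        if e.muscle != muscle.id:
            raise RoleError(f"electrode assigned to {e.muscle}, not {muscle.id}")
    a, b = muscle.segment
    for e in (e1, e2):
        if point_segment_distance(e.center, a, b) > MUSCLE_LINE_MAX_OFFSET:
            return 1.0
    for e in (e1, e2):
        for iz in muscle.iz:
            if _disk_intersects_polygon(e.center, e.radius, iz):
                return 1.0
    d = math.dist(e1.center, e2.center)
    if d <= 0:
        return 1.0
    theta = pair_angle_to_line(e1.center, e2.center, a, b)
    return alpha * omega(theta) + (1.0 - alpha) * nu(d)


def emg_total(layout: Layout, model: ForearmModel,
              muscles: Sequence[str] | None = None, alpha: float = 0.5,
              ) -> tuple[float, dict[str, float]]:
    """Mean EMG cost over the selected muscles plus the per-muscle map.

    The mean is unweighted; the EMG priority weight is applied once, in
    :func:`global_objective`.
    """
    muscles = tuple(muscles) if muscles is not None else layout.muscles
    if not muscles:
        raise ConfigError("EMG enabled but no muscle selected")
    per = {}
    for mid in muscles:
        if mid not in model.muscles:
            raise ConfigError(f"muscle {mid} not in the anatomical model")
        per[mid] = emg_muscle_cost(layout.emg_pair(mid), model.muscles[mid], alpha)
    return sum(per.values()) / len(per), per


def eda_gland_count(d: float, r: float, density: float) -> float:
    """Number of sweat glands covered by an EDA pair: the two disk surfaces
    plus the strip between them, ``(pi r^2 + d * 2r) * D_s`` (all mm)."""
    if d < 0 or r <= 0 or density <= 0:
        raise DomainError("d must be >= 0, r and density > 0")
    return (math.pi * r * r + d * 2.0 * r) * density


def eda_cost(pair: Sequence[Electrode], density: float) -> float:
    """EDA cost: 1 when non-functional (fewer than 140 glands covered, or
    spacing beyond the recommended 6 cm), else ``1 - N_s / N_max``."""
    e1, e2 = pair
    for e in (e1, e2):
        if e.modality != "eda" or e.is_reference:
            raise RoleError("eda_cost needs EDA measurement electrodes")
    d = math.dist(e1.center, e2.center)
    r = e1.radius
    n_s = eda_gland_count(d, r, density)
    if n_s <= MIN_GLANDS or d > EDA_RECOMMENDED_DISTANCE:
        return 1.0
    n_max = eda_gland_count(EDA_RECOMMENDED_DISTANCE, EDA_ELECTRODE_RADIUS, density)
    return 1.0 - n_s / n_max


def ecg_cost(pair: Sequence[Electrode], model: ForearmModel,
             capture_radius: float = ECG_CAPTURE_RADIUS) -> float:
    """ECG cost via nearest-candidate matching.

    The placed pair is assigned to the candidate keypoint pair minimizing the
    summed centre-to-keypoint distance (over both assignments).  Within the
    capture budget (``2 * capture_radius`` summed) the cost is
    ``1 - SNR/SNR_max`` of that candidate; beyond it, 1.
    """
    e1, e2 = pair
    for e in (e1, e2):
        if e.modality != "ecg" or e.is_reference:
            raise RoleError("ecg_cost needs ECG measurement electrodes")
    if not model.ecg_pairs:
        raise ConfigError("anatomical model has no ECG candidate pairs")
    best_d = math.inf
    best_snr = 0.0
    for cand in model.ecg_pairs.values():
        k1, k2 = cand.points
        d = min(math.dist(e1.center, k1) + math.dist(e2.center, k2),
                math.dist(e1.center, k2) + math.dist(e2.center, k1))
        if d < best_d:
            best_d, best_snr = d, cand.rel_snr
    if best_d > 2.0 * capture_radius:
        return 1.0
    snr_max = max(c.rel_snr for c in model.ecg_pairs.values())
    return 1.0 - best_snr / snr_max


_CIRCLE_SAMPLES = 32
_CIRCLE_ANGLES = np.linspace(0.0, 2.0 * math.pi, _CIRCLE_SAMPLES, endpoint=False)


def layout_hull_area(layout: Layout) -> float:
    """Footprint of a layout: area of the convex hull of the measurement
    electrode *disks* (mm^2).

    The disks, not just the centres, define the hull: the device substrate
    must cover the electrodes, and a centres-only hull would rate a
    collinear strip of electrodes as having zero area.  With equal radii
    the disk hull is exact (Minkowski sum: centres-hull area + perimeter*r
    + pi*r^2, degenerating to a capsule/disk for collinear or single
    points); with mixed radii each circle is sampled at 32 boundary points
    and Graham-scanned, underestimating by < 0.7%, which cancels in the
    baseline-normalized ratio.
    """
    meas = layout.measurement
    if not meas:
        return 0.0
    radii = {e.radius for e in meas}
    if len(radii) == 1:
        r = radii.pop()
        centers = np.array([e.center for e in meas])
        try:
            hull = convex_hull(centers)
        except DegenerateGeometryError:
            # collinear or coincident centres: capsule around the two
            # extreme points (a single disk when they coincide)
            d = max(math.dist(a.center, b.center)
                    for a in meas for b in meas)
            return math.pi * r * r + 2.0 * r * d
        per = float(np.sum(np.hypot(*(np.roll(hull, -1, axis=0) - hull).T)))
        return polygon_area(hull) + per * r + math.pi * r * r
    boundary = np.concatenate([
        np.column_stack((e.center[0] + e.radius * np.cos(_CIRCLE_ANGLES),
                         e.center[1] + e.radius * np.sin(_CIRCLE_ANGLES)))
        for e in meas
    ])
    return convex_hull_area(boundary)


def area_cost(layout: Layout, baseline_area: float | None) -> tuple[float, float]:
    """(area ratio, hull area).  The ratio normalizes the disk-hull
    footprint by the baseline layout's; without a baseline the ratio is 0
    and only the absolute hull area is reported."""
    hull = layout_hull_area(layout)
    if baseline_area is None or baseline_area <= 0:
        return 0.0, hull
    return hull / baseline_area, hull


def lower_bound_penalty(cost: float, bound: float, softness: float) -> float:
    """Exponential penalty ``p * (exp(max(O_k - l_k, 0)) - 1)``; zero while
    the modality cost stays at or below its ceiling."""
    return softness * (math.exp(max(cost - bound, 0.0)) - 1.0)


# ---------------------------------------------------------------------------
# layout construction

def measurement_roster(muscles: Sequence[str], modalities: Iterable[str],
                       ) -> tuple[Electrode, ...]:
    """Unpositioned measurement-electrode roster for a configuration.

    Two EMG electrodes per selected muscle, two EDA, two ECG; placeholder
    centres at the origin.
    """
    modalities = frozenset(modalities)
    unknown = modalities - set(MODALITIES)
    if unknown:
        raise ConfigError(f"unknown modalities: {sorted(unknown)}")
    if not modalities:
        raise ConfigError("at least one modality must be enabled")
    if "emg" in modalities and not muscles:
        raise ConfigError("EMG enabled but no muscle selected")
    roster: list[Electrode] = []
    if "emg" in modalities:
        for mid in muscles:
            for member in "AB":
                roster.append(Electrode((0.0, 0.0), EMG_ELECTRODE_RADIUS,
                                        "emg", member=member, muscle=mid))
    if "eda" in modalities:
        for member in "AB":
            roster.append(Electrode((0.0, 0.0), EDA_ELECTRODE_RADIUS,
                                    "eda", member=member))
    if "ecg" in modalities:
        for member in "AB":
            roster.append(Electrode((0.0, 0.0), EMG_ELECTRODE_RADIUS,
                                    "ecg", member=member))
    return tuple(roster)


def _reference_electrodes(modalities: Iterable[str], model: ForearmModel,
                          ) -> tuple[Electrode, ...]:
    """At most two reference electrodes (shared EMG ref, ECG ref), placed
    off the forearm past the elbow; excluded from all geometric rules."""
    modalities = frozenset(modalities)
    refs = []
    off_v = model.length + 50.0
    if "emg" in modalities:
        refs.append(Electrode((-15.0, off_v), EMG_ELECTRODE_RADIUS, "emg",
                              member="R", is_reference=True))
    if "ecg" in modalities:
        refs.append(Electrode((15.0, off_v), EMG_ELECTRODE_RADIUS, "ecg",
                              member="R", is_reference=True))
    return tuple(refs)


def build_baseline_layout(model: ForearmModel, muscles: Sequence[str] = (),
                          modalities: Iterable[str] = ("emg",)) -> Layout:
    """Rule-based baseline: the placement the published guides prescribe.

    EMG pairs sit exactly on their muscle keypoints, the EDA pair sits on the
    template's EDA anchor with the recommended 6 cm spacing along the arm
    axis, and the ECG pair occupies the best candidate keypoints.  Under the
    default template every enabled modality scores 0, so the baseline has
    predicted quality 1 and defines the reference area.
    """
    from .optimize import validate_layout  # local import to avoid a cycle

    modalities = frozenset(modalities)
    electrodes: list[Electrode] = []
    if "emg" in modalities:
        if not muscles:
            raise ConfigError("EMG enabled but no muscle selected")
        for mid in muscles:
            if mid not in model.muscles:
                raise ConfigError(f"muscle {mid} not in the anatomical model")
            k1, k2 = model.muscles[mid].segment
            electrodes.append(Electrode(k1, EMG_ELECTRODE_RADIUS, "emg",
                                        member="A", muscle=mid))
            electrodes.append(Electrode(k2, EMG_ELECTRODE_RADIUS, "emg",
                                        member="B", muscle=mid))
    if "eda" in modalities:
        au, av = model.eda_anchor
        half = EDA_RECOMMENDED_DISTANCE / 2.0
        electrodes.append(Electrode((au, av - half), EDA_ELECTRODE_RADIUS,
                                    "eda", member="A"))
        electrodes.append(Electrode((au, av + half), EDA_ELECTRODE_RADIUS,
                                    "eda", member="B"))
    if "ecg" in modalities:
        best = max(model.ecg_pairs.values(), key=lambda c: c.rel_snr)
        k1, k2 = best.points
        electrodes.append(Electrode(k1, EMG_ELECTRODE_RADIUS, "ecg", member="A"))
        electrodes.append(Electrode(k2, EMG_ELECTRODE_RADIUS, "ecg", member="B"))
    layout = Layout(tuple(electrodes) + _reference_electrodes(modalities, model))
    ok, violations = validate_layout(layout, [model.outline])
    if not ok:
        raise TemplateError(f"baseline layout infeasible under this template: {violations}")
    return layout


def baseline_area(model: ForearmModel, muscles: Sequence[str] = (),
                  modalities: Iterable[str] = ("emg",)) -> float:
    """Disk-hull footprint of the rule-based baseline layout (mm^2), the
    normalization reference for the area cost."""
    return layout_hull_area(build_baseline_layout(model, muscles, modalities))


# ---------------------------------------------------------------------------
# global objective

def combine_objective(modality_costs: Mapping[str, float], area_ratio: float,
                      weights: Weights, scheme: str = "weights",
                      bounds: LowerBounds | None = None,
                      ) -> tuple[float, dict[str, float], float]:
    """Combine per-modality costs into (objective, penalties, quality).

    Schemes: ``weights`` (weighted sum, enabled modality weights must sum to
    1), ``bounds`` (penalties only, modality weights ignored), ``hybrid``
    (both).  The reported quality excludes the area term: it is the
    complement of the weighted (or, under ``bounds``, unweighted) mean of
    the enabled modality costs.
    """
    if scheme not in ("weights", "bounds", "hybrid"):
        raise ConfigError(f"unknown scheme {scheme!r}")
    enabled = sorted(modality_costs)
    if not enabled:
        raise ConfigError("no modality costs supplied")
    penalties: dict[str, float] = {}
    if scheme in ("bounds", "hybrid"):
        if bounds is None:
            raise ConfigError(f"scheme {scheme!r} requires lower bounds")
        penalties = {
            k: lower_bound_penalty(modality_costs[k], bounds.bound(k), bounds.softness)
            for k in enabled
        }
    objective = weights.area * area_ratio + sum(penalties.values())
    if scheme in ("weights", "hybrid"):
        wsum = sum(weights.modality_weight(k) for k in enabled)
        if abs(wsum - 1.0) > 1e-9:
            raise ConfigError(
                f"weights of enabled modalities must sum to 1, got {wsum}")
        objective += sum(weights.modality_weight(k) * modality_costs[k] for k in enabled)
        quality = 1.0 - sum(weights.modality_weight(k) * modality_costs[k]
                            for k in enabled) / wsum
    else:
        quality = 1.0 - sum(modality_costs.values()) / len(enabled)
    return objective, penalties, quality


def global_objective(layout: Layout, model: ForearmModel, weights: Weights,
                     bounds: LowerBounds | None = None,
                     baseline_area: float | None = None,
                     scheme: str = "weights") -> CostBreakdown:
    """Score a layout: per-modality costs, area ratio, penalties and the
    scheme-dependent global objective."""
    modality_costs: dict[str, float] = {}
    muscle_costs: dict[str, float] = {}
    o_emg = o_eda = o_ecg = None
    if "emg" in layout.modalities:
        o_emg, muscle_costs = emg_total(layout, model, alpha=weights.alpha)
        modality_costs["emg"] = o_emg
    if "eda" in layout.modalities:
        o_eda = eda_cost(layout.modality_pair("eda"), model.gland_density_per_mm2)
        modality_costs["eda"] = o_eda
    if "ecg" in layout.modalities:
        o_ecg = ecg_cost(layout.modality_pair("ecg"), model)
        modality_costs["ecg"] = o_ecg
    ratio, hull = area_cost(layout, baseline_area)
    objective, penalties, quality = combine_objective(
        modality_costs, ratio, weights, scheme=scheme, bounds=bounds)
    return CostBreakdown(
        muscle_costs=muscle_costs, emg=o_emg, eda=o_eda, ecg=o_ecg,
        hull_area=hull, baseline_area=baseline_area, area_ratio=ratio,
        penalties=penalties, objective=objective, quality=quality,
    )
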