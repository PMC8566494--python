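"""Anatomical model of the anterior forearm.

A normalized :class:`AnatomicalTemplate` describes the flattened anterior
forearm surface in ``(u, v)`` coordinates with ``u`` in [0, 1] across the
width (0 = ulnar edge, 1 = radial edge) and ``v`` in [0, 1] along the length
(0 = wrist crease, 1 = elbow crease).  :func:`build_forearm_model` scales it
with four body measurements into millimetre coordinates: origin at the
wrist-crease midpoint, +v toward the elbow, +u toward the radial side.  The
v axis is scaled by the forearm length; the u axis by the local width,
interpolated linearly wrist -> mid -> elbow.

The default template is a SYNTHETIC stand-in: muscle lines, innervation
zones and ECG keypoints are plausible constructions in the spirit of the
published placement guides (SENIAM-style keypoints, forearm three-electrode
ECG maps), not digitized anatomy.  Real coordinates can be substituted via
the JSON/YAML template file without code changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import MeasurementError, TemplateError
from .geometry import point_in_polygon

__all__ = [
    "MUSCLES",
    "ForearmMeasurements",
    "MuscleTemplate",
    "EcgPairTemplate",
    "AnatomicalTemplate",
    "MuscleGeometry",
    "EcgPair",
    "ForearmModel",
    "build_forearm_model",
    "default_template",
    "default_measurements",
    "load_template",
    "save_template",
]

#: The five supported anterior-forearm muscles: Flexor Carpi Radialis,
#: Brachioradialis, Palmaris Longus, Pronator Quadratus, Flexor Carpi Ulnaris.
MUSCLES = ("FCR", "BR", "PL", "PQ", "FCU")

TEMPLATE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ForearmMeasurements:
    """Four forearm measurements, all in mm.

    length
        f1: wrist crease to elbow crease.
    wrist_width, mid_width, elbow_width
        f2, f3, f4: widths of the unrolled anterior surface at the wrist,
        mid-forearm and elbow end.
    """

    length: float
    wrist_width: float
    mid_width: float
    elbow_width: float

    def __post_init__(self) -> None:
        vals = (self.length, self.wrist_width, self.mid_width, self.elbow_width)
        if not all(np.isfinite(vals)) or any(x <= 0 for x in vals):
            raise MeasurementError(f"measurements must be strictly positive, got {vals}")
        if self.length <= self.wrist_width:
            raise MeasurementError(
                f"forearm length ({self.length} mm) must exceed wrist width "
                f"({self.wrist_width} mm)"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.length, self.wrist_width, self.mid_width, self.elbow_width)


@dataclass(frozen=True)
class MuscleTemplate:
    """One muscle line in normalized coordinates: two placement keypoints and
    1+ innervation-zone polygons lying on the line."""

    id: str
    k1: tuple[float, float]
    k2: tuple[float, float]
    iz: tuple[tuple[tuple[float, float], ...], ...] = ()


@dataclass(frozen=True)
class EcgPairTemplate:
    """A candidate ECG electrode pair with its SNR relative to the best pair."""

    id: str
    k1: tuple[float, float]
    k2: tuple[float, float]
    rel_snr: float


@dataclass(frozen=True)
class AnatomicalTemplate:
    version: int
    outline: tuple[tuple[float, float], ...]
    muscles: tuple[MuscleTemplate, ...]
    ecg_pairs: tuple[EcgPairTemplate, ...]
    eda_anchor: tuple[float, float]
    gland_density_per_mm2: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.outline) < 3:
            raise TemplateError("outline needs at least 3 vertices")
        for pt in self._all_points():
            if not (-1e-9 <= pt[0] <= 1 + 1e-9 and -1e-9 <= pt[1] <= 1 + 1e-9):
                raise TemplateError(f"template element outside the unit square: {pt}")
        ids = [m.id for m in self.muscles]
        if len(set(ids)) != len(ids):
            raise TemplateError("duplicate muscle ids")
        unknown = set(ids) - set(MUSCLES)
        if unknown:
            raise TemplateError(f"unknown muscle ids: {sorted(unknown)}")
        for m in self.muscles:
            if m.k1 == m.k2:
                raise TemplateError(f"muscle {m.id}: keypoints coincide")
        for p in self.ecg_pairs:
            if not 0 < p.rel_snr <= 1:
                raise TemplateError(f"ECG pair {p.id}: rel_snr must be in (0, 1]")
        n_best = sum(1 for p in self.ecg_pairs if abs(p.rel_snr - 1.0) < 1e-12)
        if self.ecg_pairs and n_best != 1:
            raise TemplateError("exactly one ECG pair must have relative SNR 1")
        if self.gland_density_per_mm2 <= 0:
            raise TemplateError("gland density must be positive")

    def _all_points(self):
        for pt in self.outline:
            yield pt
        for m in self.muscles:
            yield m.k1
            yield m.k2
            for poly in m.iz:
                yield from poly
        for p in self.ecg_pairs:
            yield p.k1
            yield p.k2
        yield self.eda_anchor

    def fingerprint(self) -> str:
        """Stable short hash of the template contents."""
        blob = json.dumps(_template_to_dict(self), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class MuscleGeometry:
    """A muscle line in mm: segment endpoints (distal, proximal) and IZ polygons."""

    id: str
    segment: tuple[tuple[float, float], tuple[float, float]]
    iz: tuple[tuple[tuple[float, float], ...], ...]


@dataclass(frozen=True)
class EcgPair:
    id: str
    points: tuple[tuple[float, float], tuple[float, float]]
    rel_snr: float


@dataclass(frozen=True)
class ForearmModel:
    """Scaled anatomical scene in mm coordinates."""

    outline: tuple[tuple[float, float], ...]
    muscles: Mapping[str, MuscleGeometry]
    ecg_pairs: Mapping[str, EcgPair]
    eda_anchor: tuple[float, float]
    gland_density_per_mm2: float
    measurements: ForearmMeasurements
    template_fingerprint: str

    @property
    def length(self) -> float:
        return self.measurements.length

    @property
    def max_width(self) -> float:
        return max(self.measurements.wrist_width, self.measurements.mid_width,
                   self.measurements.elbow_width)


def _width_at(F: ForearmMeasurements, v: float) -> float:
    """Anterior-surface width at normalized length fraction v, piecewise
    linear through (0, f2), (0.5, f3), (1, f4)."""
    if v <= 0.5:
        return F.wrist_width + (F.mid_width - F.wrist_width) * (v / 0.5)
    return F.mid_width + (F.elbow_width - F.mid_width) * ((v - 0.5) / 0.5)


def _scale_point(F: ForearmMeasurements, pt: Sequence[float]) -> tuple[float, float]:
    u, v = float(pt[0]), float(pt[1])
    return ((u - 0.5) * _width_at(F, v), v * F.length)


def build_forearm_model(F: ForearmMeasurements, template: AnatomicalTemplate) -> ForearmModel:
    """Scale a normalized template with forearm measurements into mm.

    The affine map is per-axis: v is multiplied by the forearm length and u
    is centred and multiplied by the local interpolated width, so the
    template midline (u = 0.5) maps to u_mm = 0.
    """
    template.validate()
    sp = lambda pt: _scale_point(F, pt)
    outline = tuple(sp(p) for p in template.outline)
    muscles = {
        m.id: MuscleGeometry(
            id=m.id,
            segment=(sp(m.k1), sp(m.k2)),
            iz=tuple(tuple(sp(p) for p in poly) for poly in m.iz),
        )
        for m in template.muscles
    }
    ecg = {
        p.id: EcgPair(id=p.id, points=(sp(p.k1), sp(p.k2)), rel_snr=p.rel_snr)
        for p in template.ecg_pairs
    }
    model = ForearmModel(
        outline=outline,
        muscles=muscles,
        ecg_pairs=ecg,
        eda_anchor=sp(template.eda_anchor),
        gland_density_per_mm2=template.gland_density_per_mm2,
        measurements=F,
        template_fingerprint=template.fingerprint(),
    )
    for mg in muscles.values():
        for p in mg.segment:
            if not point_in_polygon(p, outline, tol=1e-6):
                raise TemplateError(f"muscle {mg.id} keypoint {p} falls outside the outline")
    for pair in ecg.values():
        for p in pair.points:
            if not point_in_polygon(p, outline, tol=1e-6):
                raise TemplateError(f"ECG pair {pair.id} keypoint {p} falls outside the outline")
    return model


def default_measurements() -> ForearmMeasurements:
    """Demo forearm: 250 mm long, 55 / 70 / 85 mm wide at wrist / mid / elbow."""
    return ForearmMeasurements(250.0, 55.0, 70.0, 85.0)


def _iz_quad(k1, k2, frac: float, du: float = 0.05, dv: float = 0.015):
    """Small axis-aligned IZ quad centred at fraction ``frac`` along the line."""
    cu = k1[0] + frac * (k2[0] - k1[0])
    cv = k1[1] + frac * (k2[1] - k1[1])
    return (
        (cu - du, cv - dv),
        (cu + du, cv - dv),
        (cu + du, cv + dv),
        (cu - du, cv + dv),
    )


def default_template() -> AnatomicalTemplate:
    """Synthetic default template for the anterior forearm.

    Muscle keypoint placements follow the qualitative arrangement of the
    published guides (FCR/PL/FCU bellies in the proximal half, PQ distal near
    the wrist, BR along the proximal radial edge) with innervation zones
    mid-belly.  Three candidate ECG pairs span the forearm: the upper-forearm
    pair is the best (relative SNR 1), the mid-forearm pair is intermediate
    (0.6) and the wrist pair retains only a quarter of the best SNR (0.25).
    Sweat-gland density is 1.08 glands/mm^2 (108 per cm^2, the forearm
    value).
    """
    muscles = (
        MuscleTemplate("FCR", (0.68, 0.35), (0.66, 0.50),
                       iz=(_iz_quad((0.68, 0.35), (0.66, 0.50), 0.5),)),
        MuscleTemplate("BR", (0.85, 0.55), (0.82, 0.72),
                       iz=(_iz_quad((0.85, 0.55), (0.82, 0.72), 0.4),
                           _iz_quad((0.85, 0.55), (0.82, 0.72), 0.6))),
        MuscleTemplate("PL", (0.50, 0.30), (0.50, 0.44),
                       iz=(_iz_quad((0.50, 0.30), (0.50, 0.44), 0.5),)),
        MuscleTemplate("PQ", (0.45, 0.08), (0.48, 0.20),
                       iz=(_iz_quad((0.45, 0.08), (0.48, 0.20), 0.5),)),
        MuscleTemplate("FCU", (0.30, 0.35), (0.28, 0.50),
                       iz=(_iz_quad((0.30, 0.35), (0.28, 0.50), 0.5),)),
    )
    ecg_pairs = (
        EcgPairTemplate("upper", (0.35, 0.88), (0.65, 0.88), 1.0),
        EcgPairTemplate("center", (0.35, 0.50), (0.65, 0.50), 0.6),
        EcgPairTemplate("wrist", (0.40, 0.06), (0.60, 0.06), 0.25),
    )
    return AnatomicalTemplate(
        version=TEMPLATE_SCHEMA_VERSION,
        outline=((0.0, 0.0), (1.0, 0.0), (1.0, 0.5), (1.0, 1.0),
                 (0.0, 1.0), (0.0, 0.5)),
        muscles=muscles,
        ecg_pairs=ecg_pairs,
        eda_anchor=(0.20, 0.68),
        gland_density_per_mm2=1.08,
    )


# ---------------------------------------------------------------------------
# template file I/O (JSON or YAML, selected by extension)

def _template_to_dict(t: AnatomicalTemplate) -> dict:
    return {
        "version": t.version,
        "outline": [list(p) for p in t.outline],
        "muscles": [
            {
                "id": m.id,
                "k1": list(m.k1),
                "k2": list(m.k2),
                "iz": [[list(p) for p in poly] for poly in m.iz],
            }
            for m in t.muscles
        ],
        "ecg_pairs": [
            {"id": p.id, "k1": list(p.k1), "k2": list(p.k2), "rel_snr": p.rel_snr}
            for p in t.ecg_pairs
        ],
        "eda_anchor": list(t.eda_anchor),
        "gland_density_per_mm2": t.gland_density_per_mm2,
    }


def _template_from_dict(d: Mapping) -> AnatomicalTemplate:
    try:
        if int(d["version"]) != TEMPLATE_SCHEMA_VERSION:
            raise TemplateError(f"unsupported template version {d['version']}")
        return AnatomicalTemplate(
            version=int(d["version"]),
            outline=tuple((float(u), float(v)) for u, v in d["outline"]),
            muscles=tuple(
                MuscleTemplate(
                    id=str(m["id"]),
                    k1=(float(m["k1"][0]), float(m["k1"][1])),
                    k2=(float(m["k2"][0]), float(m["k2"][1])),
                    iz=tuple(
                        tuple((float(u), float(v)) for u, v in poly)
                        for poly in m.get("iz", [])
                    ),
                )
                for m in d["muscles"]
            ),
            ecg_pairs=tuple(
                EcgPairTemplate(
                    id=str(p["id"]),
                    k1=(float(p["k1"][0]), float(p["k1"][1])),
                    k2=(float(p["k2"][0]), float(p["k2"][1])),
                    rel_snr=float(p["rel_snr"]),
                )
                for p in d["ecg_pairs"]
            ),
            eda_anchor=(float(d["eda_anchor"][0]), float(d["eda_anchor"][1])),
            gland_density_per_mm2=float(d["gland_density_per_mm2"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise TemplateError(f"malformed template: {exc!r}") from exc


def save_template(template: AnatomicalTemplate, path: str | Path) -> None:
    path = Path(path)
    d = _template_to_dict(template)
    if path.suffix.lower() in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_template(path: str | Path) -> AnatomicalTemplate:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in {".yml", ".yaml"}:
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise TemplateError(f"cannot parse template file {path}: {exc}") from exc
    return _template_from_dict(d)
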