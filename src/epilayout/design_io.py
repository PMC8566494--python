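"""Design-file persistence (JSON) and SVG export.

A design file records everything needed to reproduce and re-score a
layout: schema version, forearm measurements, configuration (modalities,
muscles, weights, bounds, optimizer settings, seed), the electrode records
in mm, the cost breakdown and the template fingerprint.  Serialization is
canonical (sorted keys, fixed float repr), so identical designs produce
byte-identical files.

SVG export uses plain SVG 1.1 with 1 user unit = 1 mm and no transforms:
``layout`` mode draws the forearm outline with filled, labelled electrode
disks; ``stencil`` mode draws punch-hole circles only, for printing on a
transparent film.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

from .anatomy import ForearmMeasurements, ForearmModel
from .costs import CostBreakdown, Electrode, Layout, LowerBounds, Weights
from .errors import DesignFileError
from .optimize import Design, OptimizerConfig

__all__ = ["DESIGN_SCHEMA_VERSION", "save_design", "load_design",
           "design_to_dict", "design_from_dict", "export_svg"]

DESIGN_SCHEMA_VERSION = 1

_MODALITY_FILL = {"emg": "#d95f02", "eda": "#1b9e77", "ecg": "#7570b3"}


def _electrode_to_dict(e: Electrode) -> dict:
    return {
        "center": [e.center[0], e.center[1]],
        "radius": e.radius,
        "modality": e.modality,
        "member": e.member,
        "muscle": e.muscle,
        "is_reference": e.is_reference,
    }


def _electrode_from_dict(d: Mapping) -> Electrode:
    return Electrode(
        center=(float(d["center"][0]), float(d["center"][1])),
        radius=float(d["radius"]),
        modality=str(d["modality"]),
        member=str(d["member"]),
        muscle=None if d.get("muscle") is None else str(d["muscle"]),
        is_reference=bool(d["is_reference"]),
    )


def _cost_to_dict(c: CostBreakdown) -> dict:
    return {
        "muscle_costs": dict(c.muscle_costs),
        "emg": c.emg,
        "eda": c.eda,
        "ecg": c.ecg,
        "hull_area": c.hull_area,
        "baseline_area": c.baseline_area,
        "area_ratio": c.area_ratio,
        "penalties": dict(c.penalties),
        "objective": c.objective,
        "quality": c.quality,
    }


def _cost_from_dict(d: Mapping) -> CostBreakdown:
    return CostBreakdown(
        muscle_costs={str(k): float(v) for k, v in d["muscle_costs"].items()},
        emg=None if d["emg"] is None else float(d["emg"]),
        eda=None if d["eda"] is None else float(d["eda"]),
        ecg=None if d["ecg"] is None else float(d["ecg"]),
        hull_area=float(d["hull_area"]),
        baseline_area=None if d["baseline_area"] is None else float(d["baseline_area"]),
        area_ratio=float(d["area_ratio"]),
        penalties={str(k): float(v) for k, v in d["penalties"].items()},
        objective=float(d["objective"]),
        quality=float(d["quality"]),
    )


def design_to_dict(design: Design) -> dict:
    w = design.weights
    cfg = design.config
    return {
        "schema_version": DESIGN_SCHEMA_VERSION,
        "measurements": list(design.measurements),
        "modalities": list(design.modalities),
        "muscles": list(design.muscles),
        "weights": {"emg": w.emg, "eda": w.eda, "ecg": w.ecg,
                    "area": w.area, "alpha": w.alpha},
        "bounds": None if design.bounds is None else {
            "emg": design.bounds.emg, "eda": design.bounds.eda,
            "ecg": design.bounds.ecg, "softness": design.bounds.softness},
        "optimizer": {
            "t0": cfg.t0, "gamma": cfg.gamma, "candidates": cfg.candidates,
            "moves_per_temp": cfg.moves_per_temp, "step": cfg.step,
            "seed": cfg.seed, "min_spacing": cfg.min_spacing,
            "scheme": cfg.scheme, "max_init_attempts": cfg.max_init_attempts,
        },
        "electrodes": [_electrode_to_dict(e) for e in design.layout.electrodes],
        "cost": _cost_to_dict(design.cost),
        "template_fingerprint": design.template_fingerprint,
        "shape": None if design.shape is None else [list(p) for p in design.shape],
        "window_height": design.window_height,
    }


def design_from_dict(d: Mapping) -> Design:
    try:
        version = d["schema_version"]
        if version != DESIGN_SCHEMA_VERSION:
            raise DesignFileError(f"unsupported design schema version {version!r}")
        b = d["bounds"]
        opt = d["optimizer"]
        return Design(
            layout=Layout(tuple(_electrode_from_dict(e) for e in d["electrodes"])),
            cost=_cost_from_dict(d["cost"]),
            weights=Weights(**{k: float(v) for k, v in d["weights"].items()}),
            bounds=None if b is None else LowerBounds(
                emg=float(b["emg"]), eda=float(b["eda"]), ecg=float(b["ecg"]),
                softness=float(b["softness"])),
            config=OptimizerConfig(
                t0=float(opt["t0"]), gamma=float(opt["gamma"]),
                candidates=int(opt["candidates"]),
                moves_per_temp=None if opt["moves_per_temp"] is None
                else int(opt["moves_per_temp"]),
                step=float(opt["step"]), seed=int(opt["seed"]),
                min_spacing=float(opt["min_spacing"]), scheme=str(opt["scheme"]),
                max_init_attempts=int(opt["max_init_attempts"])),
            muscles=tuple(str(m) for m in d["muscles"]),
            modalities=tuple(str(m) for m in d["modalities"]),
            measurements=tuple(float(x) for x in d["measurements"]),  # type: ignore[arg-type]
            template_fingerprint=str(d["template_fingerprint"]),
            shape=None if d["shape"] is None
            else tuple((float(p[0]), float(p[1])) for p in d["shape"]),
            window_height=None if d.get("window_height") is None
            else float(d["window_height"]),
        )
    except DesignFileError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise DesignFileError(f"malformed design file: {exc!r}") from exc


def save_design(design: Design, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(design_to_dict(design), indent=2, sort_keys=True) + "\n")


def load_design(path: str | Path) -> Design:
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DesignFileError(
            f"cannot parse {path}: {exc.msg} at line {exc.lineno}, "
            f"column {exc.colno}") from exc
    if not isinstance(d, dict):
        raise DesignFileError(f"design file {path} is not a JSON object")
    return design_from_dict(d)


def design_measurements(design: Design) -> ForearmMeasurements:
    return ForearmMeasurements(*design.measurements)


# ---------------------------------------------------------------------------
# SVG export

def _svg_coords(model: ForearmModel, point) -> tuple[float, float]:
    """Map model mm coordinates to SVG user units (y grows downward; the
    wrist crease sits at the bottom of the document)."""
    half = model.max_width / 2.0
    return (point[0] + half, model.length - point[1])


def export_svg(design: Design, model: ForearmModel, mode: str,
               path: str | Path) -> None:
    """Write an SVG 1.1 file; 1 user unit = 1 mm, document size equals the
    forearm bounding box.

    ``layout``: forearm outline, muscle lines and filled electrode disks
    labelled by role.  ``stencil``: unfilled punch-hole circles at the
    measurement electrode locations only.
    """
    if mode not in ("layout", "stencil"):
        raise ValueError(f"mode must be 'layout' or 'stencil', got {mode!r}")
    width = model.max_width
    height = model.length
    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": f"{width}mm",
        "height": f"{height}mm",
        "viewBox": f"0 0 {width} {height}",
    })
    if mode == "layout":
        pts = " ".join(f"{x:.4f},{y:.4f}"
                       for x, y in (_svg_coords(model, p) for p in model.outline))
        ET.SubElement(svg, "polygon", {
            "points": pts, "fill": "#f7e8d8", "stroke": "#555",
            "stroke-width": "0.5"})
        for mg in model.muscles.values():
            (x1, y1), (x2, y2) = (_svg_coords(model, p) for p in mg.segment)
            ET.SubElement(svg, "line", {
                "x1": f"{x1:.4f}", "y1": f"{y1:.4f}",
                "x2": f"{x2:.4f}", "y2": f"{y2:.4f}",
                "stroke": "#b55", "stroke-width": "0.6",
                "stroke-dasharray": "2,2"})
    for e in design.layout.measurement:
        cx, cy = _svg_coords(model, e.center)
        attrs = {"cx": f"{cx:.6f}", "cy": f"{cy:.6f}", "r": f"{e.radius:.6f}"}
        if mode == "stencil":
            attrs.update({"fill": "none", "stroke": "#000", "stroke-width": "0.4"})
        else:
            attrs.update({"fill": _MODALITY_FILL[e.modality],
                          "fill-opacity": "0.85", "stroke": "#222",
                          "stroke-width": "0.3"})
        ET.SubElement(svg, "circle", attrs)
        if mode == "layout":
            label = e.muscle if e.modality == "emg" else e.modality.upper()
            text = ET.SubElement(svg, "text", {
                "x": f"{cx:.4f}", "y": f"{cy - e.radius - 1.0:.4f}",
                "font-size": "3", "text-anchor": "middle",
                "font-family": "sans-serif"})
            text.text = f"{label}/{e.member}"
    ET.ElementTree(svg).write(path, encoding="unicode", xml_declaration=True)
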