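"""Assemble the complete radial figure as one self-contained SVG document.

The document is drawn bottom-up: the recommended-band annulus, one arc and
label per measurement group, one closed polygon per time snapshot (older
snapshots first, in lightened strokes), one traffic-light circle per
(measurement, snapshot), and finally the de-collided measurement labels.
Everything is styled through presentation attributes — no <script>, no
<style>, no external references — so the file renders identically when
embedded in an article, a poster or another application.

Group arcs and labels are always drawn; measurement-label visibility is
the only optional layer, and toggling it never changes the polygon
geometry (the figure's shape is constant).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

from .data_model import HealthDataset, Snapshot, SnapshotMode, extract_snapshots, validate_dataset
from .layout import (
    LabelBox,
    build_angular_layout,
    compute_label_radius,
    estimate_label_box,
    place_labels,
    polar_to_canvas,
)
from .scales import GeometryConfig, Palette, classify_value, lighten, normalize_value, snapshot_color

__all__ = ["RenderOptions", "SvgDocument", "render_figure", "write_svg"]

SVG_NS = "http://www.w3.org/2000/svg"

BAND_FILL = "#dcebf5"
ARC_STROKE = "#666666"
SAMPLE_CIRCLE_RADIUS = 6.0
TEXT_FILL = "#222222"
FONT = "Helvetica, Arial, sans-serif"


@dataclass(frozen=True)
class RenderOptions:
    """What to render: which snapshots, which labels, which colors/geometry.

    ``snapshot_targets`` are sample indices (``by_index`` mode) or epoch
    timestamps (``nearest_time``), ordered oldest to newest; the last
    target is treated as the current snapshot (age 0) and older ones are
    drawn in progressively lighter colors.
    """

    snapshot_targets: Sequence[int] = (0,)
    mode: SnapshotMode | str = SnapshotMode.BY_INDEX
    show_measurement_labels: bool = True
    show_values_in_labels: bool = True
    palette: Palette = dc_field(default_factory=Palette)
    geometry: GeometryConfig = dc_field(default_factory=GeometryConfig)

    def __post_init__(self):
        if not self.snapshot_targets:
            raise ValueError("at least one snapshot target is required")


@dataclass(frozen=True)
class SvgDocument:
    """A finished, stand-alone SVG 1.1 document."""

    xml_text: str


def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s != "-0" else "0"


def _fmt_value(v: float) -> str:
    s = f"{v:g}"
    return s


def _circle_path(cx: float, cy: float, r: float) -> str:
    # Full circle as two arcs (a single path can hold both annulus rings).
    return (
        f"M {_fmt(cx)} {_fmt(cy - r)} "
        f"A {_fmt(r)} {_fmt(r)} 0 1 1 {_fmt(cx)} {_fmt(cy + r)} "
        f"A {_fmt(r)} {_fmt(r)} 0 1 1 {_fmt(cx)} {_fmt(cy - r)} Z"
    )


def _arc_path(g: GeometryConfig, radius: float, a0: float, a1: float) -> str:
    x0, y0 = polar_to_canvas(radius, a0, g)
    x1, y1 = polar_to_canvas(radius, a1, g)
    large = 1 if (a1 - a0) % (2 * math.pi) > math.pi else 0
    return (
        f"M {_fmt(x0)} {_fmt(y0)} "
        f"A {_fmt(radius)} {_fmt(radius)} 0 {large} 1 {_fmt(x1)} {_fmt(y1)}"
    )


def render_figure(ds: HealthDataset, opts: RenderOptions) -> SvgDocument:
    """Render a dataset into a self-contained SVG document.

    Raises ``ValueError`` on an empty or non-renderable dataset and
    propagates snapshot-extraction errors (ragged sample counts, indices
    out of range).
    """
    issues = validate_dataset(ds)
    if issues:
        raise ValueError("dataset is not renderable: " + "; ".join(issues))

    geo = opts.geometry
    pal = opts.palette
    cx, cy = geo.center
    layout = build_angular_layout(ds)
    snapshots = extract_snapshots(ds, opts.mode, list(opts.snapshot_targets))
    n_snap = len(snapshots)

    root = ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": _fmt(geo.width),
            "height": _fmt(geo.height),
            "viewBox": f"0 0 {_fmt(geo.width)} {_fmt(geo.height)}",
        },
    )

    # 1. Recommended-band annulus.
    ET.SubElement(
        root,
        "path",
        {
            "d": _circle_path(cx, cy, geo.r_band_outer)
            + " "
            + _circle_path(cx, cy, geo.r_band_inner),
            "fill": BAND_FILL,
            "fill-rule": "evenodd",
            "class": "recommended-band",
        },
    )

    # 2. Group sector arcs + group labels (always visible).
    arc_radius = geo.r_max + 8.0
    label_radius = geo.r_max + 28.0
    for group in ds.groups:
        a0, a1 = layout.group_arc[group.label]
        ET.SubElement(
            root,
            "path",
            {
                "d": _arc_path(geo, arc_radius, a0, a1),
                "fill": "none",
                "stroke": ARC_STROKE,
                "stroke-width": "2",
                "class": "group-arc",
            },
        )
        mid = (a0 + a1) / 2.0
        tx, ty = polar_to_canvas(label_radius, mid, geo)
        el = ET.SubElement(
            root,
            "text",
            {
                "x": _fmt(tx),
                "y": _fmt(ty),
                "text-anchor": "middle",
                "font-family": FONT,
                "font-size": _fmt(geo.label_line_height),
                "font-weight": "bold",
                "fill": TEXT_FILL,
                "class": "group-label",
            },
        )
        el.text = group.label

    # Normalized radius per (measurement, snapshot), in dataset order.
    radii: list[dict[tuple[str, str], float]] = []
    for snap in snapshots:
        radii.append(
            {
                key: normalize_value(snap.entries[key].value, m, geo)
                for g_, m in ds.iter_measurements()
                for key in [(g_.label, m.label)]
            }
        )

    # 3. One closed polygon per snapshot, oldest (lightest) first.
    for pos, snap in enumerate(snapshots):
        age = n_snap - 1 - pos
        points = []
        for g_, m in ds.iter_measurements():
            key = (g_.label, m.label)
            x, y = polar_to_canvas(radii[pos][key], layout.measurement_angle[key], geo)
            points.append(f"{_fmt(x)},{_fmt(y)}")
        ET.SubElement(
            root,
            "polygon",
            {
                "points": " ".join(points),
                "fill": "none",
                "stroke": lighten(pal.polygon, age, pal.lighten_step),
                "stroke-width": "2",
                "class": "snapshot-polygon",
            },
        )

    # 4. Traffic-light sample circles, oldest snapshot first so the newest on top.
    for pos, snap in enumerate(snapshots):
        age = n_snap - 1 - pos
        for g_, m in ds.iter_measurements():
            key = (g_.label, m.label)
            sample = snap.entries[key]
            x, y = polar_to_canvas(radii[pos][key], layout.measurement_angle[key], geo)
            ET.SubElement(
                root,
                "circle",
                {
                    "cx": _fmt(x),
                    "cy": _fmt(y),
                    "r": _fmt(SAMPLE_CIRCLE_RADIUS),
                    "fill": snapshot_color(classify_value(sample.value, m), age, pal),
                    "stroke": "#ffffff",
                    "stroke-width": "1",
                    "class": "sample",
                },
            )

    # 5. Measurement labels at collision-free positions.
    if opts.show_measurement_labels:
        newest = snapshots[-1]
        boxes: list[LabelBox] = []
        for g_, m in ds.iter_measurements():
            key = (g_.label, m.label)
            sample = newest.entries[key]
            if opts.show_values_in_labels:
                text = f"{m.label}: {_fmt_value(sample.value)}"
                if m.units:
                    text += f" {m.units}"
            else:
                text = m.label
            w, h = estimate_label_box(text, geo)
            anchor_r = compute_label_radius(
                [radii[pos][key] for pos in range(n_snap)], geo.label_margin
            )
            boxes.append(
                LabelBox(
                    text=text,
                    anchor_angle=layout.measurement_angle[key],
                    anchor_radius=anchor_r,
                    box_width=w,
                    box_height=h,
                )
            )
        for box in place_labels(boxes, geo):
            x, y = box.final_position  # type: ignore[misc]
            el = ET.SubElement(
                root,
                "text",
                {
                    "x": _fmt(x),
                    "y": _fmt(y),
                    "text-anchor": "start" if box.side == "right" else "end",
                    "dominant-baseline": "middle",
                    "font-family": FONT,
                    "font-size": _fmt(geo.label_line_height * 0.85),
                    "fill": TEXT_FILL,
                    "class": "measurement-label",
                },
            )
            el.text = box.text

    xml_text = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )
    return SvgDocument(xml_text=xml_text)


def write_svg(doc: SvgDocument, path: str | Path) -> None:
    """Write the document to disk as UTF-8, byte-identical to ``doc.xml_text``."""
    Path(path).write_bytes(doc.xml_text.encode("utf-8"))
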