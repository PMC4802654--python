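"""Angular layout, polar/canvas conversion and label placement.

The circle is divided into N + G equal slots: one per measurement plus one
spacer per group, so consecutive groups are separated by a blank sector.
Angle 0 points to 12 o'clock and increases clockwise; each measurement
sits at its slot's center.

Measurement labels are anchored at the measurement's angle, at a radius
equal to the largest sample radius plus a fixed margin — so a label can
never sit on top of its own sample circles, even when an out-of-range
value is pushed far out.  Collisions between labels are resolved by
quadrant stacking: within each canvas quadrant labels are processed from
the horizontal axis toward the vertical axis and shifted vertically (up in
the upper half, down in the lower) by the minimum amount that clears the
labels already placed on that side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .data_model import HealthDataset
from .scales import GeometryConfig

__all__ = [
    "AngularLayout",
    "LabelBox",
    "build_angular_layout",
    "polar_to_canvas",
    "compute_label_radius",
    "estimate_label_box",
    "place_labels",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class AngularLayout:
    """Slot assignment for one dataset.

    ``measurement_angle`` maps (group label, measurement label) to the slot
    center in radians; ``group_arc`` maps a group label to the (start, end)
    radians of its measurement slots, spacers excluded.
    """

    slot_angle: float
    measurement_angle: dict[tuple[str, str], float]
    group_arc: dict[str, tuple[float, float]]


@dataclass
class LabelBox:
    """A measurement label before/after de-collision.

    The anchor is polar (angle, radius); ``final_position`` is the canvas
    point of the text anchor after vertical shifting.  Right-side boxes
    extend rightward from the anchor, left-side boxes leftward; vertically
    the box is centered on the anchor.
    """

    text: str
    anchor_angle: float
    anchor_radius: float
    box_width: float
    box_height: float
    side: str = field(init=False, default="right")
    final_position: tuple[float, float] | None = None

    def __post_init__(self):
        # Anchors exactly on the vertical axis count as right by convention.
        s = math.sin(self.anchor_angle % TWO_PI)
        self.side = "right" if s >= -1e-12 else "left"

    def rect(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the placed box; requires final_position."""
        if self.final_position is None:
            raise ValueError("label not yet placed")
        x, y = self.final_position
        if self.side == "right":
            x0, x1 = x, x + self.box_width
        else:
            x0, x1 = x - self.box_width, x
        return (x0, y - self.box_height / 2.0, x1, y + self.box_height / 2.0)


def build_angular_layout(ds: HealthDataset) -> AngularLayout:
    """Assign each measurement an equal-width slot, with one spacer slot per group.

    Slots run in dataset order, clockwise from 12 o'clock; after each
    group's measurements one empty slot is skipped, so the total slot count
    is N measurements + G groups.
    """
    n = ds.n_measurements
    g_count = len(ds.groups)
    if n == 0:
        raise ValueError("cannot lay out an empty dataset")
    slot = TWO_PI / (n + g_count)
    measurement_angle: dict[tuple[str, str], float] = {}
    group_arc: dict[str, tuple[float, float]] = {}
    i = 0
    for group in ds.groups:
        start = i * slot
        for m in group.measurements:
            measurement_angle[(group.label, m.label)] = (i + 0.5) * slot
            i += 1
        group_arc[group.label] = (start, i * slot)
        i += 1  # spacer slot after every group
    return AngularLayout(
        slot_angle=slot, measurement_angle=measurement_angle, group_arc=group_arc
    )


def polar_to_canvas(
    radius: float, angle: float, g: GeometryConfig
) -> tuple[float, float]:
    """Convert (radius, clockwise angle from 12 o'clock) to canvas x, y.

    Canvas y grows downward, so angle 0 points toward smaller y.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    cx, cy = g.center
    return (cx + radius * math.sin(angle), cy - radius * math.cos(angle))


def compute_label_radius(sample_radii: list[float], margin: float) -> float:
    """Label anchor radius: the largest sample radius plus the margin."""
    if not sample_radii:
        raise ValueError("sample_radii must be non-empty")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    return max(sample_radii) + margin


def estimate_label_box(text: str, g: GeometryConfig) -> tuple[float, float]:
    """Deterministic text-box estimate from fixed per-character metrics.

    Width is the longest line's character count times ``label_char_width``;
    height is the line count times ``label_line_height``.  No font engine
    is consulted, so estimates are identical on every platform.
    """
    if not text:
        raise ValueError("label text must be non-empty")
    lines = text.split("\n")
    width = max(len(line) for line in lines) * g.label_char_width
    height = len(lines) * g.label_line_height
    return (width, height)


def _axis_distance(angle: float) -> float:
    """Angular distance from the horizontal (3 o'clock / 9 o'clock) axis."""
    a = angle % TWO_PI
    return min(abs(a - math.pi / 2), abs(a - 3 * math.pi / 2))


def place_labels(boxes: list[LabelBox], g: GeometryConfig) -> list[LabelBox]:
    """Resolve label collisions by quadrant stacking; sets final_position.

    Each box starts at its polar anchor.  Per canvas side, boxes are
    processed outward from the horizontal axis (ties broken by input
    order) and shifted vertically — up in the upper half, down in the
    lower — by the minimum amount giving every previously placed box on
    that side a vertical center gap of at least the mean box height plus
    ``label_margin``.  Horizontal positions never change, and the vertical
    order within a quadrant is preserved.  Returns the input list.
    """
    order = sorted(
        range(len(boxes)), key=lambda i: (_axis_distance(boxes[i].anchor_angle), i)
    )
    placed: dict[str, list[LabelBox]] = {"left": [], "right": []}
    for i in order:
        box = boxes[i]
        x, y = polar_to_canvas(box.anchor_radius, box.anchor_angle, g)
        upward = math.cos(box.anchor_angle % TWO_PI) >= 0  # upper half shifts up
        same_side = placed[box.side]
        moved = True
        while moved:
            moved = False
            for other in same_side:
                oy = other.final_position[1]  # type: ignore[index]
                gap_needed = (box.box_height + other.box_height) / 2.0 + g.label_margin
                if abs(y - oy) < gap_needed - 1e-9:
                    y = oy - gap_needed if upward else oy + gap_needed
                    moved = True
        if y - box.box_height / 2.0 < 0 or y + box.box_height / 2.0 > g.height:
            raise ValueError(
                f"label {box.text!r} shifted off the canvas; enlarge the canvas "
                "or hide measurement labels"
            )
        box.final_position = (x, y)
        same_side.append(box)
    return boxes


def rects_overlap(
    a: tuple[float, float, float, float], b: tuple[float, float, float, float]
) -> bool:
    """Strict rectangle intersection (shared edges do not count)."""
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]
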