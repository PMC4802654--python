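"""Value-to-radius normalization and traffic-light status coding.

The figure places each sample on a radius so that the recommended range
[rec_min, rec_max] maps linearly onto a fixed annulus (the recommended
band).  Outside the band the same pixels-per-unit slope continues, clamped
to the plottable ring [r_min, r_max], so out-of-range values sit visibly
inside or outside the band.  Larger values always plot at larger radius.

Statuses follow a traffic-light convention: green for values within the
recommended range, yellow for values in a declared warning zone, red once
a critical threshold is passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from .data_model import Measurement

__all__ = [
    "GeometryConfig",
    "Status",
    "Palette",
    "normalize_value",
    "classify_value",
    "snapshot_color",
    "lighten",
]


@dataclass(frozen=True)
class GeometryConfig:
    """Canvas size and the radii that define the plottable space.

    ``r_band_inner``/``r_band_outer`` bound the recommended-band annulus;
    ``r_min``/``r_max`` clamp the plottable ring.  ``label_margin`` is the
    margin added to the largest sample radius when anchoring a measurement
    label; ``label_char_width``/``label_line_height`` are the fixed text
    metrics used to estimate label boxes (no font engine is consulted).
    All lengths are canvas pixels.
    """

    width: float = 1200.0
    height: float = 1200.0
    r_min: float = 120.0
    r_band_inner: float = 280.0
    r_band_outer: float = 380.0
    r_max: float = 480.0
    label_margin: float = 12.0
    label_line_height: float = 14.0
    label_char_width: float = 7.0

    def __post_init__(self):
        if not 0 < self.r_min < self.r_band_inner < self.r_band_outer < self.r_max:
            raise ValueError(
                "radii must satisfy 0 < r_min < r_band_inner < r_band_outer < r_max, "
                f"got {self.r_min}, {self.r_band_inner}, {self.r_band_outer}, {self.r_max}"
            )
        if self.r_max > min(self.width, self.height) / 2:
            raise ValueError(
                f"r_max ({self.r_max}) exceeds half the canvas "
                f"({min(self.width, self.height) / 2})"
            )
        if self.label_margin < 0:
            raise ValueError("label_margin must be >= 0")

    @property
    def center(self) -> tuple[float, float]:
        return (self.width / 2.0, self.height / 2.0)


class Status(IntEnum):
    """Traffic-light severity, ordered normal < warning < critical."""

    NORMAL = 0
    WARNING = 1
    CRITICAL = 2


@dataclass(frozen=True)
class Palette:
    """Status colors plus the per-age-step whitening fraction for older snapshots."""

    normal: str = "#2ca25f"
    warning: str = "#f1c40f"
    critical: str = "#e74c3c"
    polygon: str = "#444444"
    lighten_step: float = 0.35

    def __post_init__(self):
        for c in (self.normal, self.warning, self.critical, self.polygon):
            _parse_hex(c)
        if not 0 <= self.lighten_step < 1:
            raise ValueError(f"lighten_step must be in [0, 1), got {self.lighten_step}")

    def color_for(self, status: Status) -> str:
        return {
            Status.NORMAL: self.normal,
            Status.WARNING: self.warning,
            Status.CRITICAL: self.critical,
        }[status]


def normalize_value(value: float, m: Measurement, g: GeometryConfig) -> float:
    """Map a measurement value to a radius in pixels.

    Piecewise-linear and monotone non-decreasing: rec_min lands on the
    band's inner radius, rec_max on its outer radius, the interior linearly
    in between; outside the band the same slope continues until clamped to
    [r_min, r_max].
    """
    slope = (g.r_band_outer - g.r_band_inner) / (m.rec_max - m.rec_min)
    r = g.r_band_inner + (value - m.rec_min) * slope
    return min(max(r, g.r_min), g.r_max)


def classify_value(value: float, m: Measurement) -> Status:
    """Assign a traffic-light status to a value.

    The recommended interval is closed (a value exactly at a bound is
    normal); a value at a warning bound is warning.  When no warning bound
    exists on the violated side, any excursion is critical.
    """
    if m.rec_min <= value <= m.rec_max:
        return Status.NORMAL
    if value < m.rec_min:
        if m.warn_min is not None and value >= m.warn_min:
            return Status.WARNING
        return Status.CRITICAL
    if m.warn_max is not None and value <= m.warn_max:
        return Status.WARNING
    return Status.CRITICAL


def _parse_hex(color: str) -> tuple[int, int, int]:
    if len(color) != 7 or not color.startswith("#"):
        raise ValueError(f"expected a 6-digit hex color like #rrggbb, got {color!r}")
    return tuple(int(color[i : i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]


def lighten(color: str, age: int, step: float) -> str:
    """Whiten a hex color by ``step`` per age unit, channel-wise linear mixing.

    Age 0 returns the color unchanged; each further step moves every RGB
    channel ``step`` of its remaining distance toward 255, so channel
    c -> 255 - (255 - c) * (1 - step)^age.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    r, g, b = _parse_hex(color)
    keep = (1.0 - step) ** age
    mixed = (round(255.0 - (255.0 - c) * keep) for c in (r, g, b))
    return "#" + "".join(f"{c:02x}" for c in mixed)


def snapshot_color(status: Status, age: int, p: Palette) -> str:
    """Color for a sample circle: the status color, whitened with snapshot age.

    Age 0 is the most recent rendered snapshot; older snapshots get
    progressively lighter so overlapping time points stay distinguishable.
    """
    return lighten(p.color_for(status), age, p.lighten_step)
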