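"""Seeded synthetic datasets: a modeled coaching-program patient and a minimal example.

The modeled patient covers nine categories of health and wellness —
blood pressure, physical activity, body composition, sleep, fitness,
laboratory tests, nutrition, drug use and emotional wellbeing — the kind
of mixed clinical/self-tracking profile a health-coaching program
monitors.  Snapshot 1 draws each value uniformly around (and partly
outside) its recommended range; each later snapshot moves values toward
the band center by an ``improvement`` fraction plus small noise,
emulating a person improving through coaching.  Generation is a pure
function of the spec: the same seed always yields the same dataset.

The reference ranges below are conventional adult values included purely
as test scaffolding; they carry no clinical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import HealthDataset, Measurement, MeasurementGroup, Sample

__all__ = ["FixtureSpec", "generate_modeled_patient", "generate_minimal_example", "REFERENCE_RANGES"]

# The two example sampling times (GMT): 2015-01-09 10:10:24 and 2015-02-12 12:05:20.
T0 = 1420798224
T1 = 1423742720

# label, units, rec_min, rec_max, warn_min (None = one-sided), warn_max
# Sources: WHO/AHA vital-sign tables, Nordic lab reference intervals, and
# common 0-10 / 0-100 coaching questionnaire scales.
REFERENCE_RANGES: dict[str, list[tuple[str, str, float, float, float | None, float | None]]] = {
    "Blood pressure": [
        ("Systolic", "mmHg", 90, 120, 80, 140),
        ("Diastolic", "mmHg", 60, 80, 50, 90),
    ],
    "Physical activity": [
        ("Weekly active days", "days", 3, 7, 2, None),
        ("Steps per day", "steps", 7000, 12000, 5000, 15000),
    ],
    "Body composition": [
        ("BMI", "kg/m2", 18.5, 25, 17, 30),
        ("Waist diameter", "cm", 70, 94, 60, 102),
        ("Fat percentage", "%", 10, 20, 8, 28),
    ],
    "Sleep": [
        ("Time in bed", "h", 7, 9, 6, 10),
        ("Time asleep", "h", 6.5, 8.5, 6, 9.5),
    ],
    "Fitness": [
        ("Resting heart rate", "bpm", 50, 70, 40, 80),
        ("Fitness index", "mL/kg/min", 35, 50, 28, None),
        ("Muscular force", "score", 60, 100, 40, None),
        ("Muscular endurance", "score", 60, 100, 40, None),
        ("Balance", "score", 60, 100, 40, None),
    ],
    "Lab Tests": [
        ("Hemoglobin", "g/L", 117, 155, 100, 170),
        ("fB-Gluc", "mmol/L", 4.0, 6.0, 3.5, 6.9),
        ("Cholesterol", "mmol/L", 3.3, 5.0, 2.5, 6.2),
        ("HDL", "mmol/L", 1.0, 2.5, 0.8, None),
        ("LDL", "mmol/L", 1.2, 3.0, 1.0, 4.1),
        ("Triglycerides", "mmol/L", 0.45, 1.7, 0.3, 2.2),
    ],
    "Nutrition": [
        ("Meal regularity", "score", 6, 10, 4, None),
        ("Vegetables and fruits", "score", 6, 10, 4, None),
        ("Sugar intake", "score", 0, 4, None, 6),
        ("Fat quality", "score", 6, 10, 4, None),
        ("Fiber intake", "g/day", 25, 40, 15, 50),
        ("Salt intake", "g/day", 0, 5, None, 7.5),
    ],
    "Drugs": [
        ("Tobacco", "cigarettes/day", 0, 1, None, 5),
        ("Alcohol", "units/week", 0, 7, None, 14),
        ("Drug abuse", "score", 0, 1, None, 2),
        ("Medication abuse", "score", 0, 1, None, 2),
    ],
    "Emotional wellbeing": [
        ("Depression level", "score", 0, 9, None, 18),
        ("Stress level", "score", 0, 3, None, 6),
        ("Stress recovery", "score", 60, 100, 40, None),
        ("Optimism", "score", 60, 100, 40, None),
    ],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the modeled-patient generator.

    ``improvement`` is the fraction by which each later snapshot closes
    the gap between a value and its band center (0 = no coaching effect,
    1 = jump straight to the center); 0.5 reflects the partial
    before/after-coaching improvement the fixture emulates.
    """

    seed: int = 0
    n_snapshots: int = 2
    improvement: float = 0.5
    include_warning_ranges: bool = True

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")
        if not 0 <= self.improvement <= 1:
            raise ValueError("improvement must be in [0, 1]")


def generate_modeled_patient(spec: FixtureSpec = FixtureSpec()) -> HealthDataset:
    """Generate the nine-group modeled patient with ``n_snapshots`` samples each.

    All measurements share the same strictly increasing timestamps, so
    index-based and nearest-time snapshot extraction agree on the result.
    First-snapshot values are uniform over the recommended range extended
    by 30 % of its width on both sides; later snapshots contract toward
    the band center by ``improvement`` with ~2 %-of-range Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    step = T1 - T0
    timestamps = [T0 + k * step for k in range(spec.n_snapshots)]

    groups = []
    for group_label, rows in REFERENCE_RANGES.items():
        measurements = []
        for label, units, rec_min, rec_max, warn_min, warn_max in rows:
            span = rec_max - rec_min
            center = (rec_min + rec_max) / 2.0
            value = rng.uniform(rec_min - 0.3 * span, rec_max + 0.3 * span)
            samples = []
            for k, ts in enumerate(timestamps):
                if k > 0:
                    noise = rng.normal(0.0, 0.02 * span)
                    value = value + spec.improvement * (center - value) + noise
                samples.append(Sample(timestamp=ts, value=round(float(value), 4)))
            measurements.append(
                Measurement(
                    label=label,
                    units=units,
                    rec_min=float(rec_min),
                    rec_max=float(rec_max),
                    warn_min=float(warn_min)
                    if (spec.include_warning_ranges and warn_min is not None)
                    else None,
                    warn_max=float(warn_max)
                    if (spec.include_warning_ranges and warn_max is not None)
                    else None,
                    samples=tuple(samples),
                )
            )
        groups.append(MeasurementGroup(label=group_label, measurements=tuple(measurements)))
    return HealthDataset(groups=tuple(groups))


def generate_minimal_example() -> HealthDataset:
    """The smallest worked example: one "Blood Pressure" group, two measurements.

    Systolic and Diastolic each carry two samples taken at the example
    times 1420798224 and 1423742720 (2015-01-09 and 2015-02-12, GMT),
    showing a slightly elevated reading improving a month later.
    """
    def bp(label: str, rec: tuple[float, float], warn: tuple[float, float], v0: float, v1: float) -> Measurement:
        return Measurement(
            label=label,
            units="mmHg",
            rec_min=rec[0],
            rec_max=rec[1],
            warn_min=warn[0],
            warn_max=warn[1],
            samples=(Sample(T0, v0), Sample(T1, v1)),
        )

    return HealthDataset(
        groups=(
            MeasurementGroup(
                label="Blood Pressure",
                measurements=(
                    bp("Systolic", (90, 120), (80, 140), 132.0, 118.0),
                    bp("Diastolic", (60, 80), (50, 90), 88.0, 79.0),
                ),
            ),
        )
    )
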