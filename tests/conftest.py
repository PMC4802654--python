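"""Shared fixtures: seeded random dataset generation for property-style tests."""

from __future__ import annotations

import numpy as np
import pytest

from hfigures.data_model import HealthDataset, Measurement, MeasurementGroup, Sample


def random_dataset(
    rng: np.random.Generator,
    max_groups: int = 12,
    max_measurements: int = 10,
    n_samples: int = 2,
) -> HealthDataset:
    """A structurally valid dataset with random groups, ranges and samples."""
    n_groups = int(rng.integers(1, max_groups + 1))
    timestamps = np.sort(rng.integers(0, 2_000_000_000, size=n_samples))
    # Shared, strictly increasing timestamps.
    timestamps = np.unique(timestamps)
    while len(timestamps) < n_samples:
        timestamps = np.unique(
            np.concatenate([timestamps, rng.integers(0, 2_000_000_000, size=n_samples)])
        )
    timestamps = timestamps[:n_samples]

    groups = []
    for gi in range(n_groups):
        n_m = int(rng.integers(1, max_measurements + 1))
        measurements = []
        for mi in range(n_m):
            rec_min = float(rng.uniform(-100, 100))
            span = float(rng.uniform(0.5, 50))
            rec_max = rec_min + span
            warn_min = rec_min - float(rng.uniform(0, 20)) if rng.random() < 0.5 else None
            warn_max = rec_max + float(rng.uniform(0, 20)) if rng.random() < 0.5 else None
            values = rng.uniform(rec_min - span, rec_max + span, size=n_samples)
            measurements.append(
                Measurement(
                    label=f"m{gi}_{mi}",
                    units="u",
                    rec_min=rec_min,
                    rec_max=rec_max,
                    warn_min=warn_min,
                    warn_max=warn_max,
                    samples=tuple(
                        Sample(int(t), float(v)) for t, v in zip(timestamps, values)
                    ),
                )
            )
        groups.append(MeasurementGroup(label=f"g{gi}", measurements=tuple(measurements)))
    return HealthDataset(groups=tuple(groups))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160322)
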