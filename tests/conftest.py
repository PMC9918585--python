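import numpy as np
import pytest

from esmpower import ESMDataset, PersonSeries, SyntheticConfig, generate_dataset


def make_series(values, person_id="p1", start="2024-01-01T09:00:00", step_hours=3.0):
    """A PersonSeries with evenly spaced timestamps (helper, not a fixture)."""
    values = np.asarray(values, dtype=float)
    t0 = np.datetime64(start, "s")
    times = t0 + (np.arange(len(values)) * step_hours * 3600).astype("timedelta64[s]")
    return PersonSeries(person_id, times, values)


def make_dataset(*value_lists, step_hours=3.0, bounds=(0.0, 100.0)):
    series = [
        make_series(v, person_id=f"p{i}", step_hours=step_hours)
        for i, v in enumerate(value_lists)
    ]
    return ESMDataset.from_series(series, bounds)


@pytest.fixture(scope="session")
def synth_default():
    """Moderate default-regime synthetic dataset with ground truth."""
    cfg = SyntheticConfig(n_persons=60, days_per_person=20, seed=101)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def synth_strong():
    """Strong diurnal-cycle / high-inertia regime.

    The condition under which sampling consecutive reports (close sampling)
    is predicted to be clearly less accurate for mean and variability
    measures: a pronounced within-day cycle plus persistent moment-to-moment
    carryover, so short windows of consecutive reports are both unbalanced
    over the day and strongly correlated.
    """
    cfg = SyntheticConfig(
        n_persons=120,
        days_per_person=40,
        diurnal_amplitude=12.0,
        phi_mean=0.7,
        phi_sd=0.1,
        weekend_shift=4.0,
        seed=202,
    )
    return generate_dataset(cfg)
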