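import datetime as dt

import numpy as np
import pandas as pd
import pytest

import phenokit as pk
from phenokit.simulate import CohortConfig, MissingnessConfig, make_profiles
from phenokit.streams import SCHEMAS, StreamDay, empty_records


def mk_day(stream: str, pid: str = "P000", date: dt.date = dt.date(2020, 4, 1),
           **cols) -> StreamDay:
    """Build a StreamDay from keyword columns (t in UTC epoch ms)."""
    if not cols:
        return StreamDay(pid, stream, date, empty_records(stream))
    n = len(next(iter(cols.values())))
    data = {"t": np.asarray(cols.pop("t", np.arange(n) * 1000), dtype=np.int64)}
    for name in SCHEMAS[stream]:
        if name in cols:
            data[name] = np.asarray(cols[name])
    df = pd.DataFrame(data).sort_values("t", kind="stable").reset_index(drop=True)
    return StreamDay(pid, stream, date, df)


DAY0_MS = int(dt.datetime(2020, 4, 1, tzinfo=dt.timezone.utc).timestamp() * 1000
              - 8 * 3_600_000)  # local midnight of 2020-04-01 at UTC+8


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x 30 days, no regime effect, default missingness."""
    cfg = pk.default_cohort_config(3, 30, seed=7, with_effect=False)
    return pk.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    return pk.build_daily_table(small_cohort)


@pytest.fixture(scope="session")
def full_stream_participant():
    """One participant x 4 days with zero missingness: all 13 streams present."""
    prof = make_profiles(1, 11)[0]
    miss = MissingnessConfig(p_phone_silent_day=0, p_nonwear_day=0,
                             p_daytime_nonwear_block=0, p_file_absent=0)
    return pk.generate_participant(prof, 4, None, miss, seed=11)


@pytest.fixture(scope="session")
def recovery_cohort():
    """2 participants x 150 days, no effect: enough days for 3-SE moment
    recovery checks against the planted truth."""
    cfg = CohortConfig(profiles=make_profiles(2, 5), n_days=150, effect=None)
    return pk.generate_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def recovery_daily(recovery_cohort):
    return pk.build_daily_table(recovery_cohort)
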