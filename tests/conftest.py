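from datetime import date, time

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from roamkit.rfid_io import EventLog, LightRegime, LightSchedule, parse_event_log

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def summer_schedule() -> LightSchedule:
    """Summertime regime: lights on 08:00, lights off 20:00."""
    return LightSchedule(
        [LightRegime(date(2019, 1, 1), date(2019, 12, 31), time(8, 0), time(20, 0))]
    )


@pytest.fixture
def seasonal_schedule() -> LightSchedule:
    """Summer (08-20) switching to winter (07-19) on 2019-10-01."""
    return LightSchedule(
        [
            LightRegime(date(2019, 1, 1), date(2019, 9, 30), time(8, 0), time(20, 0)),
            LightRegime(date(2019, 10, 1), date(2019, 12, 31), time(7, 0), time(19, 0)),
        ]
    )


def make_log(rows, k=27) -> EventLog:
    """Build an EventLog from (iso_timestamp, antenna, animal) tuples."""
    text = "timestamp,antenna_id,animal_id\n" + "\n".join(
        f"{ts},{ant},{animal}" for ts, ant, animal in rows
    )
    return parse_event_log(text, k)


@pytest.fixture
def tiny_night_log() -> EventLog:
    """One animal, one night: contacts at antennas 5, 5, 7."""
    return make_log(
        [
            ("2019-06-01T21:00:00", 5, "M01"),
            ("2019-06-01T22:00:00", 5, "M01"),
            ("2019-06-01T23:00:00", 7, "M01"),
        ]
    )
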