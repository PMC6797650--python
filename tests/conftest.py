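import io

import numpy as np
import pytest

from rfidcontacts.events import DyadRaster, EventLog, events_from_raster, read_event_log

# The six example badge records shown in the field study's data excerpt.
TABLE1_CSV = """\
start,id_a,id_b,end
18:19:46,3,5,18:19:58
18:19:47,1,10,18:20:15
18:19:47,1,8,18:22:32
18:19:49,10,8,18:22:35
18:19:53,2,5,18:20:37
18:20:04,6,11,18:20:14
"""


@pytest.fixture
def table1_log() -> EventLog:
    return read_event_log(io.StringIO(TABLE1_CSV))


def make_random_log(rng: np.random.Generator, n: int, s: int, density: float = 0.3) -> EventLog:
    """Random normalized log over roster 1..n and window [0, s)."""
    roster = list(range(1, n + 1))
    d = n * (n - 1) // 2
    data = rng.random((d, s)) < density
    dyads = [
        (roster[i], roster[j]) for i in range(n) for j in range(i + 1, n)
    ]
    return events_from_raster(DyadRaster(data, dyads, 0), roster=roster)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
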