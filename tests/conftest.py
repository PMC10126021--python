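import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from remkit.core import ActorTable, RawEvent
from remkit.ingest import split_group_events


@pytest.fixture
def actors5() -> ActorTable:
    """Five actors with known attributes and pre-standardized traits."""
    frame = pd.DataFrame(
        {
            "gender": ["female", "male", "male", "female", "female"],
            "age_group": ["young", "young", "older", "older", "young"],
        },
        index=pd.Index(["anne", "ben", "chris", "dan", "emma"], name="id"),
    )
    z = np.array([-1.2, 0.5, 1.4, -0.9, 0.2])
    frame["extraversion"] = (z - z.mean()) / z.std(ddof=1)
    return ActorTable(frame=frame, traits=("extraversion",))


@pytest.fixture
def first_events() -> list[RawEvent]:
    """Four dyadic interactions: the worked opening sequence of the docs."""
    return [
        RawEvent(1, ("anne", "ben"), "leisure", 30),
        RawEvent(61, ("anne", "chris"), "leisure", 20),
        RawEvent(121, ("dan", "emma"), "study", 15),
        RawEvent(151, ("ben", "dan"), "study", 300),
    ]


@pytest.fixture
def first_dyadic(first_events):
    dyadic, _ = split_group_events(first_events, seed=1)
    return dyadic


@pytest.fixture
def actor_file(tmp_path):
    path = tmp_path / "actors.csv"
    path.write_text(
        "id,gender,age,extraversion,agreeableness\n"
        "anne,female,20,4,5\n"
        "ben,male,24,6,3\n"
        "chris,male,25,,4\n"
    )
    return path


@pytest.fixture
def event_file_dyadic(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "time,actor1,actor2,setting,duration\n"
        "1,anne,ben,leisure,30\n"
        "61,anne,chris,leisure,20\n"
        "121,chris,anne,study,15\n"
        "151,ben,chris,study,300\n"
    )
    return path
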