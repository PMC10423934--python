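import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ethochunk import (
    AnnotationSet,
    BehaviorEvent,
    default_ethogram,
)


@pytest.fixture(scope="session")
def ethogram():
    return default_ethogram()


@pytest.fixture
def retrieval_annotations():
    """A small, fully valid annotation set for one 30-min recording."""
    vid = "damA-ld1"
    events = [
        BehaviorEvent.interval(vid, "pup retrieval", 45.2, 50.2),
        BehaviorEvent.interval(vid, "pup retrieval", 80.0, 85.0),
        BehaviorEvent.interval(vid, "pup retrieval", 115.0, 120.0),
        BehaviorEvent.interval(vid, "all pups retrieved and grouped", 120.0, 1800.0),
        BehaviorEvent.interval(vid, "nest building", 300.0, 360.5),
        BehaviorEvent.point(vid, "pup interaction", 15.0),
    ]
    return AnnotationSet(
        video_id=vid, duration_s=1800.0, fps=30.0, events=events,
        animal_id="damA", strain="C57BL/6", lactation_day=1, annotator="rater1",
    )
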