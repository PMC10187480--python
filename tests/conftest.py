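import numpy as np
import pytest

from mvshake.io_formats import EventList, MultiViewSession, labels_from_events
from mvshake.synthetic import (
    RenderParams,
    ScheduleParams,
    render_session,
    sample_event_schedule,
)


def make_session(
    n_views: int = 3,
    T: int = 10,
    events: tuple = ((2, 4),),
    fps: float = 30.0,
    hw: int = 16,
    session_id: str = "fixture",
    seed: int = 0,
) -> MultiViewSession:
    """Small in-memory session with random frames and the given events."""
    rng = np.random.default_rng(seed)
    ev = EventList(events)
    return MultiViewSession(
        session_id=session_id,
        fps=fps,
        views=[rng.integers(0, 255, (T, hw, hw), dtype=np.uint8)
               for _ in range(n_views)],
        view_names=[f"view_{i}" for i in range(n_views)],
        labels=labels_from_events(ev, T),
        events=ev,
    )


@pytest.fixture(scope="session")
def rendered_session() -> MultiViewSession:
    """A short rendered session shared by localization/dataset tests."""
    sp = ScheduleParams(session_seconds=120.0, fps=15.0, n_events=4)
    rp = RenderParams(frame_px=64, n_views=3, session_seconds=120.0, fps=15.0)
    schedule = sample_event_schedule(sp, 7)
    return render_session(schedule, rp, seed=7, session_id="rendered")


def random_event_list(
    rng: np.random.Generator, T: int, max_events: int = 6
) -> EventList:
    """Random valid event list: sorted intervals with >= 1 frame gaps."""
    n = int(rng.integers(0, max_events + 1))
    cuts = np.sort(rng.choice(T, size=min(2 * n, T), replace=False))
    intervals = []
    prev_end = -2
    for i in range(0, len(cuts) - 1, 2):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if s > prev_end + 1:
            intervals.append((s, e))
            prev_end = e
    return EventList(tuple(intervals))
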