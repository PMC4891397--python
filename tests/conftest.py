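import pytest

from roomwalk import fig3_fixture, palace44_fixture
from roomwalk.trajectories import Trajectory, TrajectoryCorpus

HOP = 6.0


def make_traj(pid, rooms, phases=None):
    rooms = list(rooms)
    return Trajectory(
        pid,
        rooms,
        [HOP * i for i in range(len(rooms))],
        phases if phases is not None else ["exploration"] * len(rooms),
    )


@pytest.fixture(scope="session")
def fig3():
    return fig3_fixture()


@pytest.fixture(scope="session")
def palace44():
    return palace44_fixture()


@pytest.fixture(scope="session")
def fig3_corpus(fig3):
    """The three worked-example players: all reach the corridor B after
    A,B,C,B,D,B; two continue to room E, one returns to corridor A."""
    return TrajectoryCorpus(
        [
            make_traj("p1", "ABCBDBE"),
            make_traj("p2", "ABCBDBE"),
            make_traj("p3", "ABCBDBA"),
        ],
        fig3,
        provenance="human",
    )
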