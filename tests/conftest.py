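import numpy as np
import pytest

from dxtrack import Trajectory, TrajectoryEnsemble


def make_trajectory(
    spot_id: str,
    chi,
    theta=None,
    frame_interval: float = 1.0,
    ring=None,
) -> Trajectory:
    chi = np.asarray(chi, dtype=float)
    theta = np.zeros_like(chi) if theta is None else np.asarray(theta, float)
    n = len(chi)
    return Trajectory(
        id=spot_id,
        frame_index=np.arange(n),
        time=np.arange(n) * frame_interval,
        theta=theta,
        chi=chi,
        source_ring=ring,
    )


def make_ensemble(
    chis: list, frame_interval: float = 1.0, n_frames_nominal=None, **kw
) -> TrajectoryEnsemble:
    trajs = [
        make_trajectory(f"t{i}", chi, frame_interval=frame_interval)
        for i, chi in enumerate(chis)
    ]
    if n_frames_nominal is None:
        n_frames_nominal = max(len(t) for t in trajs)
    return TrajectoryEnsemble(
        trajectories=trajs,
        frame_interval=frame_interval,
        n_frames_nominal=n_frames_nominal,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def random_ensemble(rng):
    """10 random-walk trajectories of mixed lengths, 1 ms frames."""
    chis = [np.cumsum(rng.normal(0, 1, size=rng.integers(5, 20)))
            for _ in range(10)]
    return make_ensemble(chis)
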