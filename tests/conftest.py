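import numpy as np
import pytest

from glycoadhesion.trajectory import (
    BoxedFrame,
    MoleculeSelection,
    PairSpec,
    Trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_tip_system(z_a, z_b, box=(5.0, 5.0, 5.5)):
    """One frame with two single-atom-tip glycolipids at fixed z heights."""
    coords = np.array([[1.0, 1.0, z_a], [1.0, 1.0, z_b]])
    frame = BoxedFrame(time=0.0, coordinates=coords, box=np.array(box))
    sel_a = MoleculeSelection(
        "gA", "glycolipid", 1, "upper",
        tip_heavy_atoms=np.array([0]),
        tail_atoms=np.empty(0, dtype=int),
        tail_masses=np.empty(0),
    )
    sel_b = MoleculeSelection(
        "gB", "glycolipid", 1, "lower",
        tip_heavy_atoms=np.array([1]),
        tail_atoms=np.empty(0, dtype=int),
        tail_masses=np.empty(0),
    )
    return frame, sel_a, sel_b


def random_trajectory(rng, n_frames=3, n_particles=4, interval=0.1, box=(6.0, 5.0, 7.0)):
    frames = [
        BoxedFrame(
            time=i * interval,
            coordinates=rng.random((n_particles, 3)) * np.array(box),
            box=np.array(box),
        )
        for i in range(n_frames)
    ]
    return Trajectory(frames=frames, frame_interval=interval)


def series_pair(pair_id="p0", relation="trans"):
    return PairSpec(pair_id, "gA", "gB", relation)
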