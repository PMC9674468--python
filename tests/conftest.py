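import numpy as np
import pytest

from groupdelim import IndividualRecord, Scene


def make_scene(coords, scene_id="s", states=None, body_lengths=None, **kwargs):
    records = tuple(
        IndividualRecord(
            individual_id=f"i{k:03d}",
            x=float(x),
            y=float(y),
            state=None if states is None else states[k],
            body_length=None if body_lengths is None else body_lengths[k],
        )
        for k, (x, y) in enumerate(coords)
    )
    return Scene(scene_id=scene_id, records=records, **kwargs)


def random_scene(rng, n=None, extent=100.0, states=None, scene_id="rand"):
    if n is None:
        n = int(rng.integers(2, 21))
    coords = rng.uniform(0, extent, (n, 2))
    state_list = None
    if states is not None:
        state_list = [states[i] for i in rng.integers(0, len(states), n)]
    return make_scene(coords, scene_id=scene_id, states=state_list)


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
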