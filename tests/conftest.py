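import numpy as np
import pytest

from cvta import erp, robot, simulate


@pytest.fixture(scope="session")
def trained_model():
    """FLDA decoder trained on one synthetic trial per item (10 repetitions),
    at the default subject SNR."""
    trials = []
    for item in range(1, erp.N_ITEMS + 1):
        sched = erp.build_schedule(10, seed=100 + item)
        rec = simulate.generate_erp_recording(
            simulate.ErpSimConfig(seed=item), sched, item
        )
        trials.append((rec, sched, item))
    return erp.train_decoder(trials)


@pytest.fixture()
def comparison_field():
    return robot.comparison_world()


@pytest.fixture()
def plain_scene():
    """Noise-free two-tone road scene with one obstacle hole."""
    cfg = simulate.RoadSceneConfig(obstacle_rects=[(60, 60, 30, 20)], seed=1)
    img, mask = simulate.generate_road_scene(cfg)
    return cfg, img, mask


def random_blob_region(rng, size=24):
    """Random 4-connected test region grown from the center of a small grid."""
    from cvta import road

    mask = np.zeros((size, size), dtype=bool)
    pos = np.array([size // 2, size // 2])
    mask[tuple(pos)] = True
    for _ in range(rng.integers(60, 200)):
        step = rng.integers(-1, 2, size=2)
        if abs(step).sum() != 1:
            continue
        pos = np.clip(pos + step, 0, size - 1)
        mask[tuple(pos)] = True
    return road.RoadRegion.from_mask(mask)
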