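import numpy as np
import pytest

from herdtrack.datamodel import Detection, FrameTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_frame_table(
    rng: np.random.Generator,
    n_frames: int = 5,
    max_objects: int = 4,
    with_ids: bool = True,
    image: float = 200.0,
    box: float = 30.0,
) -> FrameTable:
    """Small random id-bearing table for metric oracle comparisons."""
    records = []
    n_ids = int(rng.integers(1, max_objects + 1))
    for f in range(1, n_frames + 1):
        present = [i for i in range(1, n_ids + 1) if rng.uniform() < 0.8]
        for i in present:
            cx, cy = rng.uniform(box, image - box, size=2)
            w, h = rng.uniform(10, box, size=2)
            records.append(Detection(f, (cx, cy), (w, h), 1.0,
                                     id=i if with_ids else None))
    return FrameTable(records)


def perturb_table(
    rng: np.random.Generator,
    gt: FrameTable,
    drop: float = 0.2,
    jitter: float = 3.0,
    fp: float = 0.3,
    relabel_shift: int = 100,
) -> FrameTable:
    """Noisy hypothesis table derived from a ground truth."""
    records = []
    for d in gt:
        if rng.uniform() < drop:
            continue
        cx = d.center[0] + rng.normal(0, jitter)
        cy = d.center[1] + rng.normal(0, jitter)
        records.append(Detection(d.frame, (cx, cy), d.size, 1.0,
                                 id=d.id + relabel_shift))
    for f in gt.frames():
        if rng.uniform() < fp:
            cx, cy = rng.uniform(30, 170, size=2)
            records.append(Detection(f, (cx, cy), (20, 20), 1.0,
                                     id=int(rng.integers(500, 600))))
    return FrameTable(records)
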