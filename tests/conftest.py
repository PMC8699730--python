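"""Shared fixtures: small synthetic videos and the scaled protocol dataset."""

import numpy as np
import pytest

from phasefluct.fluctuation import fluctuation_map
from phasefluct.synthetic import generate_dataset, simulate_cell_video
from phasefluct.train_eval import CellRecord


def make_records(n_per_class: int, seed: int, size: int = 64,
                 frames: int = 256) -> list[CellRecord]:
    """Generate classifier records (first-frame morphology + fluctuation map)."""
    records = []
    for cell_id, params in generate_dataset(n_per_class, seed=seed, size=size,
                                            frames=frames):
        video, mask = simulate_cell_video(params)
        fmap = fluctuation_map(video, mask)
        records.append(CellRecord(cell_id, params.class_label,
                                  video.frames[0], fmap.power))
    return records


@pytest.fixture(scope="session")
def protocol_records() -> list[CellRecord]:
    """Default scaled-down dataset: 60 cells/class, 64x64x256 videos."""
    return make_records(60, seed=20210)


@pytest.fixture(scope="session")
def tiny_records() -> list[CellRecord]:
    """A fast 6-cells/class dataset for smoke-level training tests."""
    return make_records(6, seed=7, size=32, frames=64)
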