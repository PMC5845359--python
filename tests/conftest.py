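from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pytest

from axontracer import FixtureSpec, write_fixture_folder


@pytest.fixture
def rgb_image() -> np.ndarray:
    rng = np.random.default_rng(7)
    return rng.integers(0, 256, size=(24, 32, 3), dtype=np.uint8)


@pytest.fixture
def make_folder(tmp_path):
    """Write named uint8 arrays as image files into a fresh analysis folder."""

    def _make(files: dict[str, np.ndarray], subdir: str = "analysis") -> Path:
        folder = tmp_path / subdir
        folder.mkdir()
        for name, pixels in files.items():
            iio.imwrite(folder / name, pixels)
        return folder

    return _make


#: batch-scale fixture: blobs sit well inside the frame so the default
#: enlarge-60/reduce-90 sequence is not clipped by the image border
def batch_spec(seed: int, **overrides) -> FixtureSpec:
    defaults = dict(
        image_size=(512, 512),
        n_axons=5,
        seed=seed,
        graft_blobs=(((256, 256), 110),),
        debris_count=8,
        x_margin=40,
    )
    defaults.update(overrides)
    return FixtureSpec(**defaults)


@pytest.fixture
def batch_folder(tmp_path):
    """Three-image analysis folder with graft blobs and axons, plus truths."""
    folder = tmp_path / "batch"
    specs = {i: batch_spec(seed=i) for i in (1, 2, 3)}
    truths = write_fixture_folder(folder, specs)
    return folder, truths


@pytest.fixture
def norm_polygon(tmp_path) -> Path:
    path = tmp_path / "norm_roi.csv"
    path.write_text("100,100\n400,100\n400,400\n100,400\n")
    return path
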