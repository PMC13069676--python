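"""Shared fixtures: small, fast synthetic scenes and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nucleopunct.config import RunConfig
from nucleopunct.synthetic import SceneParams, generate_scene


def small_scene_params(seed: int = 0, **overrides) -> SceneParams:
    """A 1024-px scene with 4 nuclei: fast enough for unit tests while
    keeping nuclei inside the default 150-600 px size window."""
    defaults = dict(
        image_shape=(1024, 1024),
        n_nuclei=4,
        nucleus_diameter_um_range=(8.0, 11.0),
        puncta_per_nucleus={"gal9": 8.0, "pdna": 8.0, "sc35": 5.0},
        seed=seed,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    params = small_scene_params(seed=11)
    stack, truth = generate_scene(params)
    return params, stack, truth


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


def make_disk(radius: int, pad: int = 4) -> np.ndarray:
    """Boolean disk mask on a tight array."""
    size = 2 * radius + 2 * pad + 1
    rr, cc = np.mgrid[:size, :size]
    c = size // 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
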