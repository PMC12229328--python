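"""Shared fixtures: phantoms, tiny datasets and tiny network specs.

Everything is generated programmatically and seeded, so the suite needs no
stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import mkdespeckle as mk


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom() -> np.ndarray:
    return mk.generate_phantom(seed=7, height=128, width=128, n_lesions=3)


@pytest.fixture(scope="session")
def tiny_dataset() -> mk.DatasetSplit:
    """Small but complete split: 4 train / 1 val / 1 test source images."""
    return mk.make_dataset(n_images=6, seed=5, noise_variances=[0.09],
                           split=(4 / 6, 1 / 6, 1 / 6), height=128, width=128)


@pytest.fixture(scope="session")
def tiny_teacher_spec() -> mk.TeacherSpec:
    return mk.TeacherSpec(input_size=(64, 64, 1), base_filters=4, depth=2,
                          bottleneck_filters=8)


@pytest.fixture(scope="session")
def tiny_student_spec() -> mk.StudentSpec:
    return mk.StudentSpec(input_size=(64, 64, 1), n_blocks=2, filters=4)
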