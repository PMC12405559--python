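"""Shared fixtures: seeded random structures and a configured oracle."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldforge.oracle import SyntheticFolder
from foldforge.structcore import Structure


def random_structure(
    rng: np.random.Generator,
    n_residues: int = 8,
    n_chains: int = 1,
    spread: float = 8.0,
    sidechains: bool = False,
) -> Structure:
    """A random but valid structure: CA cloud plus jittered backbone atoms."""
    ca = rng.normal(scale=spread, size=(n_residues, 3))
    bb = np.empty((n_residues, 4, 3))
    bb[:, 1] = ca
    bb[:, 0] = ca + rng.normal(scale=0.4, size=(n_residues, 3)) + [1.0, 0, 0]
    bb[:, 2] = ca + rng.normal(scale=0.4, size=(n_residues, 3)) + [0, 1.0, 0]
    bb[:, 3] = ca + rng.normal(scale=0.4, size=(n_residues, 3)) + [0, 0, 1.2]
    per = n_residues // n_chains
    intervals = [(k * per, (k + 1) * per) for k in range(n_chains)]
    intervals[-1] = (intervals[-1][0], n_residues)
    sc = {}
    if sidechains:
        for i in range(n_residues):
            k = int(rng.integers(1, 4))
            sc[i] = ca[i] + rng.normal(scale=1.5, size=(k, 3))
    return Structure(bb, tuple(intervals), sc)


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation and translation."""
    rot = Rotation.from_rotvec(rng.normal(scale=2.0, size=3)).as_matrix()
    return rot, rng.normal(scale=20.0, size=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def folder() -> SyntheticFolder:
    return SyntheticFolder(seed=7)
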