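"""Shared fixtures: memoized synthetic systems and docking runs.

Mini-pocket generation and docking jobs are the expensive operations in
this suite, and several tests interrogate the same systems from different
angles; a session-scoped cache keeps each (seed, difficulty) system and
each docking run computed exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from covflex.dockcore import DockJobConfig, dock_covalent
from covflex.fixtures import make_minipocket


@pytest.fixture(scope="session")
def system_cache():
    cache: dict = {}

    def get(seed: int, difficulty: str):
        key = (seed, difficulty)
        if key not in cache:
            cache[key] = make_minipocket(seed, difficulty)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def dock_cache(system_cache):
    cache: dict = {}

    def run(seed: int, difficulty: str, config_seed: int, mode: str):
        key = (seed, difficulty, config_seed, mode)
        if key not in cache:
            system = system_cache(seed, difficulty)
            config = DockJobConfig(site=system.site, warhead=system.warhead,
                                   seed=config_seed)
            cache[key] = dock_covalent(system.receptor, system.ligand,
                                       config, mode=mode)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def easy_system(system_cache):
    return system_cache(3, "easy")


@pytest.fixture(scope="session")
def blocking_system(system_cache):
    return system_cache(3, "blocking")


def best_rmsd_topn(result, reference_pose, topn: int) -> float:
    """Best in-frame heavy-atom RMSD among the first ``topn`` ranked poses."""
    heavy = reference_pose.ligand.heavy_indices()
    ref = np.array([reference_pose.ligand.atoms[i].coords for i in heavy])
    best = np.inf
    for pose in result.poses[:topn]:
        xyz = np.array([pose.ligand.atoms[i].coords for i in heavy])
        best = min(best, float(np.sqrt(np.mean(((xyz - ref) ** 2).sum(axis=1)))))
    return best
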