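"""Experiment partitioning: meta-training/meta-test splits, 80/20 train/validation
splits, and the repeated K-shot sampling protocol.

All randomness flows from a master seed through ``numpy.random.SeedSequence``
spawn keys, so any single cell of the (K, repeat) grid is reproducible in
isolation and all adaptation methods see identical shot sets per repeat.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import PhenotypeTable

__all__ = [
    "MetaSplit",
    "KShotSplit",
    "ExperimentPlan",
    "round_half_up",
    "split_train_val",
    "make_kshot_splits",
    "make_meta_split",
    "child_seed",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def child_seed(master_seed: int, *keys: int) -> int:
    """Deterministic child seed for a grid cell, derived via SeedSequence spawn keys."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class MetaSplit:
    """Disjoint meta-training / meta-test participant and phenotype sets."""

    meta_train_ids: list[str]
    meta_test_ids: list[str]
    meta_train_phenotypes: list[str]
    meta_test_phenotypes: list[str]

    def __post_init__(self) -> None:
        if set(self.meta_train_ids) & set(self.meta_test_ids):
            raise ValueError("meta-training and meta-test participants overlap")
        if set(self.meta_train_phenotypes) & set(self.meta_test_phenotypes):
            raise ValueError("meta-training and meta-test phenotypes overlap")


@dataclass
class KShotSplit:
    """One repeat's split of the meta-test participants into K shots and the rest."""

    K: int
    shot_ids: list[str]
    test_ids: list[str]
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.shot_ids) != self.K:
            raise ValueError(f"|shot_ids| = {len(self.shot_ids)} != K = {self.K}")
        if set(self.shot_ids) & set(self.test_ids):
            raise ValueError("shot and test participants overlap")
        if not self.test_ids:
            raise ValueError("test side is empty; evaluation impossible")


@dataclass
class ExperimentPlan:
    """The K-shot grid: which K values, how many repeats, master seed."""

    K_values: tuple[int, ...] = (10, 20, 50, 100, 200)
    repeats: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.K_values = tuple(int(k) for k in self.K_values)
        if any(k <= 0 for k in self.K_values):
            raise ValueError("K values must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        return cls(tuple(d.get("K_values", (10, 20, 50, 100, 200))),
                   int(d.get("repeats", 100)), int(d.get("master_seed", 0)))


def split_train_val(ids: Sequence[str], fraction: float = 0.8,
                    seed: int = 0) -> tuple[list[str], list[str]]:
    """Random train/validation split with |train| = round-half-up(fraction·N).

    Reproduces the printed 80% splits: N=26,573 → 21,258/5,315 and
    N=36,461 → 29,169/7,292.
    """
    ids = [str(i) for i in ids]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = round_half_up(fraction * n)
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} leaves an empty side for N={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    val = [ids[i] for i in perm[n_train:]]
    return train, val


def make_kshot_splits(meta_test_ids: Sequence[str], plan: ExperimentPlan) -> list[KShotSplit]:
    """All (K, repeat) shot/test splits of the meta-test participants.

    Each cell draws K participants uniformly without replacement under a seed
    derived from (master_seed, K, repeat); regeneration with the same master
    seed yields identical splits.
    """
    ids = [str(i) for i in meta_test_ids]
    n = len(ids)
    for k in plan.K_values:
        if k >= n:
            raise ValueError(f"K={k} leaves no test participants out of {n}")
    splits: list[KShotSplit] = []
    for k in plan.K_values:
        for rep in range(plan.repeats):
            seed = child_seed(plan.master_seed, k, rep)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(n)
            shot = sorted(ids[i] for i in perm[:k])
            test = sorted(ids[i] for i in perm[k:])
            splits.append(KShotSplit(k, shot, test, rep, seed))
    return splits


def make_meta_split(table: PhenotypeTable, n_test_participants: int,
                    test_phenotypes: Sequence[str], seed: int = 0) -> MetaSplit:
    """Partition a phenotype table's participants and phenotypes into disjoint
    meta-training and meta-test sets (within-dataset mode)."""
    test_phenotypes = [str(p) for p in test_phenotypes]
    unknown = [p for p in test_phenotypes if p not in table.phenotype_names]
    if unknown:
        raise ValueError(f"test phenotypes not in table: {unknown}")
    n = table.n_participants
    if not 0 < n_test_participants < n:
        raise ValueError(f"n_test_participants={n_test_participants} infeasible for N={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_ids = sorted(table.participant_ids[i] for i in perm[:n_test_participants])
    train_ids = sorted(table.participant_ids[i] for i in perm[n_test_participants:])
    train_phenos = [p for p in table.phenotype_names if p not in set(test_phenotypes)]
    return MetaSplit(train_ids, test_ids, train_phenos, test_phenotypes)


def export_splits(splits: Sequence[KShotSplit], path: str | Path) -> None:
    """Write K-shot splits as JSON for audit."""
    Path(path).write_text(json.dumps([
        {"K": s.K, "repeat_index": s.repeat_index, "seed": s.seed,
         "shot_ids": s.shot_ids, "test_ids": s.test_ids}
        for s in splits
    ]))
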