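"""Genre-stratified train/test split and cross-validation folds.

The study layout: of 60 excerpts, 16 (4 per genre) are held out for testing,
4 (1 per genre) are "always-train" excerpts present in every training set,
and the remaining 40 form five genre-balanced folds of 8 (2 per genre).  Each
fold's network trains on the other four folds plus the always-train excerpts:
36 excerpts, 9 per genre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic_data import ConfigError, substream

__all__ = ["Partition", "make_partition", "training_set"]

N_FOLDS = 5
TEST_PER_GENRE = 4
ALWAYS_PER_GENRE = 1
FOLD_PER_GENRE = 2


@dataclass
class Partition:
    test_ids: list[str]
    always_train_ids: list[str]
    folds: list[list[str]]
    seed: int
    genre_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def train_pool_ids(self) -> list[str]:
        """All excerpts ever used for training (always-train + every fold)."""
        return self.always_train_ids + [e for fold in self.folds for e in fold]

    def to_dict(self) -> dict:
        return {"seed": self.seed, "test_ids": self.test_ids,
                "always_train_ids": self.always_train_ids, "folds": self.folds,
                "genre_of": self.genre_of}

    @classmethod
    def from_dict(cls, d: dict) -> "Partition":
        return cls(test_ids=list(d["test_ids"]),
                   always_train_ids=list(d["always_train_ids"]),
                   folds=[list(f) for f in d["folds"]], seed=int(d["seed"]),
                   genre_of=dict(d.get("genre_of", {})))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Partition":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_partition(excerpts: pd.DataFrame, seed: int,
                   n_folds: int = N_FOLDS,
                   test_per_genre: int = TEST_PER_GENRE,
                   always_per_genre: int = ALWAYS_PER_GENRE,
                   fold_per_genre: int = FOLD_PER_GENRE) -> Partition:
    """Draw the stratified split uniformly at random within genre strata.

    `excerpts` needs `excerpt_id` and `genre` columns.  Counts must tile each
    genre exactly: per genre, test + always + n_folds * fold_per_genre excerpts.
    """
    needed = test_per_genre + always_per_genre + n_folds * fold_per_genre
    rng = substream(seed, "partition")
    test: list[str] = []
    always: list[str] = []
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    genre_of: dict[str, str] = dict(zip(excerpts["excerpt_id"], excerpts["genre"]))
    for genre, group in excerpts.groupby("genre", sort=True):
        ids = list(group["excerpt_id"])
        if len(ids) != needed:
            raise ConfigError(
                f"genre {genre!r} has {len(ids)} excerpts; the layout needs {needed}")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        test.extend(ids[:test_per_genre])
        always.extend(ids[test_per_genre:test_per_genre + always_per_genre])
        rest = ids[test_per_genre + always_per_genre:]
        for k in range(n_folds):
            folds[k].extend(rest[k * fold_per_genre:(k + 1) * fold_per_genre])
    return Partition(test_ids=sorted(test), always_train_ids=sorted(always),
                     folds=[sorted(f) for f in folds], seed=seed, genre_of=genre_of)


def training_set(partition: Partition, fold_index: int) -> list[str]:
    """Training excerpts for one fold: the other folds plus always-train ids."""
    if not 0 <= fold_index < partition.n_folds:
        raise IndexError(f"fold_index {fold_index} outside 0..{partition.n_folds - 1}")
    ids = list(partition.always_train_ids)
    for k, fold in enumerate(partition.folds):
        if k != fold_index:
            ids.extend(fold)
    return sorted(ids)
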