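"""Shared in-memory container for beat segments.

A `BeatDataset` is the unit every stage consumes: an n x segment_len feature
matrix, AAMI class labels, train/val/test split tags and per-row provenance
(source record id and R-peak sample index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: AAMI class order used everywhere (labels, confusion matrices, reports).
CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

SPLITS = ("train", "val", "test")


@dataclass
class BeatDataset:
    X: np.ndarray                      # (n, segment_len) float
    y: np.ndarray                      # (n,) AAMI class labels, '<U1'
    split: np.ndarray = None           # (n,) '' or train/val/test
    record_id: np.ndarray = None       # (n,) source record ids
    r_index: np.ndarray = None         # (n,) R-peak sample in the source record

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D (n, segment_len), got shape {self.X.shape}")
        n = self.X.shape[0]
        self.y = np.asarray(self.y, dtype="<U1")
        if self.split is None:
            self.split = np.full(n, "", dtype="<U5")
        else:
            self.split = np.asarray(self.split, dtype="<U5")
        if self.record_id is None:
            self.record_id = np.full(n, "", dtype="<U32")
        else:
            self.record_id = np.asarray(self.record_id, dtype="<U32")
        if self.r_index is None:
            self.r_index = np.full(n, -1, dtype=np.int64)
        else:
            self.r_index = np.asarray(self.r_index, dtype=np.int64)
        for name, arr in (("y", self.y), ("split", self.split),
                          ("record_id", self.record_id), ("r_index", self.r_index)):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        bad = set(np.unique(self.y)) - set(CLASSES) if n else set()
        if bad:
            raise ValueError(f"labels outside the AAMI classes {CLASSES}: {sorted(bad)}")
        bad_split = set(np.unique(self.split)) - {"", *SPLITS} if n else set()
        if bad_split:
            raise ValueError(f"invalid split tags: {sorted(bad_split)}")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def y_index(self) -> np.ndarray:
        """Integer labels in CLASSES order."""
        return np.array([CLASS_INDEX[c] for c in self.y], dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.y == c).sum()) for c in CLASSES}

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        return BeatDataset(self.X[mask], self.y[mask], self.split[mask],
                           self.record_id[mask], self.r_index[mask])

    def split_subset(self, which: str) -> "BeatDataset":
        if which not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {which!r}")
        return self.subset(self.split == which)

    @staticmethod
    def concatenate(parts: list["BeatDataset"]) -> "BeatDataset":
        return BeatDataset(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.split for p in parts]),
            np.concatenate([p.record_id for p in parts]),
            np.concatenate([p.r_index for p in parts]),
        )
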