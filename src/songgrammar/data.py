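"""Shared data containers: song regions, feature strings, corpus I/O.

A :class:`FeatureString` is the atomic datum of the grammatical analysis:
one song region's ordered sequence of D-dimensional feature vectors
(13 MFCCs by default).  Corpora are plain lists of feature strings and are
serialized as JSON Lines, one record per string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SongRegion", "FeatureString", "write_jsonl", "read_jsonl", "corpus_lengths"]


@dataclass(frozen=True)
class SongRegion:
    """Half-open time interval [start, end) in seconds judged to contain song."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class FeatureString:
    """One song region's sequence of feature vectors.

    Attributes
    ----------
    string_id : str
        Stable identifier within a corpus.
    vectors : (l, D) ndarray
        Ordered feature vectors; all entries finite, l >= 1.
    region : SongRegion or None
        Originating time interval (None for synthetic corpora).
    peak_times : list of float
        Peak locations in seconds, aligned with ``vectors`` (may be empty
        for synthetic corpora).
    """

    string_id: str
    vectors: np.ndarray
    region: SongRegion | None = None
    peak_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.ndim != 2 or len(self.vectors) < 1:
            raise ValueError("vectors must be a non-empty (l, D) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError(f"non-finite feature vector in string {self.string_id!r}")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def write_jsonl(strings: Iterable[FeatureString], path) -> int:
    """Write a corpus as JSON Lines; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for s in strings:
            rec = {
                "string_id": s.string_id,
                "region_start_s": s.region.start if s.region else None,
                "region_end_s": s.region.end if s.region else None,
                "peaks_s": list(map(float, s.peak_times)),
                "mfcc": s.vectors.tolist(),
            }
            fh.write(json.dumps(rec) + "\n")
            n += 1
    return n


def read_jsonl(path) -> list[FeatureString]:
    out: list[FeatureString] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            region = None
            if rec.get("region_start_s") is not None:
                region = SongRegion(rec["region_start_s"], rec["region_end_s"])
            out.append(
                FeatureString(
                    string_id=rec["string_id"],
                    vectors=np.asarray(rec["mfcc"], dtype=float),
                    region=region,
                    peak_times=rec.get("peaks_s", []),
                )
            )
    return out


def corpus_lengths(corpus: Sequence[FeatureString]) -> np.ndarray:
    return np.array([len(s) for s in corpus], dtype=int)
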