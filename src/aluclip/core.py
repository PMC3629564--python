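"""Shared containers for iCLIP-style analyses.

Coordinates are 0-based, half-open throughout the in-memory API; GTF output
is converted to 1-based inclusive on write.  Strands are ``"+"``/``"-"``.
"""

from __future__ import annotations

import numpy as np

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A gene with its exon structure on a genome contig.

    ``exons`` are genomic half-open intervals sorted by coordinate; UTR
    intervals, when present, are sub-intervals of the terminal exons.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty gene interval for {self.gene_id}")


@dataclass
class AluRecord:
    """A strand-aware repeat annotation interval (BED6-level)."""

    name: str
    contig: str
    start: int
    end: int
    strand: str
    gene_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BindingSite:
    """A called binding site: a cluster of significantly enriched
    crosslink positions, with its summit and randomization FDR."""

    contig: str
    strand: str
    start: int
    end: int
    summit: int
    event_count: int
    fdr: float
    gene_id: str

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside site interval")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class CrosslinkTrack:
    """Per-contig, per-strand counts of unique crosslink events.

    Sparse: only positions with at least one event are stored.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], Counter] = defaultdict(Counter)
        self._index: dict[tuple[str, str], tuple] = {}

    def add(self, contig: str, strand: str, pos: int, count: int = 1) -> None:
        if count <= 0:
            raise ValueError("crosslink counts must be positive")
        self._data[(contig, strand)][pos] += count
        self._index.pop((contig, strand), None)

    def counts(self, contig: str, strand: str) -> Counter:
        return self._data.get((contig, strand), Counter())

    def count_at(self, contig: str, strand: str, pos: int) -> int:
        return self._data.get((contig, strand), Counter()).get(pos, 0)

    def keys(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._data))

    def _sorted_index(self, contig: str, strand: str):
        """Cached (positions, counts, cumulative counts) arrays."""
        key = (contig, strand)
        cached = self._index.get(key)
        if cached is None:
            c = self._data.get(key)
            if not c:
                cached = (np.empty(0, dtype=np.int64),) * 2 + (np.zeros(1),)
            else:
                pos = np.array(sorted(c), dtype=np.int64)
                cnt = np.array([c[p] for p in pos], dtype=np.int64)
                cached = (pos, cnt, np.concatenate([[0], np.cumsum(cnt)]))
            self._index[key] = cached
        return cached

    def positions_in(
        self, contig: str, strand: str, start: int, end: int
    ) -> list[tuple[int, int]]:
        """(position, count) pairs within [start, end), sorted by position."""
        pos, cnt, _ = self._sorted_index(contig, strand)
        lo, hi = np.searchsorted(pos, [start, end])
        return list(zip(pos[lo:hi].tolist(), cnt[lo:hi].tolist()))

    def events_in(self, contig: str, strand: str, start: int, end: int) -> int:
        pos, _, csum = self._sorted_index(contig, strand)
        lo, hi = np.searchsorted(pos, [start, end])
        return int(csum[hi] - csum[lo])

    def total(self) -> int:
        return sum(sum(c.values()) for c in self._data.values())

    def merged_with(self, *others: "CrosslinkTrack") -> "CrosslinkTrack":
        """Pooled track summing this track with ``others``."""
        out = CrosslinkTrack()
        for trk in (self, *others):
            for (contig, strand), counter in trk._data.items():
                for pos, n in counter.items():
                    out.add(contig, strand, pos, n)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrosslinkTrack):
            return NotImplemented
        a = {k: dict(v) for k, v in self._data.items() if v}
        b = {k: dict(v) for k, v in other._data.items() if v}
        return a == b
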