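"""Core domain types for the CNV population-analysis pipeline.

Coordinate convention: all genomic intervals are 1-based and inclusive at
both ends, so ``length = end - start + 1``.  BED input/output converts from
the 0-based half-open convention at the I/O boundary (see :mod:`cnvpop.io`).
Only autosomes ("1".."22") are modelled; calls on sex chromosomes are
rejected at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROM_LABELS = {"X", "Y", "XY", "MT", "M", "23", "24", "25", "26"}

DELETION = "deletion"
AMPLIFICATION = "amplification"
NEUTRAL = "neutral"
CNV_TYPES = (DELETION, AMPLIFICATION)

DELETION_ONLY = "deletion_only"
AMPLIFICATION_ONLY = "amplification_only"
GAIN_AND_LOSS = "gain_and_loss"


def normalize_chrom(label: object) -> str:
    """Strip a ``chr`` prefix and return the bare chromosome label."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def is_autosome(label: str) -> bool:
    return label in AUTOSOMES


def chrom_sort_key(chrom: str) -> int:
    return int(chrom)


@dataclass(frozen=True)
class CnvCall:
    """One caller's raw CNV call for one sample.

    ``confidence`` is a log-Bayes-factor-like score emitted by caller A
    only; caller B reports copy number without a confidence.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int
    caller: str
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"call {self.sample_id} {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.caller not in ("A", "B"):
            raise ValueError(f"caller must be 'A' or 'B', got {self.caller!r}")
        if not is_autosome(self.chrom):
            raise ValueError(f"chromosome {self.chrom!r} is not an autosome")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusEvent:
    """A dual-caller-confirmed CNV for one sample.

    The interval is the overlapped section of the two matched calls; when
    source calls are attached the interval must be contained in both.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    source_a: Optional[CnvCall] = None
    source_b: Optional[CnvCall] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start > end")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"cnv_type must be one of {CNV_TYPES}")
        for src in (self.source_a, self.source_b):
            if src is not None and not (src.start <= self.start and self.end <= src.end):
                raise ValueError("event interval not contained in source call")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Cnvr:
    """A copy-number-variable region: the union span of a single-linkage
    cluster of overlapping per-sample events."""

    cnvr_id: str
    chrom: str
    start: int
    end: int
    members: tuple[ConsensusEvent, ...]
    type_class: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNVR start > end")
        for m in self.members:
            if m.chrom != self.chrom or m.end < self.start or m.start > self.end:
                raise ValueError("member does not overlap CNVR span")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)

    def carriers_in(self, panel: "Panel", population: str) -> frozenset[str]:
        return frozenset(s for s in self.carriers if panel.population_of(s) == population)

    def population_carrier_counts(self, panel: "Panel") -> dict[str, int]:
        counts = {pop: 0 for pop in panel.populations}
        for s in self.carriers:
            counts[panel.population_of(s)] += 1
        return counts


class Panel:
    """Sample-to-population assignment."""

    def __init__(self, membership: Mapping[str, str]):
        if not membership:
            raise ValueError("panel is empty")
        self._membership = dict(membership)
        self._populations = tuple(sorted(set(self._membership.values())))

    @property
    def populations(self) -> tuple[str, ...]:
        return self._populations

    @property
    def membership(self) -> dict[str, str]:
        return dict(self._membership)

    def population_of(self, sample_id: str) -> str:
        try:
            return self._membership[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in panel") from None

    def samples(self, population: Optional[str] = None) -> tuple[str, ...]:
        if population is None:
            return tuple(sorted(self._membership))
        if population not in self._populations:
            raise KeyError(f"unknown population {population!r}")
        return tuple(sorted(s for s, p in self._membership.items() if p == population))

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._membership

    def __len__(self) -> int:
        return len(self._membership)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Panel) and self._membership == other._membership


@dataclass(frozen=True)
class Individual:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: str
    population: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """A set of individuals with parent links, stored in topological order
    (parents before children).  Construction validates parent references
    and rejects cycles."""

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        by_id: dict[str, Individual] = {}
        for ind in members:
            if ind.id in by_id:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            by_id[ind.id] = ind
        for ind in members:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in by_id:
                    raise ValueError(f"unknown parent id {parent!r} of {ind.id!r}")
        self._by_id = by_id
        self._order = self._toposort(members)

    @staticmethod
    def _toposort(members: list[Individual]) -> tuple[Individual, ...]:
        children: dict[str, list[str]] = {m.id: [] for m in members}
        indeg = {m.id: 0 for m in members}
        by_id = {m.id: m for m in members}
        for m in members:
            for p in (m.father, m.mother):
                if p is not None:
                    children[p].append(m.id)
                    indeg[m.id] += 1
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[Individual] = []
        while queue:
            nid = queue.pop(0)
            order.append(by_id[nid])
            for c in children[nid]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(members):
            raise ValueError("pedigree contains a cycle (individual is its own ancestor)")
        return tuple(order)

    @property
    def individuals(self) -> tuple[Individual, ...]:
        return self._order

    @property
    def founders(self) -> tuple[Individual, ...]:
        return tuple(i for i in self._order if i.is_founder)

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._order)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and set(self._order) == set(other._order)


class AnnotationTrack:
    """A named set of genomic intervals (centromeres, genes, segmental
    duplications, reported CNVs, ...), sorted per chromosome."""

    def __init__(
        self,
        name: str,
        intervals: Mapping[str, Sequence[tuple]] | Iterable[tuple],
    ):
        self.name = name
        per_chrom: dict[str, list[tuple[int, int, Optional[str]]]] = {}
        if isinstance(intervals, Mapping):
            items: Iterable[tuple] = (
                (chrom, *iv) for chrom, ivs in intervals.items() for iv in ivs
            )
        else:
            items = intervals
        for rec in items:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            label = rec[3] if len(rec) > 3 else None
            if start > end:
                raise ValueError(f"malformed interval {chrom}:{start}-{end}")
            per_chrom.setdefault(str(chrom), []).append((start, end, label))
        for chrom in per_chrom:
            per_chrom[chrom].sort(key=lambda iv: (iv[0], iv[1]))
        self.intervals = per_chrom

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self.intervals, key=chrom_sort_key))

    def merged(self, chrom: str) -> list[tuple[int, int]]:
        """Union of the track's intervals on one chromosome."""
        out: list[tuple[int, int]] = []
        for s, e, _ in self.intervals.get(chrom, []):
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AnnotationTrack)
            and self.name == other.name
            and self.intervals == other.intervals
        )


class SnpMap:
    """Strictly increasing SNP base positions per chromosome."""

    def __init__(self, positions: Mapping[str, Sequence[int]]):
        self.positions: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            arr = np.unique(np.asarray(pos, dtype=np.int64))
            if arr.size == 0:
                raise ValueError(f"chromosome {chrom!r} has no SNPs")
            self.positions[str(chrom)] = arr

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self.positions, key=chrom_sort_key))

    def extent(self, chrom: str) -> tuple[int, int]:
        """Span from the first to the last SNP on a chromosome."""
        arr = self.positions[chrom]
        return int(arr[0]), int(arr[-1])

    def count_in(self, chrom: str, start: int, end: int) -> int:
        arr = self.positions.get(chrom)
        if arr is None:
            return 0
        return int(np.searchsorted(arr, end, side="right") - np.searchsorted(arr, start, side="left"))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SnpMap)
            and self.positions.keys() == other.positions.keys()
            and all(np.array_equal(self.positions[c], other.positions[c]) for c in self.positions)
        )
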