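"""CNVR construction and cross-population sharing statistics.

Per-sample consensus events are clustered per chromosome by single linkage:
events sharing at least one base pair, directly or transitively, form one
copy-number-variable region (CNVR) whose span is the union of its members.
CNVRs are the cross-sample unit for frequency, sharing and kinship
analyses.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    AMPLIFICATION,
    AMPLIFICATION_ONLY,
    DELETION,
    DELETION_ONLY,
    GAIN_AND_LOSS,
    Cnvr,
    ConsensusEvent,
    Panel,
    chrom_sort_key,
)


def _type_class(members: Sequence[ConsensusEvent]) -> str:
    types = {m.cnv_type for m in members}
    if types == {DELETION}:
        return DELETION_ONLY
    if types == {AMPLIFICATION}:
        return AMPLIFICATION_ONLY
    return GAIN_AND_LOSS


def build_cnvrs(events: Sequence[ConsensusEvent]) -> list[Cnvr]:
    """Cluster events into CNVRs by single-linkage >=1 bp overlap.

    The result is independent of the input order; ids are assigned after
    sorting regions by (chromosome, start).
    """
    by_chrom: dict[str, list[ConsensusEvent]] = defaultdict(list)
    for ev in events:
        by_chrom[ev.chrom].append(ev)
    clusters: list[list[ConsensusEvent]] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        evs = sorted(
            by_chrom[chrom], key=lambda e: (e.start, e.end, e.sample_id, e.cnv_type)
        )
        current = [evs[0]]
        max_end = evs[0].end
        for ev in evs[1:]:
            if ev.start <= max_end:  # 1-based inclusive: touching bases overlap
                current.append(ev)
                max_end = max(max_end, ev.end)
            else:
                clusters.append(current)
                current = [ev]
                max_end = ev.end
        clusters.append(current)
    width = max(4, len(str(len(clusters))))
    out = []
    for idx, members in enumerate(clusters, start=1):
        out.append(
            Cnvr(
                cnvr_id=f"CNVR{idx:0{width}d}",
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                members=tuple(members),
                type_class=_type_class(members),
                carriers=frozenset(m.sample_id for m in members),
            )
        )
    return out


def boundary_concordance(cnvr: Cnvr) -> bool:
    """True iff some pair of member events from distinct samples differs in
    start or end — i.e. the region's boundaries are not equivalent across
    carriers."""
    if len(cnvr.members) < 2:
        raise ValueError(f"{cnvr.cnvr_id}: boundary concordance needs >=2 members")
    return any(
        m1.sample_id != m2.sample_id and (m1.start, m1.end) != (m2.start, m2.end)
        for m1, m2 in combinations(cnvr.members, 2)
    )


@dataclass(frozen=True)
class FrequencySpec:
    """How CNVR frequencies are computed.

    denominator_mode
        ``"carriers"`` — divide by the number of CNV-carrier individuals
        (the scale on which the overall frequency range 1/carriers ..
        max_carriers/carriers is expressed); ``"all_samples"`` — divide by
        the panel (or population) size.
    scope
        ``"overall"`` or ``"per_population"``.
    """

    denominator_mode: str = "carriers"
    scope: str = "overall"

    def __post_init__(self) -> None:
        if self.denominator_mode not in ("carriers", "all_samples"):
            raise ValueError("denominator_mode must be 'carriers' or 'all_samples'")
        if self.scope not in ("overall", "per_population"):
            raise ValueError("scope must be 'overall' or 'per_population'")


def carrier_individuals(cnvrs: Sequence[Cnvr]) -> frozenset[str]:
    """All distinct individuals carrying at least one CNVR."""
    out: set[str] = set()
    for c in cnvrs:
        out |= c.carriers
    return frozenset(out)


def cnvr_frequency(
    cnvr: Cnvr,
    panel: Panel,
    spec: FrequencySpec = FrequencySpec(),
    population: Optional[str] = None,
    n_carriers: Optional[int] = None,
) -> float:
    """Frequency of one CNVR under the given spec.

    In ``carriers`` mode the denominator (total carrier individuals in
    scope) must be supplied via ``n_carriers`` because a single region
    cannot know the cohort-wide carrier count.  Rounding (5 decimals) is a
    reporting concern and is not applied here.
    """
    if spec.scope == "per_population":
        if population is None:
            raise ValueError("per_population scope requires a population")
        numerator = len(cnvr.carriers_in(panel, population))
        denominator = (
            n_carriers if spec.denominator_mode == "carriers" else len(panel.samples(population))
        )
    else:
        numerator = len(cnvr.carriers)
        denominator = n_carriers if spec.denominator_mode == "carriers" else len(panel)
    if denominator is None or denominator <= 0:
        raise ValueError("frequency denominator must be positive")
    return numerator / denominator


@dataclass(frozen=True)
class SharingPartition:
    """Venn-style partition of CNVRs by the populations their carriers span.

    ``private``: population -> count of CNVRs seen only there;
    ``pairwise``: sorted population pair -> count; ``all_populations``:
    CNVRs with carriers in every population; ``presence``: per-CNVR sorted
    tuple of populations with >=1 carrier; ``strata``: for each carrier-
    count stratum ("2".."10", ">10"), the fraction of CNVRs private to one
    population / spanning two / spanning three or more.
    """

    private: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    all_populations: int
    presence: dict[str, tuple[str, ...]]
    strata: dict[str, dict[int, float]]

    @property
    def total(self) -> int:
        return sum(self.private.values()) + sum(self.pairwise.values()) + self.all_populations


def sharing_partition(cnvrs: Sequence[Cnvr], panel: Panel) -> SharingPartition:
    pops = panel.populations
    if not pops:
        raise ValueError("panel has no populations")
    private = {p: 0 for p in pops}
    pairwise = {tuple(sorted(pair)): 0 for pair in combinations(pops, 2)}
    n_all = 0
    presence: dict[str, tuple[str, ...]] = {}
    strata_counts: dict[str, dict[int, int]] = {}
    for cnvr in cnvrs:
        present = tuple(sorted({panel.population_of(s) for s in cnvr.carriers}))
        presence[cnvr.cnvr_id] = present
        if len(present) == 1:
            private[present[0]] += 1
        elif len(present) == 2:
            pairwise[present] += 1
        elif len(present) == len(pops):
            n_all += 1
        n = cnvr.carrier_count
        if n >= 2:
            key = str(n) if n <= 10 else ">10"
            bucket = strata_counts.setdefault(key, {1: 0, 2: 0, 3: 0})
            bucket[min(len(present), 3)] += 1
    strata: dict[str, dict[int, float]] = {}
    for key, bucket in strata_counts.items():
        total = sum(bucket.values())
        strata[key] = {k: v / total for k, v in bucket.items()}
    return SharingPartition(
        private=private,
        pairwise=pairwise,
        all_populations=n_all,
        presence=presence,
        strata=strata,
    )


def population_frequencies(
    cnvrs: Sequence[Cnvr],
    panel: Panel,
    population: str,
    denominator_mode: str = "all_samples",
) -> np.ndarray:
    """Per-CNVR frequencies within one population (vector aligned with
    ``cnvrs``)."""
    if denominator_mode == "all_samples":
        denom = len(panel.samples(population))
    else:
        denom = len(
            {s for c in cnvrs for s in c.carriers_in(panel, population)}
        )
    if denom <= 0:
        raise ValueError(f"zero frequency denominator for population {population!r}")
    return np.array([len(c.carriers_in(panel, population)) / denom for c in cnvrs])


def frequency_correlation(
    cnvrs: Sequence[Cnvr],
    panel: Panel,
    pop_a: str,
    pop_b: str,
    min_freq: float = 0.01,
    denominator_mode: str = "all_samples",
) -> tuple[float, float]:
    """Pearson correlation of common-CNVR frequencies between populations.

    CNVRs exceeding ``min_freq`` in ``pop_a`` (the selection population)
    are chosen, and that set's frequencies in the two populations are
    correlated (two-sided p).
    """
    freq_a = population_frequencies(cnvrs, panel, pop_a, denominator_mode)
    freq_b = population_frequencies(cnvrs, panel, pop_b, denominator_mode)
    mask = freq_a > min_freq
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} CNVRs exceed frequency {min_freq} in {pop_a!r}; "
            "lower the threshold"
        )
    r, p = stats.pearsonr(freq_a[mask], freq_b[mask])
    return float(r), float(p)
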