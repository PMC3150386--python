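"""Consensus CNV calling: per-sample merging of two callers' calls.

A confirmed CNV requires that both callers report a change at the same
locus, with the same direction (loss vs gain), a reciprocal overlap
exceeding half of each call's length, and an overlapped section between
1 kb and 3 Mb.  The consensus event takes the overlapped section as its
interval.  Samples reporting an excessive number of raw calls are removed
wholesale, and events overlapping centromeres are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import (
    AMPLIFICATION,
    DELETION,
    NEUTRAL,
    AnnotationTrack,
    CnvCall,
    ConsensusEvent,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunable thresholds of the consensus-calling stage.

    min_overlap_fraction
        Each call must be overlapped over more than this fraction of its
        own length (reciprocal criterion, strict inequality).
    min_length / max_length
        Inclusive bounds on the overlapped section (1 kb .. 3 Mb).
    max_calls_per_sample
        A sample is excluded when any caller in ``qc_callers`` reports
        strictly more raw calls than this.
    deletion_max_cn / amplification_min_cn
        Copy-number thresholds classifying a call as loss / gain; copy
        number 2 is neutral and never enters consensus.
    overlap_denominator
        ``"reciprocal"`` (default), ``"either"`` (fraction of at least one
        call), or ``"union"`` (fraction of the union span) — the source
        text does not name the denominator, so the choice is exposed.
    """

    min_overlap_fraction: float = 0.5
    min_length: int = 1_000
    max_length: int = 3_000_000
    max_calls_per_sample: int = 35
    deletion_max_cn: int = 1
    amplification_min_cn: int = 3
    qc_callers: tuple[str, ...] = ("A", "B")
    overlap_denominator: str = "reciprocal"

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")
        if not (self.deletion_max_cn < 2 < self.amplification_min_cn):
            raise ValueError("copy-number thresholds must bracket the neutral state 2")
        if self.overlap_denominator not in ("reciprocal", "either", "union"):
            raise ValueError("overlap_denominator must be reciprocal, either or union")


def classify_call(call: CnvCall, config: ConsensusConfig = ConsensusConfig()) -> str:
    """Classify a raw call as deletion, amplification or neutral."""
    if call.copy_number <= config.deletion_max_cn:
        return DELETION
    if call.copy_number >= config.amplification_min_cn:
        return AMPLIFICATION
    return NEUTRAL


def sample_qc(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    config: ConsensusConfig = ConsensusConfig(),
) -> tuple[list[str], dict[str, str]]:
    """Exclude samples in which any QC-checked caller reports more than
    ``max_calls_per_sample`` raw calls.

    Returns ``(retained sample ids, {excluded id: reason})``.
    """
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for sample in sorted(calls_by_sample):
        counts: dict[str, int] = defaultdict(int)
        for call in calls_by_sample[sample]:
            counts[call.caller] += 1
        over = [
            (caller, counts[caller])
            for caller in config.qc_callers
            if counts[caller] > config.max_calls_per_sample
        ]
        if over:
            caller, n = over[0]
            excluded[sample] = (
                f"caller {caller} reported {n} calls (> {config.max_calls_per_sample})"
            )
        else:
            retained.append(sample)
    return retained, excluded


def _overlap_ok(ov: int, len_a: int, len_b: int, config: ConsensusConfig) -> bool:
    f = config.min_overlap_fraction
    if config.overlap_denominator == "reciprocal":
        return ov > f * len_a and ov > f * len_b
    if config.overlap_denominator == "either":
        return ov > f * len_a or ov > f * len_b
    union = len_a + len_b - ov
    return ov > f * union


def match_calls(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    config: ConsensusConfig = ConsensusConfig(),
) -> list[ConsensusEvent]:
    """Pair one sample's calls from the two callers into consensus events.

    A pair is admissible iff it is on one chromosome, both calls have the
    same non-neutral direction, the overlap exceeds the configured fraction
    of each call's length, and the overlapped section is within the length
    window.  Among admissible pairs a one-to-one matching maximising the
    total overlapped length is chosen (assignment problem); each call joins
    at most one event and the event interval is the intersection.
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"match_calls received calls from multiple samples: {sorted(samples)}")
    events: list[ConsensusEvent] = []
    chroms = sorted(
        {c.chrom for c in calls_a} & {c.chrom for c in calls_b}, key=chrom_sort_key
    )
    for chrom in chroms:
        sub_a = [
            c
            for c in calls_a
            if c.chrom == chrom and classify_call(c, config) != NEUTRAL
        ]
        sub_b = [
            c
            for c in calls_b
            if c.chrom == chrom and classify_call(c, config) != NEUTRAL
        ]
        if not sub_a or not sub_b:
            continue
        sub_a.sort(key=lambda c: (c.start, c.end))
        sub_b.sort(key=lambda c: (c.start, c.end))
        weights = np.zeros((len(sub_a), len(sub_b)))
        for i, a in enumerate(sub_a):
            ta = classify_call(a, config)
            for j, b in enumerate(sub_b):
                if classify_call(b, config) != ta:
                    continue
                ov_start = max(a.start, b.start)
                ov_end = min(a.end, b.end)
                ov = ov_end - ov_start + 1
                if ov <= 0:
                    continue
                if not _overlap_ok(ov, a.length, b.length, config):
                    continue
                if not (config.min_length <= ov <= config.max_length):
                    continue
                weights[i, j] = ov
        if not weights.any():
            continue
        rows, cols = linear_sum_assignment(weights, maximize=True)
        for i, j in zip(rows, cols):
            if weights[i, j] <= 0:
                continue
            a, b = sub_a[i], sub_b[j]
            events.append(
                ConsensusEvent(
                    sample_id=a.sample_id,
                    chrom=chrom,
                    start=max(a.start, b.start),
                    end=min(a.end, b.end),
                    cnv_type=classify_call(a, config),
                    source_a=a,
                    source_b=b,
                )
            )
    events.sort(key=lambda e: (chrom_sort_key(e.chrom), e.start, e.end))
    return events


def filter_events(
    events: Sequence[ConsensusEvent],
    centromeres: AnnotationTrack,
    config: ConsensusConfig = ConsensusConfig(),
) -> list[ConsensusEvent]:
    """Drop events overlapping a centromere or outside the length window.

    The length window is a redundant guard after :func:`match_calls`; the
    centromere filter reflects the sparse SNP coverage of centromeric
    regions, where calls are unreliable.
    """
    retained: list[ConsensusEvent] = []
    for ev in events:
        if ev.chrom not in centromeres.intervals:
            raise ValueError(f"chromosome {ev.chrom!r} missing from centromere track")
        if not (config.min_length <= ev.length <= config.max_length):
            continue
        hits_cen = any(
            ev.start <= cen_end and cen_start <= ev.end
            for cen_start, cen_end, _ in centromeres.intervals[ev.chrom]
        )
        if hits_cen:
            continue
        retained.append(ev)
    return retained


def call_consensus(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    centromeres: Optional[AnnotationTrack] = None,
    config: ConsensusConfig = ConsensusConfig(),
) -> tuple[list[ConsensusEvent], dict[str, str]]:
    """Full per-cohort consensus stage: sample QC, per-sample matching and
    event filtering.

    Returns ``(events, excluded samples with reasons)``.
    """
    by_sample: dict[str, list[CnvCall]] = defaultdict(list)
    for call in list(calls_a) + list(calls_b):
        by_sample[call.sample_id].append(call)
    retained, excluded = sample_qc(by_sample, config)
    events: list[ConsensusEvent] = []
    for sample in retained:
        sample_a = [c for c in by_sample[sample] if c.caller == "A"]
        sample_b = [c for c in by_sample[sample] if c.caller == "B"]
        events.extend(match_calls(sample_a, sample_b, config))
    if centromeres is not None:
        events = filter_events(events, centromeres, config)
    if excluded:
        logger.info("sample QC excluded %d samples", len(excluded))
    events.sort(key=lambda e: (chrom_sort_key(e.chrom), e.start, e.end, e.sample_id))
    return events, excluded
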