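"""Population-level CNV summaries, length contrasts, annotation-overlap
statistics and chromosomal zone-density analysis.

The annotation operations work on arbitrary interval tracks (genes,
segmental duplications, reported-CNV catalogues, centromeres).  Enrichment
questions are answered by seeded randomization tests that place length-
matched random intervals, stratified by local SNP density where the
array's probe spacing would otherwise confound the comparison.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .model import (
    AMPLIFICATION,
    DELETION,
    AnnotationTrack,
    Cnvr,
    ConsensusEvent,
    Panel,
    SnpMap,
    chrom_sort_key,
)

Region = Union[Cnvr, ConsensusEvent]

PERI_TELOMERIC = "peri_telomeric"
SUB_CENTROMERIC = "sub_centromeric"
REST = "rest"


@dataclass(frozen=True)
class PopulationSummary:
    """Per-population CNV characteristics (the cohort-description table).

    All derived fields are stored at full precision; :meth:`report` rounds
    to the conventional printed precision (percent to 1 dp, per-person and
    per-carrier ratios to 2 dp, mean length to 1 dp kb).
    """

    population: str
    sample_size: int
    carrier_count: int
    cnv_count: int
    amplification_count: int
    deletion_count: int
    mean_length_kb: float
    carrier_percent: float
    cnvs_per_person: float

    @classmethod
    def from_counts(
        cls,
        population: str,
        sample_size: int,
        carrier_count: int,
        cnv_count: int,
        amplification_count: int,
        deletion_count: int,
        mean_length_kb: float = float("nan"),
    ) -> "PopulationSummary":
        if carrier_count > sample_size:
            raise ValueError("carrier_count exceeds sample_size")
        if amplification_count + deletion_count != cnv_count:
            raise ValueError("amplifications + deletions must equal cnv_count")
        return cls(
            population=population,
            sample_size=sample_size,
            carrier_count=carrier_count,
            cnv_count=cnv_count,
            amplification_count=amplification_count,
            deletion_count=deletion_count,
            mean_length_kb=mean_length_kb,
            carrier_percent=100.0 * carrier_count / sample_size if sample_size else 0.0,
            cnvs_per_person=cnv_count / sample_size if sample_size else 0.0,
        )

    @property
    def cnvs_per_carrier(self) -> float:
        return self.cnv_count / self.carrier_count if self.carrier_count else 0.0

    def report(self) -> dict[str, object]:
        return {
            "population": self.population,
            "sample_size": self.sample_size,
            "carrier_count": self.carrier_count,
            "carrier_percent": round(self.carrier_percent, 1),
            "cnv_count": self.cnv_count,
            "cnvs_per_person": round(self.cnvs_per_person, 2),
            "cnvs_per_carrier": round(self.cnvs_per_carrier, 2),
            "amplification_count": self.amplification_count,
            "deletion_count": self.deletion_count,
            "mean_length_kb": round(self.mean_length_kb, 1),
        }


def summarize_population(
    events: Sequence[ConsensusEvent],
    panel: Panel,
    population: str = "combined",
) -> PopulationSummary:
    """Summary statistics for one population, or ``"combined"`` for the
    whole panel."""
    if population == "combined":
        samples = set(panel.samples())
    else:
        samples = set(panel.samples(population))  # raises on unknown label
    sub = [e for e in events if e.sample_id in samples]
    for e in sub:
        if e.sample_id not in panel:
            raise KeyError(f"event sample {e.sample_id!r} not in panel")
    carriers = {e.sample_id for e in sub}
    amps = sum(1 for e in sub if e.cnv_type == AMPLIFICATION)
    dels = sum(1 for e in sub if e.cnv_type == DELETION)
    mean_len = float(np.mean([e.length for e in sub]) / 1_000) if sub else 0.0
    return PopulationSummary.from_counts(
        population=population,
        sample_size=len(samples),
        carrier_count=len(carriers),
        cnv_count=len(sub),
        amplification_count=amps,
        deletion_count=dels,
        mean_length_kb=mean_len,
    )


def length_contrast(
    events: Sequence[ConsensusEvent],
) -> tuple[float, float, float]:
    """Mean lengths (kb) of amplifications and deletions with a two-sided
    Mann-Whitney U p-value for the length difference."""
    amp = np.array([e.length for e in events if e.cnv_type == AMPLIFICATION], dtype=float)
    dele = np.array([e.length for e in events if e.cnv_type == DELETION], dtype=float)
    if amp.size == 0 or dele.size == 0:
        raise ValueError("length_contrast needs at least one event of each type")
    res = stats.mannwhitneyu(amp, dele, alternative="two-sided")
    return float(amp.mean() / 1_000), float(dele.mean() / 1_000), float(res.pvalue)


@dataclass(frozen=True)
class TrackOverlapResult:
    """Per-region overlap flags against an annotation track."""

    flags: dict[str, bool]
    overlap_bp: dict[str, int]
    n_overlapping: int
    total_bp: int


def _region_id(region: Region, idx: int) -> str:
    return region.cnvr_id if isinstance(region, Cnvr) else f"event{idx}"


def _merged_trees(track: AnnotationTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom in track.intervals:
        tree = IntervalTree.from_tuples(
            (s, e + 1) for s, e, _ in track.intervals[chrom]
        )
        tree.merge_overlaps()
        trees[chrom] = tree
    return trees


def track_overlap(
    regions: Sequence[Region],
    track: AnnotationTrack,
    min_bp: int = 1,
) -> TrackOverlapResult:
    """Flag regions overlapping a track by at least ``min_bp`` bases and
    report the per-region and total overlapped base count."""
    trees = _merged_trees(track)
    flags: dict[str, bool] = {}
    overlap_bp: dict[str, int] = {}
    for idx, region in enumerate(regions):
        rid = _region_id(region, idx)
        tree = trees.get(region.chrom)
        ov = 0
        if tree is not None:
            for hit in tree.overlap(region.start, region.end + 1):
                ov += min(hit.end - 1, region.end) - max(hit.begin, region.start) + 1
        flags[rid] = ov >= min_bp
        overlap_bp[rid] = ov
    return TrackOverlapResult(
        flags=flags,
        overlap_bp=overlap_bp,
        n_overlapping=sum(flags.values()),
        total_bp=sum(overlap_bp.values()),
    )


def segdup_classification(
    regions: Sequence[Region],
    segdups: AnnotationTrack,
    hotspot_span: int = 10_000_000,
) -> dict[str, str]:
    """Classify each region's relation to segmental duplications (SDs):
    ``overlaps_sd``, ``between_sds`` (inside the gap between two SDs closer
    than ``hotspot_span`` on the same chromosome — a putative rearrangement
    hotspot), or ``outside``."""
    merged = {chrom: segdups.merged(chrom) for chrom in segdups.intervals}
    gaps: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, ivs in merged.items():
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 - e1 - 1 <= hotspot_span:
                gaps[chrom].append((e1 + 1, s2 - 1))
    out: dict[str, str] = {}
    for idx, region in enumerate(regions):
        rid = _region_id(region, idx)
        sd_hit = any(
            region.start <= e and s <= region.end
            for s, e in merged.get(region.chrom, [])
        )
        if sd_hit:
            out[rid] = "overlaps_sd"
        elif any(
            region.start <= e and s <= region.end for s, e in gaps.get(region.chrom, [])
        ):
            out[rid] = "between_sds"
        else:
            out[rid] = "outside"
    return out


def _snp_density_bins(
    snp_map: SnpMap, bin_size: int = 1_000_000
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Bin each chromosome's SNP-mapped extent and compute per-bin SNP
    density terciles (genome-wide tercile edges)."""
    edges_by_chrom: dict[str, np.ndarray] = {}
    counts_by_chrom: dict[str, np.ndarray] = {}
    all_counts = []
    for chrom in snp_map.chromosomes():
        lo, hi = snp_map.extent(chrom)
        edges = np.arange(lo, hi + bin_size, bin_size, dtype=np.int64)
        if edges[-1] <= hi:
            edges = np.append(edges, hi + 1)
        counts = np.diff(np.searchsorted(snp_map.positions[chrom], edges))
        edges_by_chrom[chrom] = edges
        counts_by_chrom[chrom] = counts
        all_counts.append(counts)
    pooled = np.concatenate(all_counts)
    tercile_edges = np.quantile(pooled, [1 / 3, 2 / 3])
    return edges_by_chrom, counts_by_chrom, tercile_edges


def _gene_counts(
    regions: Sequence[tuple[str, int, int]],
    gene_starts: dict[str, np.ndarray],
    gene_ends: dict[str, np.ndarray],
) -> np.ndarray:
    out = np.zeros(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        starts = gene_starts.get(chrom)
        if starts is None:
            continue
        ends = gene_ends[chrom]
        # genes overlapping [start, end]: start_g <= end and end_g >= start
        out[i] = np.searchsorted(starts, end, side="right") - np.searchsorted(
            ends, start, side="left"
        )
    return out


def gene_content_test(
    events: Sequence[Region],
    genes: AnnotationTrack,
    snp_map: SnpMap,
    n_random: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed mean gene count per CNV versus a length-matched random
    placement null, stratified by local SNP-density tercile.

    Each null replicate re-places every event on its own chromosome, in a
    1 Mb bin drawn from the bins of the same SNP-density tercile (the
    array's probe density confounds gene content, so placements are
    matched on it).  p is the fraction of null mean gene counts >= the
    observed mean.
    """
    rng = np.random.default_rng(seed)
    for ev in events:
        if ev.chrom not in snp_map.positions:
            raise ValueError(f"chromosome {ev.chrom!r} absent from SNP map")
    gene_starts = {
        chrom: np.array(sorted(s for s, _, _ in ivs), dtype=np.int64)
        for chrom, ivs in genes.intervals.items()
    }
    gene_ends = {
        chrom: np.array(sorted(e for _, e, _ in ivs), dtype=np.int64)
        for chrom, ivs in genes.intervals.items()
    }
    observed = _gene_counts(
        [(e.chrom, e.start, e.end) for e in events], gene_starts, gene_ends
    )
    obs_mean = float(observed.mean()) if len(events) else 0.0

    edges_by_chrom, counts_by_chrom, terc = _snp_density_bins(snp_map)
    # bins of each tercile per chromosome
    bins_by_stratum: dict[tuple[str, int], np.ndarray] = {}
    for chrom, counts in counts_by_chrom.items():
        strata = np.digitize(counts, terc)
        for t in range(3):
            idx = np.nonzero(strata == t)[0]
            if idx.size:
                bins_by_stratum[(chrom, t)] = idx

    ev_meta = []
    for ev in events:
        edges = edges_by_chrom[ev.chrom]
        mid = ev.midpoint
        b = int(np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(edges) - 2))
        stratum = int(np.digitize(counts_by_chrom[ev.chrom][b], terc))
        candidates = bins_by_stratum.get((ev.chrom, stratum))
        if candidates is None:
            candidates = np.arange(len(edges) - 1)
        ev_meta.append((ev.chrom, ev.length, candidates))

    null_means = np.empty(n_random)
    for rep in range(n_random):
        placed = []
        for chrom, length, candidates in ev_meta:
            edges = edges_by_chrom[chrom]
            b = int(rng.choice(candidates))
            mid = int(rng.integers(edges[b], edges[b + 1]))
            lo, hi = snp_map.extent(chrom)
            start = max(lo, mid - length // 2)
            end = min(hi, start + length - 1)
            start = max(lo, end - length + 1)
            placed.append((chrom, start, end))
        null_means[rep] = _gene_counts(placed, gene_starts, gene_ends).mean() if placed else 0.0
    p = float(np.mean(null_means >= obs_mean)) if n_random else 1.0
    return obs_mean, p


@dataclass(frozen=True)
class ZoneDensity:
    zone: str
    span_bp: int
    event_count: int

    @property
    def density_per_mb(self) -> float:
        return self.event_count / (self.span_bp / 1_000_000) if self.span_bp else 0.0


def _subtract(intervals: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set-difference of sorted, disjoint 1-based inclusive interval lists."""
    out = []
    for s, e in intervals:
        cur = s
        for ms, me in minus:
            if me < cur or ms > e:
                continue
            if ms > cur:
                out.append((cur, min(e, ms - 1)))
            cur = max(cur, me + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


def zone_density(
    events: Sequence[ConsensusEvent],
    snp_map: SnpMap,
    centromeres: AnnotationTrack,
    zone_width: int = 10_000_000,
) -> list[ZoneDensity]:
    """Event density (per Mb) in peri-telomeric and sub-centromeric zones
    versus the rest of the SNP-mapped genome.

    Peri-telomeric zones extend ``zone_width`` inward from the most distal
    SNP at each chromosome end; sub-centromeric zones extend ``zone_width``
    from the SNPs closest to the centromere on each side.  Zones are
    clipped to the SNP-mapped extent (with a warning when truncated) and
    peri-telomeric assignment takes precedence where zones collide.
    Events are assigned to zones by their midpoint.
    """
    tel: dict[str, list[tuple[int, int]]] = {}
    cen: dict[str, list[tuple[int, int]]] = {}
    rest: dict[str, list[tuple[int, int]]] = {}
    for chrom in snp_map.chromosomes():
        if chrom not in centromeres.intervals:
            raise ValueError(f"chromosome {chrom!r} missing from centromere track")
        lo, hi = snp_map.extent(chrom)
        if 2 * zone_width > hi - lo + 1:
            warnings.warn(
                f"chromosome {chrom}: zone width {zone_width} exceeds the mapped arm; truncating"
            )
        t1 = (lo, min(lo + zone_width - 1, hi))
        t2 = (max(hi - zone_width + 1, lo), hi)
        tel_iv = [t1] if t2[0] <= t1[1] else [t1, t2]
        tel[chrom] = tel_iv
        cen_start, cen_end, _ = centromeres.intervals[chrom][0]
        pos = snp_map.positions[chrom]
        cen_iv: list[tuple[int, int]] = []
        left = pos[pos < cen_start]
        if left.size:
            anchor = int(left[-1])
            cen_iv.append((max(lo, anchor - zone_width + 1), anchor))
        right = pos[pos > cen_end]
        if right.size:
            anchor = int(right[0])
            cen_iv.append((anchor, min(hi, anchor + zone_width - 1)))
        cen_iv = _subtract(sorted(cen_iv), tel_iv)
        cen[chrom] = cen_iv
        rest[chrom] = _subtract([(lo, hi)], sorted(tel_iv + cen_iv))

    spans = {PERI_TELOMERIC: 0, SUB_CENTROMERIC: 0, REST: 0}
    counts = {PERI_TELOMERIC: 0, SUB_CENTROMERIC: 0, REST: 0}
    for zone, table in ((PERI_TELOMERIC, tel), (SUB_CENTROMERIC, cen), (REST, rest)):
        for ivs in table.values():
            spans[zone] += sum(e - s + 1 for s, e in ivs)
    for ev in events:
        mid = ev.midpoint
        for zone, table in ((PERI_TELOMERIC, tel), (SUB_CENTROMERIC, cen), (REST, rest)):
            if any(s <= mid <= e for s, e in table.get(ev.chrom, [])):
                counts[zone] += 1
                break
    return [
        ZoneDensity(zone=z, span_bp=spans[z], event_count=counts[z])
        for z in (PERI_TELOMERIC, SUB_CENTROMERIC, REST)
    ]


def snp_density_contrast(
    snp_map: SnpMap,
    cnvrs: Sequence[Cnvr],
    n_perm: int = 1_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """SNP density (per Mb) inside versus outside CNVRs, with a two-sided
    permutation p-value from length-preserving random re-placement of the
    CNVRs on their chromosomes."""
    if not cnvrs:
        raise ValueError("snp_density_contrast needs a non-empty CNVR set")
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for c in cnvrs:
        by_chrom[c.chrom].append((c.start, c.end))
    extents = {chrom: snp_map.extent(chrom) for chrom in snp_map.chromosomes()}

    def merged_union(table: dict[str, list[tuple[int, int]]]) -> dict[str, list[tuple[int, int]]]:
        out = {}
        for chrom, ivs in table.items():
            lo, hi = extents[chrom]
            clipped = [(max(s, lo), min(e, hi)) for s, e in sorted(ivs)]
            merged: list[tuple[int, int]] = []
            for s, e in clipped:
                if s > e:
                    continue
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            out[chrom] = merged
        return out

    def statistic(table: dict[str, list[tuple[int, int]]]) -> tuple[float, float, float]:
        union = merged_union(table)
        in_bp = in_snps = 0
        total_bp = total_snps = 0
        for chrom, (lo, hi) in extents.items():
            total_bp += hi - lo + 1
            total_snps += len(snp_map.positions[chrom])
            for s, e in union.get(chrom, []):
                in_bp += e - s + 1
                in_snps += snp_map.count_in(chrom, s, e)
        out_bp = total_bp - in_bp
        if in_bp <= 0 or out_bp <= 0:
            raise ValueError("CNVRs cover none or all of a chromosome's mapped extent")
        d_in = in_snps / (in_bp / 1e6)
        d_out = (total_snps - in_snps) / (out_bp / 1e6)
        return d_in, d_out, d_in - d_out

    d_in, d_out, obs = statistic(by_chrom)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        placed: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for c in cnvrs:
            lo, hi = extents[c.chrom]
            length = min(c.length, hi - lo + 1)
            start = int(rng.integers(lo, hi - length + 2))
            placed[c.chrom].append((start, start + length - 1))
        _, _, stat = statistic(placed)
        if abs(stat) >= abs(obs):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(d_in), float(d_out), float(p)
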