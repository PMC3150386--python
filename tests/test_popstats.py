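import numpy as np
import pytest
from scipy import stats

from cnvpop.model import AnnotationTrack, Cnvr, ConsensusEvent, Panel, SnpMap
from cnvpop.popstats import (
    PopulationSummary,
    gene_content_test,
    length_contrast,
    segdup_classification,
    snp_density_contrast,
    summarize_population,
    track_overlap,
    zone_density,
)


def event(start, end, sample="s1", cnv_type="deletion", chrom="1"):
    return ConsensusEvent(sample, chrom, start, end, cnv_type)


def region(cid, start, end, chrom="1"):
    return Cnvr(cid, chrom, start, end, (), "deletion_only", frozenset({"s1"}))


class TestPopulationSummary:
    def test_arithmetic_identities(self):
        s = PopulationSummary.from_counts("combined", 2789, 1964, 4016, 2160, 1856, 205.1)
        assert s.carrier_percent == pytest.approx(100 * 1964 / 2789)
        assert s.cnvs_per_person == pytest.approx(4016 / 2789)
        assert s.cnvs_per_carrier == pytest.approx(4016 / 1964)
        rep = s.report()
        assert rep["carrier_percent"] == 70.4
        assert rep["cnvs_per_person"] == 1.44

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            PopulationSummary.from_counts("x", 10, 5, 7, 3, 3)
        with pytest.raises(ValueError):
            PopulationSummary.from_counts("x", 10, 11, 2, 1, 1)

    def test_summarize_from_events(self):
        panel = Panel({"a": "pop1", "b": "pop1", "c": "pop2"})
        events = [
            event(1_000, 3_000, "a", "deletion"),
            event(5_000, 9_000, "a", "amplification"),
            event(1_000, 3_000, "c", "deletion"),
        ]
        s = summarize_population(events, panel, "pop1")
        assert (s.sample_size, s.carrier_count, s.cnv_count) == (2, 1, 2)
        assert (s.amplification_count, s.deletion_count) == (1, 1)
        assert s.mean_length_kb == pytest.approx((2001 + 4001) / 2 / 1000)
        combined = summarize_population(events, panel)
        assert combined.cnv_count == 3

    def test_zero_events_all_zero(self):
        panel = Panel({"a": "pop1"})
        s = summarize_population([], panel, "pop1")
        assert (s.cnv_count, s.carrier_count, s.carrier_percent, s.mean_length_kb) == (0, 0, 0.0, 0.0)

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError):
            summarize_population([], Panel({"a": "pop1"}), "nowhere")


class TestLengthContrast:
    def test_single_pair_closed_form(self):
        # n1 = n2 = 1: U statistic in {0, 1}; exact two-sided p = 1
        amp_kb, del_kb, p = length_contrast(
            [event(1, 2_000, cnv_type="amplification"), event(1, 1_000, cnv_type="deletion")]
        )
        assert (amp_kb, del_kb) == (2.0, 1.0)
        assert p == pytest.approx(1.0)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(10_000, 500_000, 200)
        events = [
            event(1, int(l), sample=f"s{i}", cnv_type=t)
            for i, l in enumerate(lengths)
            for t in ("amplification", "deletion")
        ]
        _, _, p = length_contrast(events)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            dels = rng.exponential(150_000, 200).astype(int) + 1_000
            amps = dels + 100_000  # +100 kb shift
            events = [event(1, int(l), cnv_type="deletion") for l in dels]
            events += [event(1, int(l), cnv_type="amplification") for l in amps]
            _, _, p = length_contrast(events)
            hits += p < 0.01
        assert hits >= 19

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError):
            length_contrast([event(1, 2_000, cnv_type="deletion")])


class TestTrackOverlap:
    track = AnnotationTrack("dgv", [("1", 10_000, 20_000, None), ("1", 30_000, 40_000, None)])

    def test_contained_region_fully_overlapped(self):
        res = track_overlap([region("r1", 12_000, 15_000)], self.track)
        assert res.flags["r1"] and res.overlap_bp["r1"] == 3_001
        assert (res.n_overlapping, res.total_bp) == (1, 3_001)

    def test_adjacent_region_not_flagged(self):
        res = track_overlap([region("r1", 20_001, 25_000)], self.track)
        assert not res.flags["r1"] and res.overlap_bp["r1"] == 0

    def test_bitmap_oracle_agreement(self):
        rng = np.random.default_rng(3)
        size = 100_000
        ivs = sorted(
            (int(s), int(s + l)) for s, l in zip(rng.integers(1, size - 500, 40), rng.integers(10, 500, 40))
        )
        track = AnnotationTrack("t", [("1", s, e, None) for s, e in ivs])
        bitmap = np.zeros(size + 1000, dtype=bool)
        for s, e in ivs:
            bitmap[s : e + 1] = True
        regions = [
            region(f"r{i}", int(s), int(s + l))
            for i, (s, l) in enumerate(zip(rng.integers(1, size, 200), rng.integers(5, 2_000, 200)))
        ]
        res = track_overlap(regions, track)
        for r in regions:
            expected = int(bitmap[r.start : r.end + 1].sum())
            assert res.overlap_bp[r.cnvr_id] == expected
            assert res.flags[r.cnvr_id] == (expected >= 1)

    def test_generated_overlap_rate_recovered(self):
        """Events generated inside track intervals at a set rate are
        recovered at that rate."""
        rng = np.random.default_rng(4)
        rate = 0.941
        track = AnnotationTrack("dgv", [("1", int(s), int(s) + 50_000, None) for s in np.arange(1, 4e7, 1e6)])
        regions = []
        for i in range(2_000):
            if rng.random() < rate:
                base = int(rng.choice(np.arange(1, 4e7, 1e6)))
                start = int(rng.integers(base, base + 45_000))
            else:
                base = int(rng.choice(np.arange(1, 4e7, 1e6))) + 60_000
                start = int(rng.integers(base, base + 900_000))
            regions.append(region(f"r{i}", start, start + 4_000))
        res = track_overlap(regions, track)
        assert res.n_overlapping / len(regions) == pytest.approx(rate, abs=0.02)


class TestSegdupClassification:
    def test_three_way_classification(self):
        sds = AnnotationTrack("sd", [("1", 1_000_000, 1_100_000, None), ("1", 3_000_000, 3_100_000, None)])
        regions = [
            region("in_sd", 1_050_000, 1_200_000),
            region("between", 1_500_000, 1_600_000),
            region("outside", 50_000_000, 50_100_000),
        ]
        out = segdup_classification(regions, sds, hotspot_span=10_000_000)
        assert out == {"in_sd": "overlaps_sd", "between": "between_sds", "outside": "outside"}

    def test_distant_sds_do_not_make_hotspot(self):
        sds = AnnotationTrack("sd", [("1", 1_000_000, 1_100_000, None), ("1", 60_000_000, 60_100_000, None)])
        out = segdup_classification([region("mid", 30_000_000, 30_100_000)], sds, hotspot_span=10_000_000)
        assert out["mid"] == "outside"


def uniform_snp_map(rng, length=50_000_000, n=5_000, chrom="1"):
    return SnpMap({chrom: np.sort(rng.choice(np.arange(1, length, dtype=np.int64), n, replace=False))})


class TestGeneContent:
    def test_empty_gene_track(self):
        rng = np.random.default_rng(0)
        snp = uniform_snp_map(rng)
        events = [event(1_000_000, 1_050_000)]
        mean, p = gene_content_test(events, AnnotationTrack("genes", []), snp, n_random=50, seed=0)
        assert (mean, p) == (0.0, 1.0)

    def test_chromosome_missing_from_snp_map(self):
        rng = np.random.default_rng(0)
        snp = uniform_snp_map(rng)
        with pytest.raises(ValueError, match="absent"):
            gene_content_test(
                [event(1, 2_000, chrom="2")], AnnotationTrack("genes", []), snp, n_random=10, seed=0
            )

    def test_null_calibration_p_uniform(self):
        """Uniformly placed events give a uniform randomization p across
        generator seeds (the null is the conditional placement law)."""
        master = np.random.default_rng(5)
        snp = uniform_snp_map(master)
        genes = AnnotationTrack(
            "genes",
            [("1", int(s), int(s + 20_000), None) for s in master.integers(1, 49_000_000, 400)],
        )
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(1_000 + seed)
            events = [
                event(int(s), int(s + l), sample=f"s{i}")
                for i, (s, l) in enumerate(
                    zip(rng.integers(1, 49_000_000, 120), rng.integers(20_000, 300_000, 120))
                )
            ]
            _, p = gene_content_test(events, genes, snp, n_random=150, seed=seed)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_gene_enrichment_detected(self):
        master = np.random.default_rng(6)
        snp = uniform_snp_map(master)
        gene_starts = master.integers(1, 49_000_000, 400)
        genes = AnnotationTrack("genes", [("1", int(s), int(s + 20_000), None) for s in gene_starts])
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(2_000 + seed)
            events = []
            for i in range(300):
                if rng.random() < 0.75:  # preferentially inside genes
                    s = int(rng.choice(gene_starts))
                else:
                    s = int(rng.integers(1, 49_000_000))
                events.append(event(s, s + int(rng.integers(20_000, 120_000)), sample=f"s{i}"))
            _, p = gene_content_test(events, genes, snp, n_random=200, seed=seed)
            hits += p < 0.05
        assert hits >= 9


class TestZoneDensity:
    CEN = AnnotationTrack("centromeres", [("1", 24_000_000, 26_000_000, "cen")])

    def snp_map(self):
        return SnpMap({"1": np.arange(1, 50_000_001, 10_000)})

    def test_telomeric_pileup_detected(self):
        snp = self.snp_map()
        events = [event(int(s), int(s) + 50_000, sample=f"s{i}") for i, s in enumerate(range(1, 5_000_000, 100_000))]
        zones = {z.zone: z for z in zone_density(events, snp, self.CEN)}
        assert zones["peri_telomeric"].density_per_mb > zones["rest"].density_per_mb
        assert zones["peri_telomeric"].event_count == len(events)

    def test_uniform_events_equal_density(self):
        snp = self.snp_map()
        rng = np.random.default_rng(9)
        events = [
            event(int(s), int(s) + 10_000, sample=f"s{i}")
            for i, s in enumerate(rng.integers(1, 49_900_000, 2_000))
        ]
        zones = {z.zone: z for z in zone_density(events, snp, self.CEN)}
        ratio = zones["peri_telomeric"].density_per_mb / zones["rest"].density_per_mb
        assert 0.8 <= ratio <= 1.2
        # zone spans partition the mapped extent
        lo, hi = snp.extent("1")
        assert sum(z.span_bp for z in zones.values()) == hi - lo + 1

    def test_no_events_zero_densities(self):
        zones = zone_density([], self.snp_map(), self.CEN)
        assert all(z.event_count == 0 and z.density_per_mb == 0 for z in zones)

    def test_narrow_chromosome_warns(self):
        snp = SnpMap({"1": np.arange(1, 12_000_000, 10_000)})
        with pytest.warns(UserWarning, match="truncating"):
            zone_density([], snp, self.CEN)


class TestSnpDensityContrast:
    def test_uniform_snps_no_contrast(self):
        rng = np.random.default_rng(10)
        snp = uniform_snp_map(rng, length=200_000_000, n=10_000)
        cnvrs = [
            region(f"r{i}", int(s), int(s) + 500_000)
            for i, s in enumerate(rng.integers(1, 199_000_000, 50))
        ]
        d_in, d_out, p = snp_density_contrast(snp, cnvrs, n_perm=200, seed=0)
        assert d_in == pytest.approx(d_out, rel=0.10)
        assert p > 0.05

    def test_enriched_snps_detected(self):
        rng = np.random.default_rng(20)
        cnvr_starts = rng.integers(1, 190_000_000, 50)
        cnvrs = [region(f"r{i}", int(s), int(s) + 500_000) for i, s in enumerate(cnvr_starts)]
        inside = np.concatenate([rng.integers(s, s + 500_000, 40) for s in cnvr_starts])
        outside = rng.integers(1, 200_000_000, 10_000)
        snp = SnpMap({"1": np.concatenate([inside, outside])})
        d_in, d_out, p = snp_density_contrast(snp, cnvrs, n_perm=200, seed=1)
        assert d_in > 1.3 * d_out
        assert p < 0.05

    def test_empty_cnvr_list_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            snp_density_contrast(uniform_snp_map(rng), [], n_perm=10)

    def test_chromosome_fully_covered_rejected(self):
        snp = SnpMap({"1": [100, 200, 300]})
        with pytest.raises(ValueError, match="all of a chromosome"):
            snp_density_contrast(snp, [region("r1", 1, 1_000)], n_perm=10)
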