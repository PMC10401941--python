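"""Occupancy totals, ranking, the ZTNB peak caller, site fold changes."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cernakit import SimConfig, generate_clip_reads, generate_transcriptome
from cernakit.intervals import (
    Annotation,
    AnnotationSet,
    GenomicInterval,
    ReadSet,
)
from cernakit.occupancy import (
    annotation_read_totals,
    call_peaks,
    class_median_ratio,
    peak_density_percentiles,
    rank_by_occupancy,
    site_coverage_fold_change,
)


def _ann(id_, start, end, cls="lncRNA"):
    return Annotation(GenomicInterval("c", start, end, "+", id_), cls, id_)


class TestAnnotationTotals:
    def test_simple_assignment(self):
        anns = AnnotationSet(
            [_ann("A", 0, 100), _ann("B", 200, 300), _ann("C", 400, 500)]
        )
        reads = ReadSet(
            [
                GenomicInterval("c", 10, 40),
                GenomicInterval("c", 50, 80),
                GenomicInterval("c", 60, 90),
                GenomicInterval("c", 250, 280),
            ]
        )
        table = annotation_read_totals(reads, anns)
        totals = dict(zip(table["annotation_id"], table["total_reads"]))
        assert totals == {"A": 3, "B": 1, "C": 0}

    def test_full_mask_zeroes_annotation(self):
        anns = AnnotationSet([_ann("A", 0, 100)])
        reads = ReadSet([GenomicInterval("c", 10, 40)])
        table = annotation_read_totals(
            reads, anns, mask=[GenomicInterval("c", 0, 100)]
        )
        assert table.loc[0, "total_reads"] == 0
        assert table.loc[0, "masked_length"] == 100

    def test_matches_per_read_oracle_randomized(self, rng):
        for _ in range(100):
            anns = AnnotationSet(
                [_ann(f"a{i}", i * 120, i * 120 + 100) for i in range(5)]
            )
            starts = rng.integers(0, 650, 60)
            lens = rng.integers(5, 50, 60)
            ivs = [GenomicInterval("c", int(s), int(s + l)) for s, l in zip(starts, lens)]
            reads = ReadSet(ivs)
            mask = [GenomicInterval("c", int(s), int(s) + 40) for s in rng.integers(0, 600, 3)]
            table = annotation_read_totals(reads, anns, mask=mask)
            from cernakit.intervals import subtract_intervals

            for _, row in table.iterrows():
                ann = next(a for a in anns if a.id == row["annotation_id"])
                pieces = subtract_intervals([ann.interval], mask)
                expect = sum(
                    1
                    for iv in ivs
                    if any(iv.overlap_length(p) >= 1 for p in pieces)
                )
                assert row["total_reads"] == expect

    def test_masking_monotone(self, rng):
        anns = AnnotationSet([_ann(f"a{i}", i * 150, i * 150 + 120) for i in range(4)])
        ivs = [
            GenomicInterval("c", int(s), int(s) + 30)
            for s in rng.integers(0, 600, 200)
        ]
        reads = ReadSet(ivs)
        plain = annotation_read_totals(reads, anns)
        masked = annotation_read_totals(
            reads, anns, mask=[GenomicInterval("c", 30, 90), GenomicInterval("c", 200, 260)]
        )
        assert (masked["total_reads"] <= plain["total_reads"]).all()


class TestRanking:
    def _table(self, totals):
        return pd.DataFrame(
            {
                "annotation_id": list(totals),
                "feature_class": "lncRNA",
                "total_reads": list(totals.values()),
                "length": 100,
                "masked_length": 0,
            }
        )

    def test_zero_rows_excluded_from_percentile(self):
        ranked = rank_by_occupancy(self._table({"A": 3, "B": 1, "C": 0}), "lncRNA")
        assert list(ranked["annotation_id"]) == ["A", "B", "C"]
        assert list(ranked["rank_within_class"]) == [1, 2, 3]
        assert ranked.attrs["n_nonzero"] == 2
        assert np.isnan(ranked.loc[2, "percentile_within_class"])

    def test_ties_break_lexicographically(self):
        ranked = rank_by_occupancy(self._table({"B": 5, "A": 5, "C": 5}), "lncRNA")
        assert list(ranked["annotation_id"]) == ["A", "B", "C"]

    def test_rank_one_percentile_is_100(self):
        totals = {f"x{i:05d}": 11_000 - i for i in range(11_000)}
        ranked = rank_by_occupancy(self._table(totals), "lncRNA")
        assert ranked.loc[0, "percentile_within_class"] == pytest.approx(100.0)

    def test_ranks_are_a_permutation(self, rng):
        totals = {f"g{i}": int(v) for i, v in enumerate(rng.integers(0, 20, 50))}
        ranked = rank_by_occupancy(self._table(totals), "lncRNA")
        assert sorted(ranked["rank_within_class"]) == list(range(1, 51))

    def test_absent_class_errors(self):
        with pytest.raises(ValueError, match="three_prime_UTR"):
            rank_by_occupancy(self._table({"A": 1}), "three_prime_UTR")


class TestClassMedianRatio:
    def _table(self, lnc, utr):
        rows = [
            {"annotation_id": f"l{i}", "feature_class": "lncRNA", "total_reads": v,
             "length": 100, "masked_length": 0}
            for i, v in enumerate(lnc)
        ] + [
            {"annotation_id": f"u{i}", "feature_class": "three_prime_UTR",
             "total_reads": v, "length": 100, "masked_length": 0}
            for i, v in enumerate(utr)
        ]
        return pd.DataFrame(rows)

    def test_worked_example(self):
        table = self._table([2, 4, 6], [8, 16, 64])
        assert class_median_ratio(table, "lncRNA", "three_prime_UTR") == pytest.approx(4.0)

    def test_identical_distributions(self):
        table = self._table([3, 5, 7], [3, 5, 7])
        assert class_median_ratio(table, "lncRNA", "three_prime_UTR") == pytest.approx(1.0)

    def test_zero_read_annotations_ignored(self):
        table = self._table([0, 0, 4], [0, 8])
        assert class_median_ratio(table, "lncRNA", "three_prime_UTR") == pytest.approx(2.0)

    def test_planted_fivefold_depth_recovered(self, rng):
        ratios = []
        for _ in range(20):
            lam = rng.lognormal(3.0, 0.5, 100)
            lnc = rng.poisson(lam)
            utr = rng.poisson(5 * rng.lognormal(3.0, 0.5, 100))
            table = self._table(list(lnc), list(utr))
            ratios.append(class_median_ratio(table, "lncRNA", "three_prime_UTR"))
        assert 4.0 <= float(np.mean(ratios)) <= 6.0


def reads_from_bin_counts(counts, region_start=0, bin_size=30, rng=None, contig="c"):
    """Place `counts[i]` read starts inside bin i (reads 30 nt long)."""
    starts = []
    for i, c in enumerate(counts):
        if c:
            lo = region_start + i * bin_size
            offs = (
                rng.integers(0, bin_size, int(c))
                if rng is not None
                else np.zeros(int(c), dtype=int)
            )
            starts.append(lo + offs)
    if starts:
        s = np.concatenate(starts)
    else:
        s = np.empty(0, dtype=np.int64)
    return ReadSet.from_arrays(contig, s, s + 30)


class TestPeakCaller:
    def test_single_hot_window(self):
        n_bins = 40
        counts = np.zeros(n_bins, dtype=int)
        counts[17] = 50
        counts[: 15] = 1  # sparse background so the fit has >= 10 positive bins
        reads = reads_from_bin_counts(counts)
        region = [GenomicInterval("c", 0, n_bins * 30, name="r")]
        peaks, model, bins = call_peaks(reads, region, bin_size=30, alpha=0.05)
        assert len(peaks) == 1
        assert peaks[0].interval.start == 17 * 30
        assert peaks[0].interval.end == 18 * 30
        assert peaks[0].reads_in_peak == 50

    def test_adjacent_significant_bins_merge(self):
        counts = np.ones(40, dtype=int)
        counts[20] = counts[21] = 60
        reads = reads_from_bin_counts(counts)
        region = [GenomicInterval("c", 0, 1200, name="r")]
        peaks, _, _ = call_peaks(reads, region, bin_size=30, alpha=0.05)
        assert len(peaks) == 1
        assert peaks[0].interval.length == 2 * 30
        assert peaks[0].density == pytest.approx(peaks[0].reads_in_peak / 60)

    def test_too_few_bins_errors(self):
        reads = reads_from_bin_counts(np.array([3, 0, 2]))
        with pytest.raises(ValueError, match="too few"):
            call_peaks(reads, [GenomicInterval("c", 0, 90, name="r")], bin_size=30)

    def test_recall_and_precision_on_spiked_background(self, rng):
        """NB background (mean 2, disp 0.5) + 20 spiked bins at mean 40."""
        n_bins = 500
        r = 1 / 0.5
        counts = rng.negative_binomial(r, r / (r + 2.0), n_bins)
        spiked = rng.choice(n_bins, 20, replace=False)
        counts[spiked] = rng.poisson(40, 20)
        reads = reads_from_bin_counts(counts, rng=rng)
        region = [GenomicInterval("c", 0, n_bins * 30, name="r")]
        peaks, _, bins = call_peaks(reads, region, bin_size=30, alpha=0.05)
        sig_bins = set(bins.loc[bins["significant"], "bin_index"])
        spiked_set = set(int(i) for i in spiked)
        recall = len(sig_bins & spiked_set) / len(spiked_set)
        precision = len(sig_bins & spiked_set) / max(len(sig_bins), 1)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_null_background_calls_at_most_alpha(self, rng):
        r = 1 / 0.5
        regions, all_counts = [], []
        for i in range(50):
            regions.append(
                GenomicInterval("c", i * 2000, i * 2000 + 1800, name=f"r{i}")
            )
            all_counts.append(rng.negative_binomial(r, r / (r + 2.0), 60))
        starts = []
        for reg, counts in zip(regions, all_counts):
            rs = reads_from_bin_counts(counts, region_start=reg.start, rng=rng)
            starts.append(rs.df["start"].to_numpy())
        s = np.concatenate(starts)
        reads = ReadSet.from_arrays("c", s, s + 30)
        peaks, _, bins = call_peaks(reads, regions, bin_size=30, alpha=0.05)
        assert bins["significant"].mean() <= 0.05


class TestDensityPercentiles:
    def _peak(self, density, name="q"):
        from cernakit.occupancy import Peak

        return Peak(
            interval=GenomicInterval("c", 0, 10, name=name),
            bin_pvalue=0.01,
            reads_in_peak=int(density * 10),
            region_id="r",
        )

    def test_above_all_references(self):
        out = peak_density_percentiles(
            [self._peak(10)], [self._peak(d) for d in (1, 2, 3)]
        )
        assert out.loc[0, "density_rank"] == 1
        assert out.loc[0, "density_percentile"] == pytest.approx(100.0)

    def test_equal_to_reference_median(self):
        out = peak_density_percentiles(
            [self._peak(2)], [self._peak(d) for d in (1, 2, 3)]
        )
        assert out.loc[0, "density_rank"] == 2
        assert out.loc[0, "density_percentile"] == pytest.approx(100 * (1 - 1 / 3))

    def test_below_all_references(self):
        refs = [self._peak(d) for d in (5, 6, 7, 8)]
        out = peak_density_percentiles([self._peak(0.1)], refs)
        assert out.loc[0, "density_percentile"] < 100 / len(refs)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            peak_density_percentiles([self._peak(1)], [])


class TestSiteFoldChange:
    def _readset(self, site_n, other_n):
        ivs = [GenomicInterval("c", 100, 130) for _ in range(site_n)]
        ivs += [GenomicInterval("c", 300, 330) for _ in range(other_n)]
        return ReadSet(ivs)

    def test_ten_fold(self):
        site = GenomicInterval("c", 100, 130)
        norm = GenomicInterval("c", 0, 500)
        a = self._readset(10, 90)
        b = self._readset(1, 99)
        fc = site_coverage_fold_change(site, a, b, norm)
        assert fc.value == pytest.approx(10.0)

    def test_identity(self):
        site = GenomicInterval("c", 100, 130)
        norm = GenomicInterval("c", 0, 500)
        a = self._readset(5, 20)
        assert site_coverage_fold_change(site, a, a, norm).value == pytest.approx(1.0)

    def test_zero_denominator_flagged_infinite(self):
        site = GenomicInterval("c", 100, 130)
        norm = GenomicInterval("c", 0, 500)
        fc = site_coverage_fold_change(site, self._readset(5, 5), self._readset(0, 10), norm)
        assert fc.infinite
        assert math.isinf(fc.value)

    def test_zero_normalizer_errors(self):
        site = GenomicInterval("c", 100, 130)
        norm = GenomicInterval("c", 0, 500)
        with pytest.raises(ValueError, match="normalizer"):
            site_coverage_fold_change(site, self._readset(1, 1), ReadSet([]), norm)

    def test_normalizer_must_contain_site(self):
        with pytest.raises(ValueError, match="contain"):
            site_coverage_fold_change(
                GenomicInterval("c", 100, 130),
                self._readset(1, 1),
                self._readset(1, 1),
                GenomicInterval("c", 200, 500),
            )


@pytest.fixture(scope="module")
def clip_fixture():
    cfg = SimConfig(
        n_mrna=200,
        n_lncrna=10,
        n_target_genes=40,
        sites_per_control_family=20,
        module_size=10,
        seed=5,
    )
    txome, _, truth = generate_transcriptome(cfg)
    reads = {
        g: generate_clip_reads(txome, truth, g, cfg) for g in ("WT", "scr", "ko")
    }
    return cfg, txome, truth, reads


class TestPlantedCircuitRecovery:
    """The planted sponge dominates lncRNA occupancy and its peak is genotype-specific."""

    def test_sponge_ranks_first_among_lncrnas(self, clip_fixture):
        _, txome, truth, reads = clip_fixture
        table = annotation_read_totals(reads["WT"], txome)
        ranked = rank_by_occupancy(table, "lncRNA")
        assert ranked.iloc[0]["annotation_id"] == truth.sponge_id

    def test_sponge_peak_called_in_wt_not_ko(self, clip_fixture):
        _, txome, truth, reads = clip_fixture
        lnc = txome.by_class("lncRNA")
        site = truth.sites[truth.sites.gene_id == truth.sponge_id].iloc[0]

        def covers_site(peaks):
            return any(
                p.region_id == truth.sponge_id
                and p.interval.start <= site.start
                and site.end <= p.interval.end
                for p in peaks
            )

        wt_peaks, _, _ = call_peaks(reads["WT"], lnc, bin_size=30, alpha=0.05)
        ko_peaks, _, _ = call_peaks(reads["ko"], lnc, bin_size=30, alpha=0.05)
        assert covers_site(wt_peaks)
        assert not covers_site(ko_peaks)

    def test_sponge_site_fold_change_collapses_in_scr(self, clip_fixture):
        _, txome, truth, reads = clip_fixture
        sponge = txome.get("lncRNA", truth.sponge_id)
        srow = truth.sites[truth.sites.gene_id == truth.sponge_id].iloc[0]
        site = GenomicInterval(srow.contig, int(srow.start), int(srow.end))
        fc = site_coverage_fold_change(site, reads["scr"], reads["WT"], sponge.interval)
        assert fc.value <= 0.2
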