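"""Allelic DMR testing, genome-wide methylation, annotation, embryo QC."""

import numpy as np
import pandas as pd
import pytest

from imprintcall.data import GeneAnnotation
from imprintcall.methylation import (MethylationRegionCounts,
                                     aggregate_region_counts,
                                     annotate_regions_to_genes,
                                     select_testable_dmrs, sex_and_qc_embryos)
from imprintcall.methylation import test_dmr_differential as run_dmr_test
from imprintcall.methylation import \
    test_genomewide_methylation as run_genomewide_test
from imprintcall.simulate import SimulationScenario, simulate_methylation

from conftest import make_sheet


def region_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "region_class"])


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["region", "sample", "allele", "meth",
                                       "unmeth"])


class TestAggregation:
    regions = region_frame([("1", 100, 200, "r1", "germline_DMR")])

    def test_sums_and_percent(self):
        cpg = pd.DataFrame({
            "chrom": ["1", "1"], "pos": [120, 150],
            "sample": ["s1", "s1"], "allele": ["maternal", "maternal"],
            "meth": [3, 2], "unmeth": [1, 2]})
        mrc = aggregate_region_counts(cpg, self.regions)
        row = mrc.counts.iloc[0]
        assert (row["meth"], row["unmeth"]) == (5, 3)
        assert mrc.percent_mc("maternal").loc["r1", "s1"] == pytest.approx(0.625)

    def test_half_open_end_excluded(self):
        cpg = pd.DataFrame({"chrom": ["1", "1"], "pos": [199, 200],
                            "sample": "s1", "allele": "maternal",
                            "meth": [1, 9], "unmeth": [0, 0]})
        mrc = aggregate_region_counts(cpg, self.regions)
        assert mrc.counts["meth"].sum() == 1

    def test_empty_region_has_no_rows_and_na_percent(self):
        cpg = pd.DataFrame({"chrom": ["2"], "pos": [150], "sample": "s1",
                            "allele": "maternal", "meth": [1], "unmeth": [1]})
        mrc = aggregate_region_counts(cpg, self.regions)
        assert mrc.counts.empty
        assert mrc.percent_mc("maternal").empty

    def test_overlapping_regions_each_count_and_totals_conserved(self):
        regions = region_frame([("1", 0, 300, "a", "cpg_island"),
                                ("1", 100, 200, "b", "cpg_island"),
                                ("1", 400, 500, "c", "cpg_island")])
        rng = np.random.default_rng(0)
        cpg = pd.DataFrame({
            "chrom": "1", "pos": rng.integers(0, 600, 50),
            "sample": "s1", "allele": "unsplit",
            "meth": rng.poisson(3, 50), "unmeth": rng.poisson(3, 50)})
        mrc = aggregate_region_counts(cpg, regions)
        in_a = cpg[(cpg["pos"] >= 0) & (cpg["pos"] < 300)]
        got_a = mrc.counts[mrc.counts["region"] == "a"]
        assert got_a["meth"].sum() == in_a["meth"].sum()
        in_b = cpg[(cpg["pos"] >= 100) & (cpg["pos"] < 200)]
        got_b = mrc.counts[mrc.counts["region"] == "b"]
        assert got_b["meth"].sum() == in_b["meth"].sum()
        # non-overlapping subset never exceeds the input total
        disjoint = mrc.counts[mrc.counts["region"].isin(["a", "c"])]
        assert disjoint["meth"].sum() <= cpg["meth"].sum()


def _dmr_counts(name, per_sample, samples):
    """per_sample: {allele: (meth, unmeth)} identical across samples."""
    rows = []
    for s in samples:
        for allele, (meth, unmeth) in per_sample.items():
            rows.append((name, s, allele, meth, unmeth))
    return rows


class TestSelectTestable:
    sheet = make_sheet({"wt": 2, "matD": 2})

    def _mrc(self, rows, name="r1"):
        regions = region_frame([("1", 0, 100, name, "germline_DMR")])
        return MethylationRegionCounts(regions, counts_frame(rows))

    def test_clear_germline_dmr_kept_with_hyper_allele(self, config):
        rows = _dmr_counts("r1", {"maternal": (45, 5), "paternal": (5, 45)},
                           self.sheet["sample_id"])
        out = select_testable_dmrs(self._mrc(rows), self.sheet, config, "matD")
        assert len(out) == 1
        assert out.iloc[0]["hyper_allele"] == "maternal"

    def test_low_coverage_in_tested_genotype_drops_region(self, config):
        rows = []
        for s in self.sheet["sample_id"]:
            cov = (25, 25) if s.startswith("wt") else (5, 4)  # matD total 9 < 10
            rows += _dmr_counts("r1", {"maternal": (cov[0], 0),
                                       "paternal": (0, cov[1])}, [s])
        out = select_testable_dmrs(self._mrc(rows), self.sheet, config, "matD")
        assert out.empty

    def test_small_wt_allelic_difference_drops_region(self, config):
        rows = _dmr_counts("r1", {"maternal": (54, 46), "paternal": (46, 54)},
                           self.sheet["sample_id"])
        out = select_testable_dmrs(self._mrc(rows), self.sheet, config, "matD")
        assert out.empty  # 8% difference < 10%


class TestDMRTest:
    def test_identical_genotypes_not_significant(self, config):
        sheet = make_sheet({"wt": 3, "matD": 3})
        rows = _dmr_counts("r1", {"maternal": (90, 10)}, sheet["sample_id"])
        regions = region_frame([("1", 0, 100, "r1", "germline_DMR")])
        mrc = MethylationRegionCounts(regions, counts_frame(rows))
        testable = pd.DataFrame({"name": ["r1"],
                                 "region_class": ["germline_DMR"],
                                 "hyper_allele": ["maternal"],
                                 "wt_maternal_mc": [0.9],
                                 "wt_paternal_mc": [0.1],
                                 "mean_coverage_wt": [100.0],
                                 "mean_coverage_test": [100.0]})
        out = run_dmr_test(mrc, testable, sheet, config, "matD")
        assert out.iloc[0]["p"] > 0.5
        assert out.iloc[0]["p_adj"] == out.iloc[0]["p"]  # single region
        assert not out.iloc[0]["called"]

    def test_strong_methylation_drop_is_called(self, config):
        """A 30-point loss at coverage 100 with n=4/group is detected."""
        rng = np.random.default_rng(5)
        sheet = make_sheet({"wt": 4, "matD": 4})
        rows = []
        for s in sheet["sample_id"]:
            level = 0.9 if s.startswith("wt") else 0.6
            meth = rng.binomial(100, level)
            rows.append(("r1", s, "maternal", meth, 100 - meth))
        # companion null regions give the common dispersion some data
        for k in range(5):
            for s in sheet["sample_id"]:
                meth = rng.binomial(100, 0.8)
                rows.append((f"null{k}", s, "maternal", meth, 100 - meth))
        regions = region_frame(
            [("1", 0, 100, "r1", "germline_DMR")]
            + [("1", 200 * (k + 1), 200 * (k + 1) + 100, f"null{k}",
                "germline_DMR") for k in range(5)])
        mrc = MethylationRegionCounts(regions, counts_frame(rows))
        testable = pd.DataFrame({
            "name": ["r1"] + [f"null{k}" for k in range(5)],
            "region_class": "germline_DMR", "hyper_allele": "maternal",
            "wt_maternal_mc": 0.9, "wt_paternal_mc": 0.1,
            "mean_coverage_wt": 100.0, "mean_coverage_test": 100.0})
        out = run_dmr_test(mrc, testable, sheet, config, "matD")
        r1 = out[out["name"] == "r1"].iloc[0]
        assert r1["called"]

    def test_simulated_germline_dmrs_pass_filters(self, config):
        """On generator truth, >=95% of germline DMRs survive the filters
        and <=5% of unmethylated islands do (coverage >= 30)."""
        sheet = make_sheet({"wt": 6, "matD": 6})
        regions = region_frame(
            [("1", i * 10_000, i * 10_000 + 2000, f"dmr{i}", "germline_DMR")
             for i in range(40)]
            + [("1", (i + 50) * 10_000, (i + 50) * 10_000 + 2000,
                f"isl{i}", "cpg_island") for i in range(40)])
        scenario = SimulationScenario(seed=41, meth_coverage=30,
                                      meth_shift={"matD": 0.0})
        mrc, truth = simulate_methylation(scenario, regions, sheet)
        out = select_testable_dmrs(mrc, sheet, config, "matD")
        kept = set(out["name"])
        dmr_names = {f"dmr{i}" for i in range(40)}
        isl_names = {f"isl{i}" for i in range(40)}
        assert len(kept & dmr_names) / 40 >= 0.95
        assert len(kept & isl_names) / 40 <= 0.05


class TestGenomewide:
    sheet = make_sheet({"wt": 3, "matD": 3})

    def _mrc(self, levels, coverage=200):
        """levels: {sample: fraction} on a single cpg_island region."""
        rows = [("r1", s, "unsplit", int(coverage * f),
                 coverage - int(coverage * f)) for s, f in levels.items()]
        regions = region_frame([("1", 0, 100, "r1", "cpg_island")])
        return MethylationRegionCounts(regions, counts_frame(rows))

    def test_significant_but_small_difference_not_called(self, config):
        levels = {s: (0.50 if s.startswith("wt") else 0.55)
                  for s in self.sheet["sample_id"]}
        out = run_genomewide_test(self._mrc(levels, coverage=20000),
                                          self.sheet, config, "matD")
        assert out.iloc[0]["p_adj"] < 0.05
        assert abs(out.iloc[0]["meth_diff"]) < 0.10
        assert not out.iloc[0]["called"]

    def test_large_difference_without_significance_not_called(self, config):
        levels = {s: (0.4 if s.startswith("wt") else 0.6)
                  for s in self.sheet["sample_id"]}
        out = run_genomewide_test(self._mrc(levels, coverage=6),
                                          self.sheet, config, "matD")
        assert out.empty or not out.iloc[0]["called"]

    def test_region_below_ten_counts_excluded(self, config):
        levels = {s: 0.5 for s in self.sheet["sample_id"]}
        rows = [("r1", self.sheet["sample_id"][0], "unsplit", 4, 5)]
        regions = region_frame([("1", 0, 100, "r1", "cpg_island")])
        mrc = MethylationRegionCounts(regions, counts_frame(rows))
        out = run_genomewide_test(mrc, self.sheet, config, "matD")
        assert out.empty

    def test_clear_shift_is_called(self, config):
        levels = {s: (0.2 if s.startswith("wt") else 0.6)
                  for s in self.sheet["sample_id"]}
        out = run_genomewide_test(self._mrc(levels), self.sheet,
                                          config, "matD")
        assert out.iloc[0]["called"]


class TestAnnotation:
    genes = [GeneAnnotation("near", "1", 10_000, 12_000),
             GeneAnnotation("far", "1", 50_000, 52_000),
             GeneAnnotation("tie_late", "1", 30_000, 31_000),
             GeneAnnotation("tie_early", "1", 25_000, 26_000)]

    def test_distance_rules(self, config):
        regions = region_frame([
            ("1", 8_200, 8_400, "upstream_1800", "cpg_island"),   # 1.6 kb away
            ("1", 45_000, 46_000, "three_kb", "cpg_island"),      # 4 kb from far
            ("1", 11_000, 11_500, "overlapping", "cpg_island"),
        ])
        got = annotate_regions_to_genes(regions, self.genes, config)
        assert got["upstream_1800"] == "near"
        assert got["three_kb"] is None
        assert got["overlapping"] == "near"

    def test_tie_broken_by_smaller_start(self, config):
        # equidistant (1.9 kb) from tie_early's end (26 000) and
        # tie_late's start (30 000)
        regions = region_frame([("1", 27_900, 28_100, "mid", "cpg_island")])
        got = annotate_regions_to_genes(regions, self.genes, config)
        assert got["mid"] == "tie_early"


class TestEmbryoQC:
    def _qc(self, config, **kw):
        base = {"sample_id": "e1", "x_paternal_reads": 45,
                "x_allelic_reads": 100, "maternal_reads": 500,
                "paternal_reads": 500}
        base.update(kw)
        return sex_and_qc_embryos(pd.DataFrame([base]), config).iloc[0]

    def test_paternal_x_fraction_calls_female(self, config):
        assert self._qc(config)["sex"] == "F"

    def test_no_paternal_x_reads_calls_male(self, config):
        assert self._qc(config, x_paternal_reads=0)["sex"] == "M"

    def test_maternal_excess_flags_contamination(self, config):
        row = self._qc(config, maternal_reads=800, paternal_reads=200)
        assert row["contamination_flag"] and not row["keep"]

    def test_zero_x_coverage_is_unsexable_and_dropped(self, config):
        row = self._qc(config, x_paternal_reads=0, x_allelic_reads=0)
        assert row["sex"] == "NA" and not row["keep"]
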