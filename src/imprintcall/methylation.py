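"""Allele-specific and genome-wide DNA-methylation testing.

Imprinted germline DMRs carry ~95% methylation on one parental allele and
~5% on the other.  After aggregating per-CpG methylated/unmethylated counts
over regions, testable DMRs (adequate coverage, a clear wild-type allelic
difference) are tested for genotype effects on the hypermethylated allele
with the paired negative-binomial engine (methylated and unmethylated
counts paired within sample, common dispersion across regions).

Genome-wide tests (CpG islands, promoters, 10 kb bins) run on the unsplit
(non-allelic) track with a per-region binomial logistic regression, BH
correction, and a 10-percentage-point effect guard.  Single-embryo QC
(sexing from paternal-X bisulfite reads, maternal-contamination flagging)
also lives here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import FormatError, GeneAnnotation, bh_adjust
from .models import PairedAlleleModel, estimate_dispersions

__all__ = [
    "MethylationRegionCounts",
    "read_regions",
    "read_cpg_calls",
    "aggregate_region_counts",
    "select_testable_dmrs",
    "test_dmr_differential",
    "test_genomewide_methylation",
    "annotate_regions_to_genes",
    "sex_and_qc_embryos",
]

REGION_CLASSES = ("germline_DMR", "secondary_DMR", "cpg_island", "promoter",
                  "bin10kb")
ALLELES = ("maternal", "paternal", "unsplit")

_REGION_COLS = ["chrom", "start", "end", "name", "region_class"]


class MethylationRegionCounts:
    """Region x sample x allele methylated/unmethylated counts.

    ``regions`` is a frame with chrom, start, end, name, region_class
    (0-based half-open coordinates); ``counts`` is long-form with columns
    region, sample, allele, meth, unmeth.
    """

    def __init__(self, regions: pd.DataFrame, counts: pd.DataFrame):
        missing = set(_REGION_COLS) - set(regions.columns)
        if missing:
            raise FormatError(f"region table missing columns {sorted(missing)}")
        bad = set(regions["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise FormatError(f"unknown region classes {sorted(bad)}")
        if regions["name"].duplicated().any():
            raise FormatError("duplicate region names")
        if (counts[["meth", "unmeth"]] < 0).any().any():
            raise FormatError("negative methylation counts")
        self.regions = regions.reset_index(drop=True)
        self.counts = counts.reset_index(drop=True)

    def pivot(self, allele: str, value: str) -> pd.DataFrame:
        """Region x sample table of ``value`` ("meth"/"unmeth") for one allele."""
        sub = self.counts[self.counts["allele"] == allele]
        return sub.pivot_table(index="region", columns="sample", values=value,
                               aggfunc="sum", fill_value=0)

    def percent_mc(self, allele: str) -> pd.DataFrame:
        """Per-region, per-sample methylation fraction; NaN at zero coverage."""
        meth = self.pivot(allele, "meth")
        unmeth = self.pivot(allele, "unmeth").reindex_like(meth).fillna(0)
        cov = meth + unmeth
        return meth.where(cov > 0) / cov.where(cov > 0)


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_REGION_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"region file missing columns {sorted(missing)}")
    return df[_REGION_COLS]


def read_cpg_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "sample", "allele", "meth", "unmeth"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"CpG call file missing columns {sorted(missing)}")
    return df


def aggregate_region_counts(cpg_calls: pd.DataFrame,
                            regions: pd.DataFrame) -> MethylationRegionCounts:
    """Sum per-CpG counts over regions (half-open; a CpG at ``end`` is out).

    CpGs outside every region are ignored; overlapping regions each
    receive the CpG.
    """
    rows = []
    by_chrom = dict(tuple(cpg_calls.groupby("chrom")))
    for region in regions.itertuples(index=False):
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        hit = sub[(sub["pos"] >= region.start) & (sub["pos"] < region.end)]
        if hit.empty:
            continue
        agg = hit.groupby(["sample", "allele"])[["meth", "unmeth"]].sum()
        for (sample, allele), vals in agg.iterrows():
            rows.append((region.name, sample, allele,
                         int(vals["meth"]), int(vals["unmeth"])))
    counts = pd.DataFrame(rows, columns=["region", "sample", "allele",
                                         "meth", "unmeth"])
    return MethylationRegionCounts(regions, counts)


def select_testable_dmrs(mrc: MethylationRegionCounts, sheet: pd.DataFrame,
                         config, test_genotype: str) -> pd.DataFrame:
    """DMRs passing coverage and wild-type allelic-difference filters.

    Keeps regions whose mean haplotyped coverage per sample is at least
    ``dmr_min_counts`` for both wild-type and the tested genotype, and
    whose wild-type |maternal - paternal| mean methylation difference is
    at least ``dmr_wt_allelic_diff_min``; assigns the hypermethylated
    allele from wild type.
    """
    wt_ids = sheet.loc[sheet["genotype"] == "wt", "sample_id"].tolist()
    test_ids = sheet.loc[sheet["genotype"] == test_genotype,
                         "sample_id"].tolist()
    if not wt_ids:
        raise ValueError("no wild-type samples")
    hap = mrc.counts[mrc.counts["allele"].isin(["maternal", "paternal"])]
    cov = hap.groupby(["region", "sample"])[["meth", "unmeth"]].sum().sum(axis=1)
    cov = cov.unstack("sample")
    pmat = mrc.percent_mc("maternal")
    ppat = mrc.percent_mc("paternal")
    rows = []
    for region in mrc.regions.itertuples(index=False):
        name = region.name
        if name not in cov.index:
            continue
        mean_cov = {}
        for label, ids in (("wt", wt_ids), ("test", test_ids)):
            present = [s for s in ids if s in cov.columns]
            vals = cov.loc[name, present].fillna(0.0) if present else pd.Series(dtype=float)
            mean_cov[label] = float(vals.mean()) if len(vals) else 0.0
        if (mean_cov["wt"] < config.dmr_min_counts
                or mean_cov["test"] < config.dmr_min_counts):
            continue
        wt_cols_m = [s for s in wt_ids if name in pmat.index and s in pmat.columns]
        wt_cols_p = [s for s in wt_ids if name in ppat.index and s in ppat.columns]
        m_mean = float(pmat.loc[name, wt_cols_m].mean()) if wt_cols_m else np.nan
        p_mean = float(ppat.loc[name, wt_cols_p].mean()) if wt_cols_p else np.nan
        if not (np.isfinite(m_mean) and np.isfinite(p_mean)):
            continue
        if abs(m_mean - p_mean) < config.dmr_wt_allelic_diff_min:
            continue
        hyper = "maternal" if m_mean > p_mean else "paternal"
        rows.append({"name": name, "region_class": region.region_class,
                     "hyper_allele": hyper,
                     "wt_maternal_mc": m_mean, "wt_paternal_mc": p_mean,
                     "mean_coverage_wt": mean_cov["wt"],
                     "mean_coverage_test": mean_cov["test"]})
    return pd.DataFrame(rows, columns=["name", "region_class", "hyper_allele",
                                       "wt_maternal_mc", "wt_paternal_mc",
                                       "mean_coverage_wt",
                                       "mean_coverage_test"])


def test_dmr_differential(mrc: MethylationRegionCounts,
                          testable: pd.DataFrame, sheet: pd.DataFrame,
                          config, test_genotype: str,
                          dispersion_max_regions: int = 500) -> pd.DataFrame:
    """Genotype effect on hypermethylated-allele methylation, per DMR.

    Methylated and unmethylated counts are paired within sample in the
    negative-binomial engine; the dispersion is the common Cox-Reid value
    across the tested regions (estimated from the first
    ``dispersion_max_regions`` when more are tested; the common value
    stabilizes long before that); BH across regions; called at
    ``p_adj < fdr_alpha``.
    """
    keep = sheet[sheet["genotype"].isin(["wt", test_genotype])]
    sample_geno = dict(zip(keep["sample_id"], keep["genotype"]))
    per_region = []
    for row in testable.itertuples(index=False):
        sub = mrc.counts[(mrc.counts["region"] == row.name)
                         & (mrc.counts["allele"] == row.hyper_allele)
                         & (mrc.counts["sample"].isin(sample_geno))]
        meth = sub["meth"].to_numpy(dtype=float)
        unmeth = sub["unmeth"].to_numpy(dtype=float)
        geno = np.array([sample_geno[s] for s in sub["sample"]], dtype=object)
        per_region.append((row.name, meth, unmeth, geno))

    obs = []
    models: dict[str, PairedAlleleModel | None] = {}
    for name, meth, unmeth, geno in per_region:
        try:
            model = PairedAlleleModel(meth, unmeth, geno, dispersion=0.0)
        except ValueError:
            model = None
        models[name] = model
        if model is not None and len(obs) < dispersion_max_regions:
            obs.append((model.endog, model.exog))
    common = None
    if obs:
        common = float(estimate_dispersions(obs, mode="common")[0])
    rows = []
    for name, meth, unmeth, geno in per_region:
        if models[name] is None or common is None:
            rows.append({"name": name, "lrt_statistic": np.nan, "df": 0,
                         "p": np.nan})
            continue
        model = PairedAlleleModel(meth, unmeth, geno, dispersion=common)
        res = model.fit()
        rows.append({"name": name, "lrt_statistic": res.lrt_statistic,
                     "df": res.df, "p": res.pvalue})
    out = pd.DataFrame(rows, columns=["name", "lrt_statistic", "df", "p"])
    out = testable.merge(out, on="name", how="left")
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["called"] = (out["p_adj"] < config.fdr_alpha).astype(bool)
    out["common_dispersion"] = common if common is not None else np.nan
    return out


def test_genomewide_methylation(mrc: MethylationRegionCounts,
                                sheet: pd.DataFrame, config,
                                test_genotype: str,
                                region_classes=("cpg_island", "promoter",
                                                "bin10kb")) -> pd.DataFrame:
    """Binomial logistic regression of genotype on unsplit methylation.

    Regions with fewer than 10 total counts are excluded; a region is
    called when ``p_adj < fdr_alpha`` and the mean methylation fraction
    differs by at least ``meth_diff_min`` between genotypes.
    """
    keep = sheet[sheet["genotype"].isin(["wt", test_genotype])]
    sample_geno = dict(zip(keep["sample_id"], keep["genotype"]))
    wanted = mrc.regions[mrc.regions["region_class"].isin(region_classes)]
    pmc = mrc.percent_mc("unsplit")
    rows = []
    for region in wanted.itertuples(index=False):
        sub = mrc.counts[(mrc.counts["region"] == region.name)
                         & (mrc.counts["allele"] == "unsplit")
                         & (mrc.counts["sample"].isin(sample_geno))]
        total = float((sub["meth"] + sub["unmeth"]).sum())
        if total < 10:
            continue
        meth = sub["meth"].to_numpy(dtype=float)
        unmeth = sub["unmeth"].to_numpy(dtype=float)
        geno = np.array([sample_geno[s] for s in sub["sample"]], dtype=object)
        groups = set(geno[(meth + unmeth) > 0])
        if len(groups) < 2:
            continue
        is_test = (geno == test_genotype).astype(float)
        endog = np.column_stack([meth, unmeth])
        X_full = np.column_stack([np.ones_like(is_test), is_test])
        full = sm.GLM(endog, X_full, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, X_full[:, :1],
                      family=sm.families.Binomial()).fit()
        stat = max(0.0, 2.0 * (full.llf - null.llf))
        p = float(stats.chi2.sf(stat, 1))
        wt_cols = [s for s in sample_geno if sample_geno[s] == "wt"
                   and region.name in pmc.index and s in pmc.columns]
        test_cols = [s for s in sample_geno if sample_geno[s] == test_genotype
                     and region.name in pmc.index and s in pmc.columns]
        diff = np.nan
        if wt_cols and test_cols:
            diff = float(pmc.loc[region.name, test_cols].mean()
                         - pmc.loc[region.name, wt_cols].mean())
        rows.append({"name": region.name, "region_class": region.region_class,
                     "lrt_statistic": stat, "p": p, "meth_diff": diff})
    out = pd.DataFrame(rows, columns=["name", "region_class", "lrt_statistic",
                                      "p", "meth_diff"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["called"] = ((out["p_adj"] < config.fdr_alpha)
                     & (out["meth_diff"].abs() >= config.meth_diff_min)
                     ).astype(bool)
    return out


def annotate_regions_to_genes(regions: pd.DataFrame,
                              genes: list[GeneAnnotation],
                              config) -> pd.Series:
    """Nearest gene within ``gene_assoc_dist`` bp of each region.

    Distance is interval distance (0 when overlapping); ties go to the
    gene with the smaller start coordinate.  Regions with no gene within
    range map to NA.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for region in regions.itertuples(index=False):
        best: tuple[int, int, str] | None = None
        for g in by_chrom.get(region.chrom, []):
            if g.end <= region.start:
                dist = region.start - g.end
            elif region.end <= g.start:
                dist = g.start - region.end
            else:
                dist = 0
            if dist > config.gene_assoc_dist:
                continue
            key = (dist, g.start, g.gene_id)
            if best is None or key < best:
                best = key
        out[region.name] = best[2] if best is not None else None
    return pd.Series(out, name="gene_id")


def sex_and_qc_embryos(qc_table: pd.DataFrame, config) -> pd.DataFrame:
    """Sex single embryos and flag maternal contamination.

    Expects columns ``sample_id``, ``x_paternal_reads``,
    ``x_allelic_reads`` (paternal-haplotyped and all haplotyped bisulfite
    reads on the X), ``maternal_reads``, ``paternal_reads`` (genome-wide
    allelic totals).  In a cross with a Cast sire, females carry a
    paternal (Cast) X, so a substantial paternal-X read fraction means
    female; an excess of maternal-genome reads flags contamination by
    maternal tissue.
    """
    rows = []
    for row in qc_table.itertuples(index=False):
        if row.x_allelic_reads <= 0:
            sex = "NA"
        else:
            frac_x = row.x_paternal_reads / row.x_allelic_reads
            sex = "F" if frac_x >= config.sex_threshold else "M"
        tot = row.maternal_reads + row.paternal_reads
        mat_frac = row.maternal_reads / tot if tot > 0 else np.nan
        contaminated = bool(np.isfinite(mat_frac)
                            and mat_frac >= config.contamination_threshold)
        keep = (sex != "NA") and not contaminated
        rows.append({"sample_id": row.sample_id, "sex": sex,
                     "maternal_fraction": mat_frac,
                     "contamination_flag": contaminated, "keep": keep})
    return pd.DataFrame(rows, columns=["sample_id", "sex",
                                       "maternal_fraction",
                                       "contamination_flag", "keep"])
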