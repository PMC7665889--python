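"""Imprinting classification from wild-type allelic counts.

A gene from the known-imprinted candidate list is called imprinted in a
tissue when the pooled wild-type maternal:paternal expression ratio departs
from balance by at least 1.5-fold on either side.  The pooled natural-log
ratio ln(sum maternal / sum paternal) is exactly the maximum-likelihood
intercept of a binomial logistic regression of allele on nothing (each
haplotyped read is a Bernoulli trial), so the closed form replaces the
iterative fit.

The silent allele is the one transcribed less in wild type: paternal when
the log-ratio is positive, maternal when negative.  Its per-sample
expression share (the silent-allele proportion) is the quantity the
differential tests compare across genotypes: ~0 under intact imprinting,
~0.5 under complete loss of imprinting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AlleleCountMatrix, filter_expressed

__all__ = [
    "ImprintingCall",
    "allelic_log_ratio",
    "call_imprinted",
    "silent_allele_proportions",
    "calls_to_frame",
    "write_imprinting_calls",
    "write_silent_table",
]


@dataclass
class ImprintingCall:
    gene_id: str
    log_ratio: float          # ln(pooled maternal / pooled paternal) in wt
    imprinted: bool
    silent_allele: str        # "maternal", "paternal", or "NA"
    mean_haplotyped_per_genotype: dict[str, float]
    testable: bool            # passes the per-genotype coverage filter
    cluster: str | None = None


def allelic_log_ratio(maternal, paternal) -> float:
    """Pooled natural-log maternal:paternal ratio.

    Equals the MLE intercept (log-odds) of an intercept-only binomial
    logistic model on the counts.  When exactly one pooled sum is zero, a
    Haldane-Anscombe pseudocount of 0.5 is added to both sums; when both
    are zero the ratio is undefined (NaN).
    """
    m = float(np.sum(maternal))
    p = float(np.sum(paternal))
    if m + p == 0:
        return float("nan")
    if m == 0 or p == 0:
        m += 0.5
        p += 0.5
    # difference of logs keeps the ratio exactly antisymmetric in (m, p)
    return math.log(m) - math.log(p)


def call_imprinted(matrix: AlleleCountMatrix, sheet: pd.DataFrame, config,
                   expressed: set[str] | None = None) -> list[ImprintingCall]:
    """Classify candidate genes as imprinted from wild-type samples.

    The candidate set is the known-imprinted genes that are autosomal,
    expressed (CPM filter on totals), and not explicitly excluded
    (*Gatm* by default, whose maternal bias reflects decidual
    contamination rather than imprinting).  A candidate is imprinted when
    |log-ratio| >= ``imprint_log_ratio_min``; imprinted genes whose mean
    haplotyped coverage falls below ``min_haplotyped_counts_per_sample``
    in any genotype are kept in the output but flagged non-testable.
    """
    wt_ids = sheet.loc[sheet["genotype"] == "wt", "sample_id"].tolist()
    if not wt_ids:
        raise ValueError("no wild-type samples in sample sheet")
    if expressed is None:
        expressed = filter_expressed(matrix, config)
    excluded = set(config.excluded_genes)
    genotypes = list(dict.fromkeys(sheet["genotype"]))
    by_genotype = {g: sheet.loc[sheet["genotype"] == g, "sample_id"].tolist()
                   for g in genotypes}
    wt_cols = [matrix.sample_index(s) for s in wt_ids]

    calls: list[ImprintingCall] = []
    for i, gene in enumerate(matrix.genes):
        if not gene.is_known_imprinted or not gene.is_autosomal:
            continue
        if gene.gene_id in excluded or gene.gene_id not in expressed:
            continue
        info = matrix.informative[i, wt_cols]
        m = matrix.maternal[i, wt_cols][info]
        p = matrix.paternal[i, wt_cols][info]
        lr = allelic_log_ratio(m, p)
        imprinted = bool(np.isfinite(lr)
                         and abs(lr) >= config.imprint_log_ratio_min)
        silent = "NA"
        if imprinted:
            silent = "paternal" if lr > 0 else "maternal"
        hap = matrix.haplotyped()[i]
        means = {}
        for g, ids in by_genotype.items():
            cols = [matrix.sample_index(s) for s in ids]
            vals = hap[cols]
            means[g] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
        testable = imprinted and all(
            np.isfinite(v) and v >= config.min_haplotyped_counts_per_sample
            for v in means.values())
        calls.append(ImprintingCall(gene.gene_id, lr, imprinted, silent,
                                    means, testable, gene.cluster))
    return calls


def silent_allele_proportions(matrix: AlleleCountMatrix,
                              calls: list[ImprintingCall]) -> pd.DataFrame:
    """Per-sample silent-allele proportion for each imprinted gene.

    Rows are genes (imprinted calls only), columns samples; entries are
    silent-allele reads over haplotyped reads, NaN where the cell is
    non-informative or has zero haplotyped depth.
    """
    rows = {}
    for call in calls:
        if not call.imprinted:
            continue
        i = matrix.gene_index(call.gene_id)
        m = matrix.maternal[i].astype(float)
        p = matrix.paternal[i].astype(float)
        depth = m + p
        silent = p if call.silent_allele == "paternal" else m
        with np.errstate(divide="ignore", invalid="ignore"):
            prop = np.where(depth > 0, silent / np.maximum(depth, 1e-300), np.nan)
        prop = np.where(matrix.informative[i], prop, np.nan)
        rows[call.gene_id] = prop
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=matrix.samples)


def calls_to_frame(calls: list[ImprintingCall]) -> pd.DataFrame:
    genotypes = sorted({g for c in calls for g in c.mean_haplotyped_per_genotype})
    rows = []
    for c in calls:
        row = {"gene_id": c.gene_id,
               "log_ratio": c.log_ratio,
               "imprinted": c.imprinted,
               "silent_allele": c.silent_allele,
               "testable": c.testable,
               "cluster": c.cluster if c.cluster is not None else "."}
        for g in genotypes:
            row[f"mean_haplotyped.{g}"] = c.mean_haplotyped_per_genotype.get(
                g, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_imprinting_calls(calls: list[ImprintingCall],
                           path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False,
                                 float_format="%.6g")


def write_silent_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
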