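"""Per-gene differential-imprinting tests and the dual calling rule.

Two engines, chosen by design:

``paired_nb``
    For complete-data designs (F1 crosses): the paired negative-binomial
    GLM of :class:`~imprintcall.models.PairedAlleleModel`, with tagwise
    (or common) Cox-Reid dispersions estimated across the tested genes.

``betabin``
    For mosaic designs (N1 backcrosses, where roughly half of the allelic
    count matrix is missing): the fixed-dispersion beta-binomial
    regression of :class:`~imprintcall.models.BetaBinomialModel`.

A gene is called differentially imprinted when the BH-adjusted
likelihood-ratio p-value is below ``fdr_alpha`` AND the mean silent-allele
proportion moves by more than ``delta_silent_min`` versus wild type — for
placental designs with both Cre lines, in at least one Cre stratum.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import AlleleCountMatrix, bh_adjust
from .imprinting import ImprintingCall
from .models import BetaBinomialModel, PairedAlleleModel, estimate_dispersions

__all__ = [
    "fit_paired_nb",
    "betabin_lrt",
    "estimate_gene_dispersions",
    "test_differential_imprinting",
    "call_differential",
    "write_differential_results",
]


def fit_paired_nb(maternal, paternal, genotypes, dispersion: float,
                  strata=None, reference: str = "wt"):
    """Paired NB likelihood-ratio test of genotype on allelic balance.

    Returns ``(lrt_statistic, df, p)``; NaNs with a reason when the
    design is not identifiable (a genotype without usable samples).
    """
    try:
        model = PairedAlleleModel(maternal, paternal, genotypes,
                                  strata=strata, dispersion=dispersion,
                                  reference=reference)
    except ValueError:
        return float("nan"), 0, float("nan")
    res = model.fit()
    return res.lrt_statistic, res.df, res.pvalue


def betabin_lrt(maternal, paternal, genotypes, phi: float,
                reference: str = "wt"):
    """Fixed-dispersion beta-binomial LRT of genotype on the maternal
    fraction; NaNs when a genotype is entirely non-informative."""
    try:
        model = BetaBinomialModel(maternal, paternal, genotypes, phi=phi,
                                  reference=reference)
    except ValueError:
        return float("nan"), 0, float("nan")
    res = model.fit()
    return res.lrt_statistic, res.df, res.pvalue


def _gene_arrays(matrix: AlleleCountMatrix, sheet: pd.DataFrame,
                 gene_id: str):
    i = matrix.gene_index(gene_id)
    cols = [matrix.sample_index(s) for s in sheet["sample_id"]]
    info = matrix.informative[i, cols]
    m = matrix.maternal[i, cols].astype(float)
    p = matrix.paternal[i, cols].astype(float)
    m[~info] = np.nan
    p[~info] = np.nan
    geno = sheet["genotype"].to_numpy(dtype=object)
    cre = sheet["cre"].to_numpy(dtype=object)
    keep = ~np.isnan(m)
    return m[keep], p[keep], geno[keep], cre[keep]


def estimate_gene_dispersions(matrix: AlleleCountMatrix, sheet: pd.DataFrame,
                              gene_ids: list[str], config,
                              mode: str = "tagwise",
                              cre_in_model: bool | None = None) -> pd.Series:
    """Cox-Reid dispersions for the paired allelic design of each gene."""
    if cre_in_model is None:
        cre_in_model = config.cre_in_model
    obs = []
    for gid in gene_ids:
        m, p, geno, cre = _gene_arrays(matrix, sheet, gid)
        strata = cre if (cre_in_model and len(set(cre)) > 1) else None
        try:
            model = PairedAlleleModel(m, p, geno, strata=strata, dispersion=0.0)
        except ValueError:
            obs.append((np.zeros(1), np.ones((1, 1))))
            continue
        obs.append((model.endog, model.exog))
    disp = estimate_dispersions(obs, mode=mode,
                                prior_weight=config.dispersion_prior_weight)
    return pd.Series(disp, index=gene_ids)


def test_differential_imprinting(matrix: AlleleCountMatrix,
                                 sheet: pd.DataFrame,
                                 calls: list[ImprintingCall], config,
                                 engine: str = "paired_nb",
                                 dispersion_mode: str = "tagwise") -> pd.DataFrame:
    """Run the chosen engine on every testable imprinted gene.

    Returns one row per tested gene with the LRT statistic, df, p-value
    and (engine) column; BH adjustment and the calling rule are applied
    afterwards by :func:`call_differential` so the family is exactly the
    genes tested within one experiment.
    """
    if engine not in ("paired_nb", "betabin"):
        raise ValueError(f"unknown engine {engine!r}")
    tested = [c.gene_id for c in calls if c.testable]
    dispersions = None
    if engine == "paired_nb" and tested:
        dispersions = estimate_gene_dispersions(matrix, sheet, tested, config,
                                                mode=dispersion_mode)
    rows = []
    for gid in tested:
        m, p, geno, cre = _gene_arrays(matrix, sheet, gid)
        if engine == "paired_nb":
            strata = cre if (config.cre_in_model and len(set(cre)) > 1) else None
            stat, df, pval = fit_paired_nb(m, p, geno,
                                           float(dispersions[gid]),
                                           strata=strata)
            disp = float(dispersions[gid])
        else:
            stat, df, pval = betabin_lrt(m, p, geno, config.betabin_phi)
            disp = config.betabin_phi
        rows.append({"gene_id": gid, "engine": engine,
                     "lrt_statistic": stat, "df": df, "p": pval,
                     "dispersion": disp})
    return pd.DataFrame(rows, columns=["gene_id", "engine", "lrt_statistic",
                                       "df", "p", "dispersion"])


def _delta_columns(silent_table: pd.DataFrame, sheet: pd.DataFrame,
                   per_cre: bool) -> pd.DataFrame:
    """Mean silent-allele proportion shifts vs wild type, per contrast.

    One column per non-wt genotype (or genotype x Cre stratum for
    placental designs); the difference of unweighted per-sample means.
    """
    contrasts: list[tuple[str, pd.DataFrame]] = []
    test_genotypes = [g for g in dict.fromkeys(sheet["genotype"]) if g != "wt"]
    if per_cre:
        cres = [c for c in dict.fromkeys(sheet["cre"]) if c != "none"]
        for g in test_genotypes:
            for c in cres:
                contrasts.append((f"{g}.{c}", sheet[sheet["cre"] == c]))
    else:
        for g in test_genotypes:
            contrasts.append((g, sheet))
    out = pd.DataFrame(index=silent_table.index)
    for label, sub in contrasts:
        g = label.split(".")[0]
        wt_ids = sub.loc[sub["genotype"] == "wt", "sample_id"]
        test_ids = sub.loc[sub["genotype"] == g, "sample_id"]
        wt_cols = [s for s in wt_ids if s in silent_table.columns]
        test_cols = [s for s in test_ids if s in silent_table.columns]
        if not wt_cols or not test_cols:
            out[f"delta.{label}"] = np.nan
            continue
        out[f"delta.{label}"] = (silent_table[test_cols].mean(axis=1)
                                 - silent_table[wt_cols].mean(axis=1))
    return out


def call_differential(results: pd.DataFrame, silent_table: pd.DataFrame,
                      sheet: pd.DataFrame, config) -> pd.DataFrame:
    """Apply BH correction and the dual calling rule.

    ``called`` requires ``p_adj < fdr_alpha`` and, in at least one
    contrast, ``|delta silent| > delta_silent_min``.  Placental designs
    with both Cre lines evaluate the delta criterion per Cre stratum.
    """
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    per_cre = (sheet["tissue"].str.startswith("placenta").any()
               and sheet.loc[sheet["cre"] != "none", "cre"].nunique() > 1)
    deltas = _delta_columns(silent_table, sheet, per_cre)
    deltas = deltas.reindex(out["gene_id"]).reset_index(drop=True)
    for col in deltas.columns:
        out[col] = deltas[col]
    delta_cols = list(deltas.columns)
    if delta_cols:
        out["max_abs_delta"] = deltas.abs().max(axis=1)
    else:
        out["max_abs_delta"] = np.nan
    out["called"] = ((out["p_adj"] < config.fdr_alpha)
                     & (out["max_abs_delta"] > config.delta_silent_min)
                     ).astype(bool)
    return out


def write_differential_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
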