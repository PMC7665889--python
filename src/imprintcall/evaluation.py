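"""Simulation-based evaluation of the analysis stages.

These routines re-run each stage on truth-tagged synthetic data and
measure operating characteristics: type-I error of the three testing
engines under their own null models, bias of the silent-allele shift
estimate, segmentation breakpoint recovery, imprinting-caller sensitivity
and false-positive rate, and the behaviour of the dual calling rule.
They define the package's reference study conditions in one place so the
test suite and the reproduction script measure the same quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig
from .data import AlleleCountMatrix
from .differential import (betabin_lrt, call_differential, fit_paired_nb,
                           test_differential_imprinting)
from .imprinting import allelic_log_ratio, call_imprinted, \
    silent_allele_proportions
from .methylation import MethylationRegionCounts, test_dmr_differential
from .models import PairedAlleleModel, estimate_dispersions
from .segmentation import segment_allelic_proportions
from .simulate import (SimulationScenario, _betabinom, _negbin,
                       simulate_backcross_bins, simulate_expression)

__all__ = [
    "betabin_null_rejection_rate",
    "paired_nb_null_rejection_rate",
    "dmr_null_rejection_rate",
    "delta_silent_bias",
    "breakpoint_recovery",
    "caller_performance",
    "calling_rule_null_rate",
    "power_curve",
    "logratio_iterative_max_error",
]


def betabin_null_rejection_rate(n_genes: int = 2000, n_per_group: int = 8,
                                depth_mean: float = 100.0, phi: float = 0.01,
                                alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical rejection rate of the beta-binomial LRT under its null.

    Per gene: equal maternal fraction in both genotypes (drawn once per
    gene), beta-binomial counts at the engine's phi.
    """
    rng = np.random.default_rng((seed, 101))
    n = 2 * n_per_group
    groups = np.array(["wt"] * n_per_group + ["matD"] * n_per_group,
                      dtype=object)
    rejections = 0
    for _ in range(n_genes):
        pi = rng.uniform(0.1, 0.9)
        depth = rng.poisson(depth_mean, n)
        m = _betabinom(rng, depth, pi, phi)
        p = depth - m
        _, _, pval = betabin_lrt(m, p, groups, phi)
        rejections += bool(np.isfinite(pval) and pval < alpha)
    return rejections / n_genes


def paired_nb_null_rejection_rate(n_genes: int = 2000, n_per_group: int = 8,
                                  mu: float = 100.0, dispersion: float = 0.05,
                                  alpha: float = 0.05, seed: int = 0,
                                  n_disp_genes: int = 300) -> float:
    """Rejection rate of the paired NB LRT under its null.

    Maternal and paternal counts share each sample's expression level with
    no genotype effect on balance; the engine runs with the common
    Cox-Reid dispersion estimated from the first ``n_disp_genes`` genes,
    as it would on real data.
    """
    rng = np.random.default_rng((seed, 102))
    n = 2 * n_per_group
    groups = np.array(["wt"] * n_per_group + ["matD"] * n_per_group,
                      dtype=object)
    genes = []
    for _ in range(n_genes):
        mu_s = mu * rng.lognormal(-0.125, 0.5, n)
        m = _negbin(rng, mu_s / 2.0, dispersion, (n,))
        p = _negbin(rng, mu_s / 2.0, dispersion, (n,))
        genes.append((m, p))
    obs = []
    for m, p in genes[:n_disp_genes]:
        model = PairedAlleleModel(m, p, groups, dispersion=0.0)
        obs.append((model.endog, model.exog))
    common = float(estimate_dispersions(obs, mode="common")[0])
    rejections = 0
    for m, p in genes:
        _, _, pval = fit_paired_nb(m, p, groups, common)
        rejections += bool(np.isfinite(pval) and pval < alpha)
    return rejections / n_genes


def dmr_null_rejection_rate(n_regions: int = 2000, n_per_group: int = 4,
                            mu: float = 100.0, dispersion: float = 0.05,
                            alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of the DMR paired test under its null.

    Methylated/unmethylated counts follow the paired NB model with a
    region-specific methylation level identical in both genotypes.
    """
    rng = np.random.default_rng((seed, 103))
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    sheet = pd.DataFrame({
        "sample_id": samples,
        "genotype": ["wt"] * n_per_group + ["matD"] * n_per_group,
        "cre": ["MMTV"] * n, "tissue": ["embryo_E9.5"] * n,
        "cross": ["F1"] * n, "maternal_strain": ["C57BL/6"] * n,
        "paternal_strain": ["CAST/EiJ"] * n, "sex": ["NA"] * n})
    rows = []
    regions = []
    for r in range(n_regions):
        name = f"r{r}"
        regions.append({"chrom": "1", "start": r * 1000,
                        "end": r * 1000 + 500, "name": name,
                        "region_class": "germline_DMR"})
        q = rng.uniform(0.2, 0.8)
        mu_s = mu * rng.lognormal(-0.125, 0.5, n)
        meth = _negbin(rng, mu_s * q, dispersion, (n,))
        unmeth = _negbin(rng, mu_s * (1 - q), dispersion, (n,))
        for i, s in enumerate(samples):
            rows.append((name, s, "maternal", int(meth[i]), int(unmeth[i])))
    mrc = MethylationRegionCounts(pd.DataFrame(regions),
                                  pd.DataFrame(rows, columns=[
                                      "region", "sample", "allele", "meth",
                                      "unmeth"]))
    testable = pd.DataFrame({
        "name": [r["name"] for r in regions],
        "region_class": "germline_DMR", "hyper_allele": "maternal",
        "wt_maternal_mc": np.nan, "wt_paternal_mc": np.nan,
        "mean_coverage_wt": np.nan, "mean_coverage_test": np.nan})
    config = AnalysisConfig()
    res = test_dmr_differential(mrc, testable, sheet, config, "matD")
    pvals = res["p"].to_numpy()
    return float(np.mean(pvals[np.isfinite(pvals)] < alpha))


def _scenario_depth(depth_mean: float, h: float = 0.8) -> float:
    """Total-count mean giving the requested mean informative depth."""
    return depth_mean / h


def delta_silent_bias(n_genes: int = 200, n_per_group: int = 8,
                      depth_mean: float = 100.0, delta: float = 0.2,
                      seed: int = 0) -> float:
    """Mean bias of the estimated silent-allele proportion shift.

    All genes are imprinted archetypes with a true per-genotype shift of
    ``delta``; the estimate is the difference of unweighted per-sample
    mean proportions, exactly as the calling rule computes it.
    """
    scenario = SimulationScenario(
        n_genes=n_genes, frac_imprinted=1.0, frac_affected=1.0,
        frac_known_biallelic=0.0,
        samples_per_genotype={"wt": n_per_group, "matD": n_per_group},
        loi_delta={"matD": delta}, mean_expression=_scenario_depth(depth_mean),
        expression_sigma=0.3, seed=seed)
    matrix, sheet, truth = simulate_expression(scenario)
    config = AnalysisConfig()
    calls = call_imprinted(matrix, sheet, config)
    silent = silent_allele_proportions(matrix, calls)
    truth = truth.set_index("gene_id")
    biases = []
    for call in calls:
        if not call.imprinted:
            continue
        if call.silent_allele != truth.loc[call.gene_id, "silent_allele"]:
            continue
        wt_ids = sheet.loc[sheet["genotype"] == "wt", "sample_id"]
        test_ids = sheet.loc[sheet["genotype"] == "matD", "sample_id"]
        est = (silent.loc[call.gene_id, test_ids].mean()
               - silent.loc[call.gene_id, wt_ids].mean())
        biases.append(est - truth.loc[call.gene_id, "delta.matD"])
    return float(np.mean(biases))


def breakpoint_recovery(n_samples: int = 8, seed: int = 0,
                        tolerance_bins: int = 1) -> float:
    """Fraction of true zygosity breakpoints recovered within a bin
    tolerance by the segmentation tree (segments >= 10 bins, depth >= 50)."""
    scenario = SimulationScenario(
        seed=seed, cross="N1",
        chrom_lengths={str(c): 60_000_000 for c in range(1, 6)},
        n1_bin_depth=80)
    samples = [f"n1_{k}" for k in range(n_samples)]
    tracks, truth = simulate_backcross_bins(scenario, samples)
    config = AnalysisConfig()
    hit = 0
    total = 0
    for sample in samples:
        model = segment_allelic_proportions(tracks[sample], config)
        for chrom in scenario.chrom_lengths:
            true_bp = truth[(truth["sample"] == sample)
                            & (truth["chrom"] == chrom)
                            & (truth["first_bin"] > 0)]["first_bin"].to_numpy()
            fitted_bp = np.array([s.first_bin for s in model.segments_for(chrom)
                                  if s.first_bin > 0])
            for b in true_bp:
                total += 1
                if fitted_bp.size and np.min(np.abs(fitted_bp - b)) <= tolerance_bins:
                    hit += 1
    return hit / total if total else float("nan")


def caller_performance(n_genes: int = 600, seed: int = 0) -> dict[str, float]:
    """Sensitivity and false-positive rate of the imprinting caller.

    Imprinted archetypes at p0 = 0.02, every biallelic gene placed on the
    candidate list, mean informative depth ~400.
    """
    scenario = SimulationScenario(
        n_genes=n_genes, frac_imprinted=0.3, frac_known_biallelic=1.0,
        frac_affected=0.0, p0_imprinted=0.02, mean_expression=500.0,
        expression_sigma=0.5, seed=seed)
    matrix, sheet, truth = simulate_expression(scenario)
    config = AnalysisConfig()
    calls = {c.gene_id: c for c in call_imprinted(matrix, sheet, config)}
    truth = truth.set_index("gene_id")
    tp = fn = fp = tn = 0
    for gid, call in calls.items():
        truly = truth.loc[gid, "archetype"] != "biallelic"
        if truly:
            tp += call.imprinted
            fn += not call.imprinted
        else:
            fp += call.imprinted
            tn += not call.imprinted
    return {"sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "false_positive_rate": fp / (fp + tn) if fp + tn else float("nan"),
            "n_true_imprinted": tp + fn, "n_true_biallelic": fp + tn}


def _run_calling(scenario: SimulationScenario, engine: str = "paired_nb"):
    matrix, sheet, truth = simulate_expression(scenario)
    config = AnalysisConfig()
    calls = call_imprinted(matrix, sheet, config)
    silent = silent_allele_proportions(matrix, calls)
    results = test_differential_imprinting(matrix, sheet, calls, config,
                                           engine=engine)
    results = call_differential(results, silent, sheet, config)
    return results, truth


def calling_rule_null_rate(n_genes: int = 1000, seed: int = 0,
                           engine: str = "paired_nb") -> dict[str, float]:
    """Called fraction among truly-null imprinted genes under a global
    null (no genotype shifts anywhere)."""
    scenario = SimulationScenario(
        n_genes=n_genes, frac_imprinted=0.10, frac_known_biallelic=0.0,
        loi_delta={"matD": 0.0}, seed=seed)
    results, truth = _run_calling(scenario, engine)
    truth = truth.set_index("gene_id")
    null_imprinted = results["gene_id"].map(
        lambda g: truth.loc[g, "archetype"] != "biallelic")
    sub = results[null_imprinted]
    n = len(sub)
    return {"called_fraction": float(sub["called"].mean()) if n else float("nan"),
            "n_tested": n}


def power_curve(deltas=(0.05, 0.1, 0.2, 0.3), n_genes: int = 400,
                seed: int = 0, engine: str = "paired_nb") -> dict[float, float]:
    """Empirical call rate among affected genes at each simulated shift."""
    out = {}
    for delta in deltas:
        scenario = SimulationScenario(
            n_genes=n_genes, frac_imprinted=0.25, frac_known_biallelic=0.0,
            frac_affected=1.0, loi_delta={"matD": float(delta)}, seed=seed)
        results, truth = _run_calling(scenario, engine)
        truth = truth.set_index("gene_id")
        affected = results["gene_id"].map(lambda g: bool(truth.loc[g, "affected"]))
        sub = results[affected]
        out[float(delta)] = float(sub["called"].mean()) if len(sub) else float("nan")
    return out


def logratio_iterative_max_error(n_fixtures: int = 100,
                                 seed: int = 0) -> float:
    """Max |closed-form log-ratio - iterative binomial-GLM intercept|.

    The pooled ratio ln(sum m / sum p) should equal the IRLS-maximized
    intercept of an intercept-only binomial logistic model to numerical
    precision.
    """
    rng = np.random.default_rng((seed, 104))
    worst = 0.0
    for _ in range(n_fixtures):
        k = rng.integers(2, 10)
        m = rng.poisson(rng.uniform(5, 200), k)
        p = rng.poisson(rng.uniform(5, 200), k)
        if m.sum() == 0 or p.sum() == 0:
            continue
        closed = allelic_log_ratio(m, p)
        endog = np.column_stack([m, p]).astype(float)
        res = sm.GLM(endog, np.ones((k, 1)),
                     family=sm.families.Binomial()).fit(tol=1e-12, maxiter=300)
        worst = max(worst, abs(closed - float(res.params[0])))
    return worst
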