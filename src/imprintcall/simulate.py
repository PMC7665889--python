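"""Truth-tagged synthetic data with the statistical structure the
analysis assumes.

Expression: per-gene totals are negative-binomial; a binomial thinning
with the haplotyping efficiency decides how many reads are allele-
assignable (the remainder inflates the total only, so maternal+paternal
< total as in real haplotyped data); the maternal share of assignable
reads is beta-binomial around the gene's parental bias.  Imprinted
archetypes start from a small silent-allele proportion p0 and loss-of-
imprinting genotypes shift it upward by a configurable delta.

Backcross bins: each chromosome alternates heterozygous and homozygous
segments with geometric lengths; heterozygous bins have Cast proportion
near 0.5, homozygous-B6 bins near 0.01.

Methylation: germline-DMR archetypes put ~95% methylation on one parental
allele and ~5% on the other; genotype shifts erode the hypermethylated
allele of affected regions.  All generators are pure functions of
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AlleleCountMatrix, GeneAnnotation
from .methylation import MethylationRegionCounts
from .segmentation import GenomicBinTrack

__all__ = [
    "ScenarioError",
    "SimulationScenario",
    "simulate_expression",
    "simulate_backcross_bins",
    "simulate_methylation",
]


class ScenarioError(ValueError):
    """A scenario parameter combination is impossible to simulate."""


@dataclass
class SimulationScenario:
    """Parameters of a synthetic imprinting study.

    Defaults are sized so the full pipeline runs in well under a minute
    while matching the statistical regime of a bulk allele-specific
    experiment: a few thousand genes, 6-8 samples per genotype, mean
    expression in the hundreds of reads, moderate negative-binomial
    dispersion, mild allelic overdispersion, and 80% of reads allele-
    assignable.
    """

    n_genes: int = 2000
    samples_per_genotype: dict[str, int] = field(
        default_factory=lambda: {"wt": 8, "matD": 8})
    #: fraction of genes with an imprinted archetype (split evenly between
    #: maternally and paternally expressed)
    frac_imprinted: float = 0.10
    #: base silent-allele proportion of imprinted genes (intact imprinting)
    p0_imprinted: float = 0.02
    #: per-genotype upward shift of the silent-allele proportion at
    #: affected genes (loss of imprinting); wt is always 0
    loi_delta: dict[str, float] = field(default_factory=lambda: {"matD": 0.2})
    #: fraction of imprinted genes affected in non-wt genotypes
    frac_affected: float = 0.5
    #: fraction of biallelic genes nevertheless on the known-imprinted
    #: list (candidates that should not be called)
    frac_known_biallelic: float = 0.10
    mean_expression: float = 200.0
    #: log-normal sigma of per-gene mean expression
    expression_sigma: float = 1.0
    nb_dispersion: float = 0.05
    #: beta-binomial intraclass correlation of the allelic split
    rho: float = 0.01
    #: fraction of total reads that are allele-assignable
    haplotyping_efficiency: float = 0.8
    tissue: str = "embryo_E9.5"
    cross: str = "F1"
    cre_lines: tuple[str, ...] = ("MMTV",)
    maternal_strain: str = "C57BL/6"
    paternal_strain: str = "CAST/EiJ"
    # --- backcross bin track ---
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 60_000_000, "2": 60_000_000})
    bin_width: int = 100_000
    #: zygosity blocks of ~25 Mb mean with a ~10 Mb floor: a first-
    #: generation backcross sees about one crossover per chromosome and
    #: meiosis, and crossover interference suppresses close double
    #: crossovers, so megabase-scale interior islands are rare
    n1_mean_segment_bins: float = 250.0
    n1_min_segment_bins: int = 100
    n1_het_fraction: float = 0.5
    n1_bin_depth: float = 80.0
    n1_rho: float = 0.01
    n1_hom_epsilon: float = 0.01
    # --- methylation ---
    meth_coverage: float = 30.0
    meth_rho: float = 0.05
    meth_shift: dict[str, float] = field(default_factory=lambda: {"matD": 0.4})
    frac_meth_affected: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0_imprinted <= 0.5:
            raise ScenarioError("p0_imprinted must lie in [0, 0.5]")
        for g, d in self.loi_delta.items():
            if d < 0 or self.p0_imprinted + d > 1.0:
                raise ScenarioError(
                    f"loi_delta[{g}]={d} pushes the silent proportion "
                    f"outside [0, 1]")
        if not 0.0 < self.haplotyping_efficiency <= 1.0:
            raise ScenarioError("haplotyping_efficiency must lie in (0, 1]")
        for name in ("frac_imprinted", "frac_affected", "frac_known_biallelic",
                     "rho", "n1_het_fraction", "meth_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name}={v} must lie in [0, 1]")


def _rng(scenario: SimulationScenario, salt: int) -> np.random.Generator:
    return np.random.default_rng((scenario.seed, salt))


def _negbin(rng, mu, phi, size):
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    if phi <= 0:
        return rng.poisson(mu)
    n = 1.0 / phi
    out = np.zeros(size, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(n, n / (n + mu[pos]))
    return out


def _betabinom(rng, n, p, rho):
    """Beta-binomial draws with mean p and intraclass correlation rho."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, p)
    s = (1.0 - rho) / rho
    a = np.clip(p * s, 1e-12, None)
    b = np.clip((1.0 - p) * s, 1e-12, None)
    probs = rng.beta(a, b)
    # degenerate means stay degenerate
    probs = np.where(p <= 0, 0.0, np.where(p >= 1, 1.0, probs))
    return rng.binomial(n, probs)


def _make_sample_sheet(scenario: SimulationScenario) -> pd.DataFrame:
    rows = []
    for geno, count in scenario.samples_per_genotype.items():
        for k in range(count):
            cre = (scenario.cre_lines[k % len(scenario.cre_lines)]
                   if scenario.cre_lines else "none")
            rows.append({"sample_id": f"{geno}_{cre}_{k + 1}",
                         "genotype": geno, "cre": cre,
                         "tissue": scenario.tissue, "cross": scenario.cross,
                         "maternal_strain": scenario.maternal_strain,
                         "paternal_strain": scenario.paternal_strain,
                         "sex": "NA"})
    return pd.DataFrame(rows)


def simulate_expression(scenario: SimulationScenario):
    """Generate (AlleleCountMatrix, sample sheet, truth table)."""
    rng = _rng(scenario, 1)
    n = scenario.n_genes
    sheet = _make_sample_sheet(scenario)
    genotypes = sheet["genotype"].to_numpy(dtype=object)
    n_samples = len(sheet)

    fi = scenario.frac_imprinted
    archetypes = rng.choice(
        ["biallelic", "maternal_expressed", "paternal_expressed"],
        size=n, p=[1.0 - fi, fi / 2.0, fi / 2.0])
    known = archetypes != "biallelic"
    known |= (archetypes == "biallelic") \
        & (rng.random(n) < scenario.frac_known_biallelic)
    affected = (archetypes != "biallelic") \
        & (rng.random(n) < scenario.frac_affected)
    mu = scenario.mean_expression * rng.lognormal(
        -0.5 * scenario.expression_sigma ** 2, scenario.expression_sigma, n)

    geno_levels = list(scenario.samples_per_genotype)
    p_silent = {}
    for g in geno_levels:
        delta = 0.0 if g == "wt" else scenario.loi_delta.get(g, 0.0)
        ps = np.where(archetypes == "biallelic", 0.5,
                      scenario.p0_imprinted + np.where(affected, delta, 0.0))
        if ((ps < 0) | (ps > 1)).any():
            raise ScenarioError("silent proportion outside [0, 1]")
        p_silent[g] = ps

    # maternal fraction per gene x sample
    pi = np.empty((n, n_samples))
    for j, g in enumerate(genotypes):
        ps = p_silent[g]
        pi[:, j] = np.where(archetypes == "maternal_expressed", 1.0 - ps,
                            np.where(archetypes == "paternal_expressed", ps,
                                     0.5))

    total = _negbin(rng, mu[:, None], scenario.nb_dispersion, (n, n_samples))
    depth = rng.binomial(total, scenario.haplotyping_efficiency)
    maternal = _betabinom(rng, depth, pi, scenario.rho)
    paternal = depth - maternal
    informative = depth > 0

    chroms = sorted(scenario.chrom_lengths)
    genes = []
    spacing = 50_000
    per_chrom = -(-n // len(chroms))
    for i in range(n):
        chrom = chroms[i // per_chrom]
        start = (i % per_chrom) * spacing
        genes.append(GeneAnnotation(f"gene{i:05d}", chrom, start,
                                    start + 20_000, "+",
                                    bool(known[i]), None))

    matrix = AlleleCountMatrix(genes, sheet["sample_id"].tolist(),
                               maternal, paternal, total, informative)
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "archetype": archetypes,
        "known_imprinted": known,
        "affected": affected,
        "mu": mu,
        "silent_allele": np.where(
            archetypes == "maternal_expressed", "paternal",
            np.where(archetypes == "paternal_expressed", "maternal", "NA")),
    })
    wt_ps = p_silent.get("wt")
    for g in geno_levels:
        truth[f"p_silent.{g}"] = p_silent[g]
        truth[f"delta.{g}"] = (p_silent[g] - wt_ps if wt_ps is not None
                               else np.nan)
    return matrix, sheet, truth


def simulate_backcross_bins(scenario: SimulationScenario,
                            sample_ids=None):
    """Binned Cast-proportion tracks for N1 samples plus true segments.

    Returns ``(tracks, truth)`` where ``tracks`` maps sample_id to a
    :class:`GenomicBinTrack` and ``truth`` lists the true zygosity
    segments (sample, chrom, zygosity, first_bin, last_bin).
    """
    rng = _rng(scenario, 2)
    if sample_ids is None:
        sample_ids = [f"{g}_{scenario.cre_lines[0]}_{k + 1}"
                      for g, c in scenario.samples_per_genotype.items()
                      for k in range(c)]
    hf = scenario.n1_het_fraction
    mean = scenario.n1_mean_segment_bins
    lo = scenario.n1_min_segment_bins
    tracks: dict[str, GenomicBinTrack] = {}
    truth_rows = []
    for sample in sample_ids:
        cast: dict[str, np.ndarray] = {}
        total: dict[str, np.ndarray] = {}
        for chrom, length in sorted(scenario.chrom_lengths.items()):
            n_bins = length // scenario.bin_width
            state = bool(rng.random() < hf)  # True = het
            pos = 0
            states = np.empty(n_bins, dtype=bool)
            while pos < n_bins:
                frac = hf if state else 1.0 - hf
                if frac >= 1.0:
                    seg_len = n_bins - pos
                else:
                    seg_mean = max(mean * frac / 0.5, lo + 1.0)
                    seg_len = lo + rng.geometric(1.0 / (seg_mean - lo))
                seg_len = min(seg_len, n_bins - pos)
                states[pos:pos + seg_len] = state
                truth_rows.append({"sample": sample, "chrom": chrom,
                                   "zygosity": "het" if state else "hom",
                                   "first_bin": pos,
                                   "last_bin": pos + seg_len - 1})
                pos += seg_len
                state = not state
            tot = rng.poisson(scenario.n1_bin_depth, n_bins)
            p = np.where(states, 0.5, scenario.n1_hom_epsilon)
            c = _betabinom(rng, tot, p, scenario.n1_rho)
            cast[chrom] = c.astype(np.int64)
            total[chrom] = tot.astype(np.int64)
        tracks[sample] = GenomicBinTrack(sample, scenario.bin_width, cast,
                                         total)
    truth = pd.DataFrame(truth_rows, columns=["sample", "chrom", "zygosity",
                                              "first_bin", "last_bin"])
    return tracks, truth


_METH_ARCHETYPES = {
    # (hyper-allele mC, hypo-allele mC); None = no allelic difference
    "germline_DMR": (0.95, 0.05),
    "secondary_DMR": (0.75, 0.25),
    "cpg_island": (0.05, 0.05),
    "promoter": (0.20, 0.20),
    "bin10kb": (0.70, 0.70),
}


def simulate_methylation(scenario: SimulationScenario,
                         regions: pd.DataFrame, sheet: pd.DataFrame):
    """Allelic methylated/unmethylated counts per region and sample.

    Germline and secondary DMR archetypes put the high methylation level
    on one randomly chosen parental allele; affected regions lose
    ``meth_shift[genotype]`` from the hypermethylated allele in non-wt
    genotypes.  Returns ``(MethylationRegionCounts, truth)``.
    """
    rng = _rng(scenario, 3)
    rows = []
    truth_rows = []
    geno = dict(zip(sheet["sample_id"], sheet["genotype"]))
    for region in regions.itertuples(index=False):
        hi, lo_level = _METH_ARCHETYPES[region.region_class]
        hyper = "maternal" if rng.random() < 0.5 else "paternal"
        dmr_like = region.region_class in ("germline_DMR", "secondary_DMR")
        affected = dmr_like and (rng.random() < scenario.frac_meth_affected)
        truth_rows.append({"region": region.name,
                           "region_class": region.region_class,
                           "hyper_allele": hyper if dmr_like else "NA",
                           "m_hyper": hi, "m_hypo": lo_level,
                           "affected": affected})
        for sample, g in geno.items():
            shift = scenario.meth_shift.get(g, 0.0) if (affected and g != "wt") else 0.0
            levels = {"maternal": hi if hyper == "maternal" else lo_level,
                      "paternal": hi if hyper == "paternal" else lo_level}
            if dmr_like:
                levels[hyper] = max(hi - shift, 0.0)
            for allele in ("maternal", "paternal"):
                cov = rng.poisson(scenario.meth_coverage)
                meth = int(_betabinom(rng, np.array([cov]),
                                      levels[allele], scenario.meth_rho)[0])
                rows.append((region.name, sample, allele, meth, cov - meth))
            cov = rng.poisson(2 * scenario.meth_coverage)
            mean_level = 0.5 * (levels["maternal"] + levels["paternal"])
            meth = int(_betabinom(rng, np.array([cov]), mean_level,
                                  scenario.meth_rho)[0])
            rows.append((region.name, sample, "unsplit", meth, cov - meth))
    counts = pd.DataFrame(rows, columns=["region", "sample", "allele",
                                         "meth", "unmeth"])
    truth = pd.DataFrame(truth_rows)
    return MethylationRegionCounts(regions, counts), truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")
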