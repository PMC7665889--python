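"""End-to-end orchestration: simulate -> segment -> call-imprinted ->
test -> methylation -> report, with a manifest for reproducibility.

Each stage reads and writes plain TSV files in the output directory, so
stages can be rerun individually and any stage's inputs can be swapped
for real data files in the same formats.  Identical config + inputs +
seed produce byte-identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .data import (read_allele_counts, read_gene_annotation,
                   read_sample_sheet, write_allele_counts,
                   write_gene_annotation, write_sample_sheet)
from .differential import (call_differential, test_differential_imprinting,
                           write_differential_results)
from .imprinting import (call_imprinted, calls_to_frame,
                         silent_allele_proportions, write_imprinting_calls,
                         write_silent_table)
from .methylation import (select_testable_dmrs, test_dmr_differential,
                          test_genomewide_methylation)
from .segmentation import (apply_informativeness, read_bin_track,
                           segment_allelic_proportions, write_bin_track,
                           write_segments_bed)
from .simulate import (SimulationScenario, simulate_backcross_bins,
                       simulate_expression, simulate_methylation, write_truth)

__all__ = ["STAGES", "DependencyError", "run_pipeline", "report",
           "example_regions", "load_scenario"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "segment", "call-imprinted", "test", "methylation",
          "report"]


class DependencyError(RuntimeError):
    """A stage's upstream outputs are missing."""


def example_regions() -> pd.DataFrame:
    """A small synthetic region panel spanning every region class."""
    rows = []
    pos = 0
    specs = [("germline_DMR", 8, 4_000), ("secondary_DMR", 4, 4_000),
             ("cpg_island", 6, 1_000), ("promoter", 4, 2_000),
             ("bin10kb", 8, 10_000)]
    for cls, count, width in specs:
        for k in range(count):
            rows.append({"chrom": "1", "start": pos, "end": pos + width,
                         "name": f"{cls}_{k + 1}", "region_class": cls})
            pos += width + 20_000
    return pd.DataFrame(rows)


def load_scenario(path: str | Path | None, seed: int | None = None,
                  **overrides) -> SimulationScenario:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if seed is not None:
        data["seed"] = seed
    known = {f.name for f in dataclasses.fields(SimulationScenario)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "cre_lines" in data:
        data["cre_lines"] = tuple(data["cre_lines"])
    return SimulationScenario(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, names: list[str], stage: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} requires missing upstream outputs: {missing}")


def run_pipeline(outdir: str | Path, config: AnalysisConfig,
                 scenario: SimulationScenario | None = None,
                 stages: list[str] | None = None,
                 engine: str | None = None) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    Stage outputs (all TSV, in ``outdir``): counts.tsv, genes.tsv,
    samples.tsv, truth_*.tsv, bins/<sample>.tsv, segments.bed,
    imprinting_calls.tsv, silent_allele_proportions.tsv,
    differential_results.tsv, dmr_results.tsv,
    genomewide_methylation.tsv, report.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(STAGES)
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    stages = [s for s in STAGES if s in stages]
    if scenario is None:
        scenario = SimulationScenario(seed=config.rng_seed)
    manifest: dict = {"tool": "imprintcall", "version": __version__,
                      "seed": scenario.seed, "config": config.to_dict(),
                      "stages": {}}

    def record(stage: str, t0: float, files: list[str], rows: dict) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f: _sha256(outdir / f) for f in files},
            "rows": rows,
        }

    for stage in stages:
        t0 = time.time()
        logger.info("[%s] starting", stage)
        if stage == "simulate":
            matrix, sheet, truth = simulate_expression(scenario)
            write_allele_counts(matrix, outdir / "counts.tsv")
            write_gene_annotation(matrix.genes, outdir / "genes.tsv")
            write_sample_sheet(sheet, outdir / "samples.tsv")
            write_truth(truth, outdir / "truth_expression.tsv")
            files = ["counts.tsv", "genes.tsv", "samples.tsv",
                     "truth_expression.tsv"]
            rows = {"genes": matrix.n_genes, "samples": matrix.n_samples}
            if scenario.cross == "N1":
                tracks, seg_truth = simulate_backcross_bins(
                    scenario, sheet["sample_id"].tolist())
                bindir = outdir / "bins"
                bindir.mkdir(exist_ok=True)
                for sample, track in tracks.items():
                    write_bin_track(track, bindir / f"{sample}.tsv")
                    files.append(f"bins/{sample}.tsv")
                write_truth(seg_truth, outdir / "truth_segments.tsv")
                files.append("truth_segments.tsv")
            regions = example_regions()
            mrc, meth_truth = simulate_methylation(scenario, regions, sheet)
            regions.to_csv(outdir / "meth_regions.tsv", sep="\t", index=False)
            mrc.counts.to_csv(outdir / "meth_counts.tsv", sep="\t",
                              index=False)
            write_truth(meth_truth, outdir / "truth_methylation.tsv")
            files += ["meth_regions.tsv", "meth_counts.tsv",
                      "truth_methylation.tsv"]
            record(stage, t0, files, rows)

        elif stage == "segment":
            _require(outdir, ["samples.tsv"], stage)
            sheet = read_sample_sheet(outdir / "samples.tsv")
            n1 = sheet.loc[sheet["cross"] == "N1", "sample_id"].tolist()
            models = {}
            for sample in n1:
                path = outdir / "bins" / f"{sample}.tsv"
                if not path.exists():
                    raise DependencyError(
                        f"stage 'segment' requires bins/{sample}.tsv")
                track = read_bin_track(path, sample, config.bin_width)
                models[sample] = segment_allelic_proportions(track, config)
            write_segments_bed(models, outdir / "segments.bed")
            if n1:
                _require(outdir, ["counts.tsv", "genes.tsv"], stage)
                genes = read_gene_annotation(outdir / "genes.tsv")
                matrix = read_allele_counts(outdir / "counts.tsv", genes)
                matrix = apply_informativeness(matrix, sheet, models)
                write_allele_counts(matrix, outdir / "counts.tsv")
            record(stage, t0, ["segments.bed"],
                   {"samples": len(models),
                    "segments": sum(len(m.segments) for m in models.values())})

        elif stage == "call-imprinted":
            _require(outdir, ["counts.tsv", "genes.tsv", "samples.tsv"], stage)
            genes = read_gene_annotation(outdir / "genes.tsv")
            matrix = read_allele_counts(outdir / "counts.tsv", genes)
            sheet = read_sample_sheet(outdir / "samples.tsv")
            calls = call_imprinted(matrix, sheet, config)
            write_imprinting_calls(calls, outdir / "imprinting_calls.tsv")
            silent = silent_allele_proportions(matrix, calls)
            write_silent_table(silent,
                               outdir / "silent_allele_proportions.tsv")
            record(stage, t0, ["imprinting_calls.tsv",
                               "silent_allele_proportions.tsv"],
                   {"candidates": len(calls),
                    "imprinted": sum(c.imprinted for c in calls)})

        elif stage == "test":
            _require(outdir, ["counts.tsv", "genes.tsv", "samples.tsv",
                              "imprinting_calls.tsv",
                              "silent_allele_proportions.tsv"], stage)
            genes = read_gene_annotation(outdir / "genes.tsv")
            matrix = read_allele_counts(outdir / "counts.tsv", genes)
            sheet = read_sample_sheet(outdir / "samples.tsv")
            calls = call_imprinted(matrix, sheet, config)
            silent = silent_allele_proportions(matrix, calls)
            use_engine = engine
            if use_engine is None:
                use_engine = ("betabin" if (sheet["cross"] == "N1").any()
                              else "paired_nb")
            results = test_differential_imprinting(matrix, sheet, calls,
                                                   config, engine=use_engine)
            results = call_differential(results, silent, sheet, config)
            write_differential_results(results,
                                       outdir / "differential_results.tsv")
            record(stage, t0, ["differential_results.tsv"],
                   {"tested": len(results),
                    "called": int(results["called"].sum())})

        elif stage == "methylation":
            _require(outdir, ["meth_regions.tsv", "meth_counts.tsv",
                              "samples.tsv"], stage)
            from .methylation import MethylationRegionCounts, read_regions
            regions = read_regions(outdir / "meth_regions.tsv")
            counts = pd.read_csv(outdir / "meth_counts.tsv", sep="\t")
            mrc = MethylationRegionCounts(regions, counts)
            sheet = read_sample_sheet(outdir / "samples.tsv")
            test_geno = next((g for g in sheet["genotype"].unique()
                              if g != "wt"), None)
            if test_geno is None:
                raise DependencyError("methylation stage needs a non-wt genotype")
            testable = select_testable_dmrs(mrc, sheet, config, test_geno)
            dmr = test_dmr_differential(mrc, testable, sheet, config,
                                        test_geno)
            dmr.to_csv(outdir / "dmr_results.tsv", sep="\t", index=False,
                       float_format="%.6g")
            gw = test_genomewide_methylation(mrc, sheet, config, test_geno)
            gw.to_csv(outdir / "genomewide_methylation.tsv", sep="\t",
                      index=False, float_format="%.6g")
            record(stage, t0, ["dmr_results.tsv",
                               "genomewide_methylation.tsv"],
                   {"dmrs_tested": len(dmr),
                    "dmrs_called": int(dmr["called"].sum()) if len(dmr) else 0,
                    "genomewide_tested": len(gw)})

        elif stage == "report":
            table = report(outdir)
            table.to_csv(outdir / "report.tsv", sep="\t", index=False,
                         float_format="%.6g")
            record(stage, t0, ["report.tsv"], {"rows": len(table)})

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(results_dir: str | Path) -> pd.DataFrame:
    """One row per tested gene: call, effect sizes, p-values, cluster.

    A pure function of the result files in ``results_dir``.
    """
    results_dir = Path(results_dir)
    _require(results_dir, ["differential_results.tsv",
                           "imprinting_calls.tsv"], "report")
    diff = pd.read_csv(results_dir / "differential_results.tsv", sep="\t")
    calls = pd.read_csv(results_dir / "imprinting_calls.tsv", sep="\t")
    if diff.empty:
        cols = ["gene_id", "cluster", "silent_allele", "engine", "p_adj",
                "max_abs_delta", "called"]
        return pd.DataFrame(columns=cols)
    merged = diff.merge(calls[["gene_id", "cluster", "silent_allele",
                               "log_ratio"]], on="gene_id", how="left")
    cols = ["gene_id", "cluster", "silent_allele", "log_ratio", "engine",
            "lrt_statistic", "p", "p_adj", "max_abs_delta", "called"]
    delta_cols = [c for c in merged.columns if c.startswith("delta.")]
    return merged[cols[:9] + delta_cols + cols[9:]].sort_values(
        "gene_id", kind="stable").reset_index(drop=True)
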