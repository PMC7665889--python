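"""Core containers and shared statistics for allele-specific analyses.

The central object is :class:`AlleleCountMatrix`: per gene and per sample it
carries the haplotype-resolved maternal and paternal read counts alongside
the non-haplotyped total, plus an informativeness mask.  Cells where no
allele assignment was possible (no strain-distinguishing SNP coverage, or a
homozygous region in a backcross sample) are non-informative: the allelic
counts are treated as missing by every downstream test while the total is
retained for expression filtering.

Also here: CPM, the expression filter, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IntegrityError",
    "GeneAnnotation",
    "AlleleCountMatrix",
    "GENOTYPES",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_sample_sheet",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_allele_counts",
    "write_allele_counts",
    "cpm",
    "filter_expressed",
    "bh_adjust",
]

GENOTYPES = ("wt", "het", "matD", "zygD", "matzygD")
_GENOTYPE_ALIASES = {"matΔ": "matD", "zygΔ": "zygD",
                     "matzygΔ": "matzygD"}
CRE_LINES = ("MMTV", "Zp3", "none")
SEX_CHROMOSOMES = frozenset({"X", "Y", "MT", "chrX", "chrY", "chrM", "chrMT"})


class FormatError(ValueError):
    """A file violates the expected layout or value domain."""


class IntegrityError(ValueError):
    """Values parse but violate a cross-field invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A single gene record; tables of these travel as DataFrames."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str = "NA"
    is_known_imprinted: bool = False
    cluster: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise IntegrityError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def is_autosomal(self) -> bool:
        return self.chrom not in SEX_CHROMOSOMES


_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand",
              "is_known_imprinted", "cluster"]


def genes_to_frame(genes: Iterable[GeneAnnotation]) -> pd.DataFrame:
    rows = [(g.gene_id, g.chrom, g.start, g.end, g.strand,
             g.is_known_imprinted, g.cluster if g.cluster is not None else ".")
            for g in genes]
    df = pd.DataFrame(rows, columns=_GENE_COLS)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise IntegrityError(f"duplicate gene_id {dup!r}")
    return df


def frame_to_genes(df: pd.DataFrame) -> list[GeneAnnotation]:
    out = []
    for row in df.itertuples(index=False):
        cluster = None if row.cluster in (".", "", None) or pd.isna(row.cluster) \
            else str(row.cluster)
        out.append(GeneAnnotation(str(row.gene_id), str(row.chrom),
                                  int(row.start), int(row.end),
                                  str(row.strand),
                                  bool(row.is_known_imprinted), cluster))
    return out


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"gene annotation missing columns {sorted(missing)}")
    df["is_known_imprinted"] = df["is_known_imprinted"].astype(bool)
    return frame_to_genes(df)


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    genes_to_frame(genes).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet

_SHEET_COLS = ["sample_id", "genotype", "cre", "tissue", "cross",
               "maternal_strain", "paternal_strain", "sex"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = set(_SHEET_COLS) - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns {sorted(missing)}")
    sheet = sheet.copy()
    sheet["genotype"] = sheet["genotype"].replace(_GENOTYPE_ALIASES)
    bad = set(sheet["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"unknown genotypes {sorted(bad)}")
    bad = set(sheet["cre"]) - set(CRE_LINES)
    if bad:
        raise FormatError(f"unknown Cre lines {sorted(bad)}")
    bad = set(sheet["cross"]) - {"F1", "N1"}
    if bad:
        raise FormatError(f"unknown cross designs {sorted(bad)}")
    if sheet["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in sample sheet")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet)[_SHEET_COLS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele count matrix

class AlleleCountMatrix:
    """Gene x sample maternal/paternal/total counts with an informative mask.

    Parameters
    ----------
    genes
        Gene annotations, one per row of the count arrays, in order.
    samples
        Sample identifiers, one per column.
    maternal, paternal, total
        Integer count arrays of shape ``(n_genes, n_samples)``.  ``total``
        is the non-haplotyped count and bounds ``maternal + paternal``
        from above (unassignable reads contribute to the total only).
    informative
        Boolean mask; where False the allelic counts are missing and the
        stored maternal/paternal values are ignored by all analyses.
    """

    def __init__(self, genes: Sequence[GeneAnnotation], samples: Sequence[str],
                 maternal: np.ndarray, paternal: np.ndarray,
                 total: np.ndarray, informative: np.ndarray | None = None):
        self.genes = list(genes)
        self.samples = list(samples)
        maternal = np.asarray(maternal, dtype=np.int64)
        paternal = np.asarray(paternal, dtype=np.int64)
        total = np.asarray(total, dtype=np.int64)
        shape = (len(self.genes), len(self.samples))
        for name, arr in (("maternal", maternal), ("paternal", paternal),
                          ("total", total)):
            if arr.shape != shape:
                raise FormatError(f"{name} has shape {arr.shape}, expected {shape}")
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative {name} count at gene {self.genes[g].gene_id!r}, "
                    f"sample {self.samples[s]!r}")
        if informative is None:
            informative = np.ones(shape, dtype=bool)
        informative = np.asarray(informative, dtype=bool)
        over = informative & (maternal + paternal > total)
        if over.any():
            g, s = np.argwhere(over)[0]
            raise IntegrityError(
                f"maternal+paternal > total at gene {self.genes[g].gene_id!r}, "
                f"sample {self.samples[s]!r} "
                f"({maternal[g, s]}+{paternal[g, s]} > {total[g, s]})")
        if len({g.gene_id for g in self.genes}) != len(self.genes):
            raise IntegrityError("duplicate gene_id in count matrix")
        self.maternal = maternal
        self.paternal = paternal
        self.total = total
        self.informative = informative

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def library_size(self) -> np.ndarray:
        """Per-sample library size: the column sum of total counts."""
        return self.total.sum(axis=0)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "AlleleCountMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return AlleleCountMatrix(self.genes, [self.samples[i] for i in idx],
                                 self.maternal[:, idx], self.paternal[:, idx],
                                 self.total[:, idx], self.informative[:, idx])

    def haplotyped(self) -> np.ndarray:
        """Maternal+paternal counts as float, NaN where non-informative."""
        hap = (self.maternal + self.paternal).astype(float)
        hap[~self.informative] = np.nan
        return hap


def read_allele_counts(path: str | Path,
                       annotation: Sequence[GeneAnnotation]) -> AlleleCountMatrix:
    """Read a TSV count matrix: ``gene_id`` then per-sample
    ``<sample>.maternal``, ``<sample>.paternal``, ``<sample>.total`` columns.

    Allelic cells containing ``.`` mark non-informative gene/sample pairs;
    the total is always required.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene_id":
        raise FormatError("first column must be gene_id")
    samples: list[str] = []
    for col in df.columns[1:]:
        if "." not in col:
            raise FormatError(f"column {col!r} is not <sample>.<field>")
        sample, field = col.rsplit(".", 1)
        if field not in ("maternal", "paternal", "total"):
            raise FormatError(f"unknown field {field!r} in column {col!r}")
        if sample not in samples:
            samples.append(sample)
    for s in samples:
        for field in ("maternal", "paternal", "total"):
            if f"{s}.{field}" not in df.columns:
                raise FormatError(f"missing column {s}.{field}")

    ann = {g.gene_id: g for g in annotation}
    genes = []
    for gid in df["gene_id"]:
        if gid not in ann:
            raise FormatError(f"gene {gid!r} absent from annotation")
        genes.append(ann[gid])

    def parse(field: str, allow_missing: bool) -> tuple[np.ndarray, np.ndarray]:
        vals = np.zeros((len(df), len(samples)), dtype=np.int64)
        present = np.ones((len(df), len(samples)), dtype=bool)
        for j, s in enumerate(samples):
            col = df[f"{s}.{field}"]
            miss = col.isna() | (col == ".")
            if miss.any() and not allow_missing:
                raise FormatError(f"missing total count for sample {s!r}")
            try:
                vals[:, j] = np.where(miss, 0, col.where(~miss, "0")).astype(np.int64)
            except ValueError as exc:
                raise FormatError(f"non-integer count in {s}.{field}: {exc}") from None
            present[:, j] = ~miss.to_numpy()
        return vals, present

    maternal, m_ok = parse("maternal", allow_missing=True)
    paternal, p_ok = parse("paternal", allow_missing=True)
    total, _ = parse("total", allow_missing=False)
    informative = m_ok & p_ok
    return AlleleCountMatrix(genes, samples, maternal, paternal, total,
                             informative)


def write_allele_counts(matrix: AlleleCountMatrix, path: str | Path) -> None:
    cols: dict[str, list] = {"gene_id": matrix.gene_ids}
    for j, s in enumerate(matrix.samples):
        m = [str(matrix.maternal[i, j]) if matrix.informative[i, j] else "."
             for i in range(matrix.n_genes)]
        p = [str(matrix.paternal[i, j]) if matrix.informative[i, j] else "."
             for i in range(matrix.n_genes)]
        cols[f"{s}.maternal"] = m
        cols[f"{s}.paternal"] = p
        cols[f"{s}.total"] = [str(t) for t in matrix.total[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shared statistics

def cpm(total: np.ndarray, library_size: np.ndarray) -> np.ndarray:
    """Counts per million: ``total[g, s] / library_size[s] * 1e6``."""
    total = np.asarray(total, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (library_size <= 0).any():
        raise ValueError("library sizes must be strictly positive")
    return total / library_size * 1e6


def filter_expressed(matrix: AlleleCountMatrix, config) -> set[str]:
    """Genes expressed at >= ``cpm_min`` in >= ``cpm_frac_libs`` of libraries.

    Computed on the non-haplotyped totals; the fraction is compared as a
    real number (a gene passing in exactly n/3 libraries is retained).
    """
    if matrix.n_samples < 1:
        raise ValueError("count matrix has no samples")
    rates = cpm(matrix.total, matrix.library_size)
    n_pass = (rates >= config.cpm_min).sum(axis=1)
    keep = n_pass >= config.cpm_frac_libs * matrix.n_samples
    return {g.gene_id for g, k in zip(matrix.genes, keep) if k}


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are passed through and do not count toward the number of
    tests; the input order is preserved and values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    out[mask] = adjusted
    return out
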