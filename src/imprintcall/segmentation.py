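"""Informativeness segmentation for backcross samples.

N1 backcross animals (CastB6 F1 x C57BL/6) are heterozygous over roughly
half of the genome; allelic tests are only meaningful inside heterozygous
regions.  Each sample's genome is tiled in fixed-width bins carrying the
Cast-allele read proportion, and a piecewise-constant regression tree is
grown per chromosome on bin index: at each node the split minimizing the
within-segment sum of squared errors is taken, accepted only when the node
holds at least ``minsplit`` observations and the split reduces the error by
at least ``cp`` times the chromosome's root SSE (cost-complexity rule).
Tree leaves become segments; a segment is heterozygous when its fitted
Cast proportion reaches the zygosity threshold (heterozygous bins sit near
0.5, homozygous-B6 bins near 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AlleleCountMatrix, GeneAnnotation

__all__ = [
    "GenomicBinTrack",
    "Segment",
    "SegmentModel",
    "read_bin_track",
    "write_bin_track",
    "segment_allelic_proportions",
    "project_informativeness",
    "apply_informativeness",
    "write_segments_bed",
]

logger = logging.getLogger(__name__)


@dataclass
class GenomicBinTrack:
    """Per-sample binned allelic read counts, one array pair per chromosome.

    Bins tile each chromosome in order; bin ``i`` spans
    ``[i * bin_width, (i + 1) * bin_width)``.
    """

    sample_id: str
    bin_width: int
    cast: dict[str, np.ndarray]
    total: dict[str, np.ndarray]

    def proportions(self, min_depth: int = 0) -> dict[str, np.ndarray]:
        """Cast-read proportion per bin; NaN where depth < ``min_depth``."""
        out = {}
        for chrom, tot in self.total.items():
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(tot > 0, self.cast[chrom] / np.maximum(tot, 1), np.nan)
            p = np.where(tot >= max(min_depth, 1), p, np.nan)
            out[chrom] = p
        return out


@dataclass(frozen=True)
class Segment:
    chrom: str
    first_bin: int
    last_bin: int  # inclusive bin index
    fitted_proportion: float
    zygosity: str  # "het" or "hom"
    n_bins: int    # non-missing member bins


@dataclass
class SegmentModel:
    sample_id: str
    bin_width: int
    segments: list[Segment]

    def segments_for(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def segment_at(self, chrom: str, pos: int) -> Segment | None:
        """The segment whose bin span contains ``pos`` (bp), if any."""
        for seg in self.segments_for(chrom):
            if seg.first_bin * self.bin_width <= pos < (seg.last_bin + 1) * self.bin_width:
                return seg
        return None


def read_bin_track(path: str | Path, sample_id: str,
                   bin_width: int) -> GenomicBinTrack:
    """Read a bin TSV (chrom, bin_start, cast, total), densifying each
    chromosome so bins tile it from 0 to the last reported bin."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cast: dict[str, np.ndarray] = {}
    total: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        idx = (sub["bin_start"].to_numpy() // bin_width).astype(int)
        n = int(idx.max()) + 1 if len(idx) else 0
        c = np.zeros(n, dtype=np.int64)
        t = np.zeros(n, dtype=np.int64)
        c[idx] = sub["cast"].to_numpy()
        t[idx] = sub["total"].to_numpy()
        cast[chrom], total[chrom] = c, t
    return GenomicBinTrack(sample_id, bin_width, cast, total)


def write_bin_track(track: GenomicBinTrack, path: str | Path) -> None:
    rows = []
    for chrom in sorted(track.cast):
        for i, (c, t) in enumerate(zip(track.cast[chrom], track.total[chrom])):
            rows.append((chrom, i * track.bin_width, int(c), int(t)))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "cast", "total"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# the tree

def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _grow(idx: np.ndarray, y: np.ndarray, minsplit: int, threshold: float,
          leaves: list[tuple[np.ndarray, np.ndarray]]) -> None:
    """Recursive greedy splitting; ``threshold`` = cp * root SSE."""
    n = y.size
    if n < minsplit or n < 2:
        leaves.append((idx, y))
        return
    node_sse = _sse(y)
    if node_sse <= 0.0:
        leaves.append((idx, y))
        return
    # prefix sums give SSE of every left/right split in O(n)
    cs = np.cumsum(y)
    cs2 = np.cumsum(y * y)
    k = np.arange(1, n)  # left part size
    left_sse = cs2[:-1] - cs[:-1] ** 2 / k
    right_sse = (cs2[-1] - cs2[:-1]) - (cs[-1] - cs[:-1]) ** 2 / (n - k)
    split_sse = left_sse + right_sse
    best = int(np.argmin(split_sse))  # leftmost on ties
    improvement = node_sse - float(split_sse[best])
    if improvement < threshold:
        leaves.append((idx, y))
        return
    cut = best + 1
    _grow(idx[:cut], y[:cut], minsplit, threshold, leaves)
    _grow(idx[cut:], y[cut:], minsplit, threshold, leaves)


def segment_allelic_proportions(track: GenomicBinTrack,
                                config) -> SegmentModel:
    """Fit the per-chromosome regression tree and return its leaf segments.

    Bins below ``config.min_bin_depth`` allelic reads are treated as
    missing: skipped by the fit but spanned by the segment containing
    their neighbours.  Chromosomes with no usable bin yield no segments.
    """
    props = track.proportions(min_depth=config.min_bin_depth)
    segments: list[Segment] = []
    for chrom in sorted(props):
        p = props[chrom]
        ok = ~np.isnan(p)
        if not ok.any():
            logger.warning("sample %s: chromosome %s has no usable bins",
                           track.sample_id, chrom)
            continue
        idx = np.flatnonzero(ok)
        y = p[idx]
        threshold = config.tree_cp * _sse(y)
        leaves: list[tuple[np.ndarray, np.ndarray]] = []
        _grow(idx, y, config.tree_minsplit, threshold, leaves)
        for leaf_idx, leaf_y in leaves:
            fitted = float(leaf_y.mean())
            zyg = "het" if fitted >= config.zygosity_threshold else "hom"
            segments.append(Segment(chrom, int(leaf_idx[0]), int(leaf_idx[-1]),
                                    fitted, zyg, int(leaf_idx.size)))
    return SegmentModel(track.sample_id, track.bin_width, segments)


def project_informativeness(model: SegmentModel,
                            genes: list[GeneAnnotation]) -> pd.Series:
    """Per-gene informativeness for one sample: True when the gene's
    midpoint lies inside a heterozygous segment."""
    chroms = {s.chrom for s in model.segments}
    flags = {}
    warned: set[str] = set()
    for g in genes:
        if g.chrom not in chroms:
            if g.chrom not in warned:
                logger.warning("sample %s: chromosome %s has no segments",
                               model.sample_id, g.chrom)
                warned.add(g.chrom)
            flags[g.gene_id] = False
            continue
        seg = model.segment_at(g.chrom, g.midpoint)
        flags[g.gene_id] = seg is not None and seg.zygosity == "het"
    return pd.Series(flags, name=model.sample_id)


def apply_informativeness(matrix: AlleleCountMatrix, sheet: pd.DataFrame,
                          models: dict[str, SegmentModel]) -> AlleleCountMatrix:
    """Mask allelic counts of N1 samples outside heterozygous segments.

    F1 samples keep their existing mask (informative wherever allelic
    reads were assignable).
    """
    informative = matrix.informative.copy()
    cross = dict(zip(sheet["sample_id"], sheet["cross"]))
    for j, sample in enumerate(matrix.samples):
        if cross.get(sample) != "N1":
            continue
        if sample not in models:
            raise KeyError(f"N1 sample {sample!r} has no segmentation model")
        flags = project_informativeness(models[sample], matrix.genes)
        informative[:, j] &= flags.reindex(matrix.gene_ids).to_numpy(dtype=bool)
    return AlleleCountMatrix(matrix.genes, matrix.samples, matrix.maternal,
                             matrix.paternal, matrix.total, informative)


def write_segments_bed(models: dict[str, SegmentModel],
                       path: str | Path) -> None:
    rows = []
    for sample in sorted(models):
        m = models[sample]
        for s in m.segments:
            rows.append((s.chrom, s.first_bin * m.bin_width,
                         (s.last_bin + 1) * m.bin_width, sample,
                         f"{s.fitted_proportion:.6f}", s.zygosity))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                "fitted_proportion", "zygosity"]) \
        .to_csv(path, sep="\t", index=False)
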