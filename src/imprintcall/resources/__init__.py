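"""Bundled illustrative annotation resources.

Both tables are *synthetic placeholders*: the gene and region names cover
the well-known mouse imprinted clusters (Snrpn, Igf2r-Airn, Kcnq1, Jade1,
and the lone non-canonical genes) so examples and pipelines have something
realistic to chew on, but the coordinates are round-number stand-ins, not
genome-build annotation.  Real analyses should supply their own curated
known-imprinted gene list and imprinted-DMR coordinates in the same TSV
formats.
"""

from importlib import resources as _resources

import pandas as pd

from ..data import GeneAnnotation, frame_to_genes
from ..methylation import read_regions


def _path(name: str):
    return _resources.files(__package__) / name


def example_known_imprinted_genes() -> list[GeneAnnotation]:
    """Illustrative known-imprinted gene list (synthetic coordinates)."""
    with _resources.as_file(_path("known_imprinted_genes.synthetic.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chrom": str})
    return frame_to_genes(df)


def example_imprinted_dmrs() -> pd.DataFrame:
    """Illustrative imprinted-DMR region table (synthetic coordinates)."""
    with _resources.as_file(_path("imprinted_dmrs.synthetic.tsv")) as p:
        return read_regions(p)
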