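import numpy as np
import pandas as pd
import pytest

from imprintcall.config import AnalysisConfig
from imprintcall.data import AlleleCountMatrix, GeneAnnotation


@pytest.fixture
def config():
    return AnalysisConfig()


def make_genes(n, chrom="1", known=True, spacing=100_000):
    return [GeneAnnotation(f"g{i}", chrom, i * spacing, i * spacing + 10_000,
                           "+", known, None) for i in range(n)]


def make_sheet(genotypes, cre="MMTV", tissue="embryo_E9.5", cross="F1"):
    """Sample sheet from a genotype -> count mapping."""
    rows = []
    for geno, n in genotypes.items():
        for k in range(n):
            c = cre[k % len(cre)] if isinstance(cre, (list, tuple)) else cre
            rows.append({"sample_id": f"{geno}_{c}_{k}", "genotype": geno,
                         "cre": c, "tissue": tissue, "cross": cross,
                         "maternal_strain": "C57BL/6",
                         "paternal_strain": "CAST/EiJ", "sex": "NA"})
    return pd.DataFrame(rows)


def make_matrix(maternal, paternal, samples=None, genes=None, total=None,
                informative=None, known=True):
    maternal = np.atleast_2d(np.asarray(maternal))
    paternal = np.atleast_2d(np.asarray(paternal))
    if samples is None:
        samples = [f"s{j}" for j in range(maternal.shape[1])]
    if genes is None:
        genes = make_genes(maternal.shape[0], known=known)
    if total is None:
        total = maternal + paternal
    return AlleleCountMatrix(genes, samples, maternal, paternal, total,
                             informative)
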