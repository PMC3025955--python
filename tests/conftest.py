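import numpy as np
import pandas as pd
import pytest

from coregnet.promoterome import PMatrix
from coregnet.synthetic_data import GeneratorConfig, generate_dataset


def make_pmatrix(values, genes=None, tfs=None, expressed=()):
    values = np.asarray(values, dtype=np.uint8)
    g, t = values.shape
    genes = genes if genes is not None else [f"g{i+1}" for i in range(g)]
    tfs = tfs if tfs is not None else [f"t{j+1}" for j in range(t)]
    return PMatrix(genes, tfs, values, frozenset(expressed))


def make_hits(rows):
    """Build a hit table from (gene, tf[, core, matrix, ortho]) tuples."""
    out = []
    for row in rows:
        gene, tf = row[0], row[1]
        core = row[2] if len(row) > 2 else 1.0
        mat = row[3] if len(row) > 3 else 1.0
        ortho = row[4] if len(row) > 4 else True
        out.append((gene, f"{gene}_p1", tf, core, mat, ortho))
    return pd.DataFrame(out, columns=["gene_id", "promoter_id", "tf",
                                      "core_sim", "matrix_sim", "ortholog_ok"])


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic study with a denser-than-default incidence so the
    shared-TF statistics have populated strata."""
    cfg = GeneratorConfig(n_genes=400, n_tfs=40, tf_degree_exponent=1.3,
                          dual_fraction=0.0, noise_sd=0.6, seed=3)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """A dataset at generator defaults (1,000 genes, 60 TFs, 75% dual)."""
    return generate_dataset(GeneratorConfig(seed=7))
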