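import numpy as np
import pandas as pd
import pytest

from coexmap import discovery, eigengenes, simulate
from coexmap.types import FoldChangeMatrix


@pytest.fixture(scope="session")
def small_reference():
    """Small planted-module corpus shared across test modules."""
    fc, truth = simulate.generate_reference(
        n_genes=300,
        n_modules=8,
        module_size_range=(8, 40),
        n_conditions=120,
        loading_range=(0.7, 0.95),
        noise_sd=0.4,
        seed=11,
    )
    return fc, truth


@pytest.fixture(scope="session")
def small_modules(small_reference):
    """ModuleSet built from the true partition of the small corpus."""
    fc, truth = small_reference
    planted = truth.planted_modules()
    zfc = eigengenes.standardize_reference(fc)
    egs, raw_sd = eigengenes.compute_module_scores(planted, zfc)
    modules = eigengenes.compute_gene_stats(planted, fc, egs, raw_sd=raw_sd)
    return modules, egs


@pytest.fixture(scope="session")
def built_modules(small_reference):
    """ModuleSet from the full discovery pipeline on the small corpus."""
    fc, _ = small_reference
    modules, report = discovery.build_modules(fc)
    return modules, report


def make_fc(values, conditions=None, genes=None, adj_p=None):
    values = np.asarray(values, dtype=float)
    conditions = conditions or [f"cond{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=conditions, columns=genes)
    p = None
    if adj_p is not None:
        p = pd.DataFrame(np.asarray(adj_p, dtype=float), index=conditions, columns=genes)
    return FoldChangeMatrix(values=df, adj_p=p)
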