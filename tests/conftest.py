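import numpy as np
import pytest

from podoscreen.genes import GeneId
from podoscreen.io import ExpressionMatrix
from podoscreen.simulate import MixtureModelSpec, simulate_matrix


def make_matrix(values, compartment=None, keys=None, symbols=None):
    """Small ExpressionMatrix from a 2-D array of values."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if keys is None:
        keys = [f"ENSG{80000000000 + i:011d}" for i in range(n_genes)]
    genes = [
        GeneId(k, 1, (symbols[i] if symbols else None)) for i, k in enumerate(keys)
    ]
    samples = [f"s{j + 1}" for j in range(n_samples)]
    if compartment is None:
        compartment = ["cortex"] * n_samples
    return ExpressionMatrix(genes, samples, values, compartment)


@pytest.fixture(scope="session")
def default_sim():
    """One default-spec simulation shared by read-only tests."""
    spec = MixtureModelSpec(seed=1)
    return simulate_matrix(spec)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced mixture (fast) with the same structure."""
    spec = MixtureModelSpec(
        n_genes=600,
        n_cortex=40,
        n_medulla=4,
        signature_genes={
            "podocyte": tuple(range(0, 40)),
            "mesangial": tuple(range(40, 60)),
            "endothelial": tuple(range(60, 80)),
            "blood": tuple(range(80, 100)),
            "tubular": tuple(range(100, 140)),
        },
        seed=7,
    )
    return simulate_matrix(spec)
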