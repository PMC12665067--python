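import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

import seedspatial as ss
from seedspatial.gem import BinnedExpression

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_section():
    """A compact simulated seed section shared by fast unit tests."""
    template = ss.make_default_template(600)
    model = ss.default_gene_model()
    capture = ss.calibrate_capture_rate(template, model)
    gem, truth = ss.simulate_section(template, model, capture_rate=capture,
                                     seed=42)
    return {"template": template, "model": model, "capture": capture,
            "gem": gem, "truth": truth}


@pytest.fixture()
def toy_gem():
    """Four records over two DNBs, two genes each with one MID."""
    return pd.DataFrame({
        "geneID": ["g1", "g2", "g1", "g3"],
        "x": [0, 0, 7, 7],
        "y": [0, 0, 3, 3],
        "MIDCount": [1, 1, 1, 1],
    })


def make_binned(counts, bin_size=50, genes=None):
    """BinnedExpression from a dense bins x genes array, bins on a line."""
    counts = np.asarray(counts)
    n_bins, n_genes = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    bins = pd.DataFrame({"bin_x": np.arange(n_bins),
                         "bin_y": np.zeros(n_bins, dtype=int)})
    return BinnedExpression(bin_size=bin_size, bins=bins,
                            genes=pd.Index(genes, name="geneID"),
                            counts=sp.csr_matrix(counts))
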