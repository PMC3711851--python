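import numpy as np
import pandas as pd
import pytest

from heatshock import SimChipParams, SimExprParams, gen_chip, gen_expression


@pytest.fixture(scope="session")
def small_expression():
    """Desk-scale expression simulation shared across tests."""
    params = SimExprParams(n_genes=3000, seed=11)
    return params, *gen_expression(params)


@pytest.fixture(scope="session")
def small_chip():
    """Reduced-size ChIP simulation (fewer promoters, default geometry)."""
    params = SimChipParams(n_promoters=120, seed=7)
    return params, *gen_chip(params)


@pytest.fixture()
def tiny_matrix():
    """Two genes, two groups x two replicates, exact means."""
    cols = ["HEP_C_r1", "HEP_C_r2", "HEP_HS_r1", "HEP_HS_r2"]
    data = pd.DataFrame(
        [[9.18, 9.18, 11.65, 11.65], [10.09, 10.09, 7.93, 7.93]],
        index=pd.Index(["Hsph1", "g2"], name="gene"),
        columns=cols,
    )
    design = pd.DataFrame(
        {
            "sample_id": cols,
            "cell_type": ["HEP"] * 4,
            "condition": ["C", "C", "HS", "HS"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return data, design


def make_contrast_frame(slr_values, index=None):
    """Minimal contrast table around given SLR values (all evaluated)."""
    slr = np.asarray(slr_values, dtype=float)
    if index is None:
        index = pd.Index([f"g{i}" for i in range(len(slr))], name="gene")
    return pd.DataFrame(
        {
            "mean_c": 8.0,
            "mean_hs": 8.0 + slr,
            "slr": slr,
            "nl_c": False,
            "nl_hs": False,
            "de_class": "null",
            "posterior_up": 0.0,
            "posterior_down": 0.0,
        },
        index=index,
    )
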