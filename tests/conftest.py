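import numpy as np
import pandas as pd
import pytest

from metabopipe.core import MetaboDataset
from metabopipe.spectrum import Spectrum


def make_dataset(expr, classes=None, groups=None, batches=None, orders=None,
                 mz=None, rt=None, polarity="pos", ms2=None):
    """Hand-build a small MetaboDataset from a features x samples array."""
    expr = pd.DataFrame(expr)
    n_feat, n_samp = expr.shape
    fids = [f"F{i + 1}" for i in range(n_feat)]
    sids = [f"S{j + 1}" for j in range(n_samp)]
    expr.index = pd.Index(fids, name="feature_id")
    expr.columns = sids
    samples = pd.DataFrame(
        {
            "class": classes or ["Subject"] * n_samp,
            "group": groups or ["g1"] * n_samp,
            "batch": [str(b) for b in (batches or ["1"] * n_samp)],
            "injection_order": orders or list(range(1, n_samp + 1)),
        },
        index=pd.Index(sids, name="sample_id"),
    )
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100.0, 900.0, n_feat),
            "rt": rt if rt is not None else np.linspace(60.0, 600.0, n_feat),
            "polarity": polarity,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return MetaboDataset(expr.astype(float), samples, features, ms2 or {})


@pytest.fixture
def clean_dataset():
    """Well-formed 10 features x 6 samples (4 Subject in 2 groups + 2 QC)."""
    rng = np.random.default_rng(42)
    return make_dataset(
        rng.uniform(1e4, 1e6, size=(10, 6)),
        classes=["Subject"] * 4 + ["QC"] * 2,
        groups=["a", "a", "b", "b", "QC", "QC"],
    )


@pytest.fixture
def spec_simple():
    return Spectrum(precursor_mz=181.07, polarity="pos",
                    peaks=[(85.03, 100.0), (127.04, 40.0)])
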