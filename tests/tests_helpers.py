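"""Shared builders for synthetic epochs used across test modules."""

import numpy as np
import pandas as pd

import hemisync as hs
from hemisync.preprocessing import Epochs


def make_epochs(data, rate, layout=None):
    layout = layout or hs.default_layout()
    n = data.shape[0]
    labels = pd.DataFrame(
        {
            "percept": ["horizontal"] * n,
            "start": np.arange(n, dtype=float),
            "session": ["in_phase"] * n,
            "condition": ["sham"] * n,
        }
    )
    return Epochs(data=data, rate=rate, labels=labels, layout=layout)


def noise_epochs(n_epochs, n_samples, rate, seed=0):
    rng = np.random.default_rng(seed)
    return make_epochs(rng.standard_normal((n_epochs, 31, n_samples)), rate)


def mirrored_epochs(n_epochs, n_samples, rate, seed=0):
    """Epochs where each right channel is an exact copy of its paired left."""
    layout = hs.default_layout()
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, 31, n_samples))
    for li, ri in layout.pairs:
        data[:, ri, :] = data[:, li, :]
    return make_epochs(data, rate, layout)
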