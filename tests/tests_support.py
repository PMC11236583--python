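"""Small helpers shared between test modules."""

import numpy as np
import pandas as pd

from deltrain.simulate import EpochSet


def make_epochs(data, sr=250.0, cond="SLOW"):
    """Wrap a (trials, channels, samples) array as an EpochSet."""
    data = np.asarray(data, dtype=float)
    k, _, n = data.shape
    meta = pd.DataFrame(
        {
            "trial": np.arange(k),
            "contour_condition": cond,
            "sentence_length": 5,
            "phase": "entrainment",
            "n_samples": n,
            "block": 0,
        }
    )
    return EpochSet(data, sr, 0.0, meta)
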