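import numpy as np
import pandas as pd
import pytest

from mobikit.montage import make_montage


@pytest.fixture(scope="session")
def small_montage():
    return make_montage(["Fz", "FCz", "Cz", "CPz", "Pz", "C3", "C4", "Oz"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_mixed_table(rng, n_a=10, n_b=10, levels=("c1", "c2", "c3"),
                     effect=0.0, subject_sd=1.0, noise_sd=1.0):
    """Long-format split-plot table: one between group, one within factor."""
    rows = []
    for g, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            base = subject_sd * rng.standard_normal()
            for j, c in enumerate(levels):
                rows.append({
                    "participant": f"{g}{i:02d}", "group": g, "cond": c,
                    "value": base + effect * j + noise_sd * rng.standard_normal(),
                })
    return pd.DataFrame(rows)
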