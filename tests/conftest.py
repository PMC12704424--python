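import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sipracs as sp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_unlabeled():
    """Default unlabeled spectrum with baseline but no noise."""
    return sp.make_spectrum(sp.PeakModel(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def noiseless_labeled():
    return sp.make_spectrum(sp.PeakModel(noise_sd=0.0, labeled=True), seed=0)


def toy_fraction_table(treatment, heavy_cols, light_cols, asv_ids=None):
    """Build a FractionTable from explicit per-sample composition columns.

    ``heavy_cols``/``light_cols`` are lists of composition vectors (each
    summing to 1), one per replicate sample.
    """
    columns = {}
    rows = []
    for cls, cols, window in (
        ("heavy", heavy_cols, sp.HEAVY_WINDOW),
        ("light", light_cols, sp.LIGHT_WINDOW),
    ):
        for r, vec in enumerate(cols, start=1):
            sid = f"{treatment}_{cls}_r{r}"
            columns[sid] = np.asarray(vec, dtype=float)
            rows.append(
                {
                    "sample_id": sid,
                    "replicate": r,
                    "fraction_class": cls,
                    "density_g_ml": 0.5 * (window[0] + window[1]),
                }
            )
    n = len(next(iter(columns.values())))
    ids = asv_ids or [f"ASV_{i + 1}" for i in range(n)]
    return sp.FractionTable(
        treatment=treatment,
        samples=pd.DataFrame(rows).set_index("sample_id"),
        abundance=pd.DataFrame(columns, index=ids),
    )
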