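import numpy as np
import pandas as pd
import pytest

from gravimet.qc import MetaboliteMatrix
from gravimet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_per_stratum=150,
        n_genotyped_per_stratum=250,
        n_snps=40,
        n_metabolites=24,
        n_nontargeted=10,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-built metabolite matrix: 6 subjects x 3 metabolites."""
    idx = pd.Index([f"S{i}" for i in range(6)], name="subject_id")
    meta = pd.DataFrame(
        {
            "class": ["acylcarnitine", "amino acid", "carbohydrate"],
            "arm": ["targeted", "targeted", "nontargeted"],
        },
        index=pd.Index(["ac_1", "alanine", "nt_sugar"], name="metabolite"),
    )
    values = pd.DataFrame(
        {
            "ac_1": [np.e, np.e**2, 1.0, np.e, np.e, np.e],
            "alanine": [350.0, 340.0, 360.0, 355.0, 345.0, 350.0],
            "nt_sugar": [1024.0, 2048.0, np.nan, 512.0, 1024.0, 1024.0],
        },
        index=idx,
    )
    batch = pd.Series(["b0", "b0", "b0", "b1", "b1", "b1"], index=idx, name="batch")
    return MetaboliteMatrix(values=values, meta=meta, timepoint="fasting", transform="raw", batch=batch)
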