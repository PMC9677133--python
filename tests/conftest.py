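import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from brainwas.datatypes import IDPMatrix
from brainwas.simulate import SimConfig, simulate_genotypes

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genotypes():
    """10k subjects x 8 variants, moderate LD — shared read-only fixture."""
    cfg = SimConfig(n_subjects=10_000, n_variants=8, n_idps=1, ld_rho=0.5, seed=7)
    return simulate_genotypes(cfg)


@pytest.fixture()
def idp_matrix():
    """120 x 6 Gaussian IDP matrix with a missing cell and group labels."""
    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.standard_normal((120, 6)),
        index=pd.Index([f"S{i:04d}" for i in range(120)], name="subject_id"),
        columns=pd.Index([f"idp{j}" for j in range(6)], name="idp_id"),
    )
    values.iloc[5, 2] = np.nan
    groups = pd.Series(
        ["GM-morphology", "GM-morphology", "WM-microstructure",
         "WM-microstructure", "functional", "functional"],
        index=values.columns,
    )
    return IDPMatrix(values, groups)
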