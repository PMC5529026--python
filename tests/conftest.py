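import numpy as np
import pandas as pd
import pytest

from glomkit import synthetic as syn


@pytest.fixture(scope="session")
def single_age_design() -> syn.StudyDesign:
    """Minimal one-age lean/obese design for count simulations."""
    return syn.StudyDesign(
        ages_weeks=(41,), endpoint_params={}, fibrosis_params=None, seed=0
    )


@pytest.fixture(scope="session")
def default_design() -> syn.StudyDesign:
    return syn.default_study_design(seed=123)


@pytest.fixture(scope="session")
def small_count_matrix(default_design):
    """2000-gene default simulation shared across transcriptome tests."""
    params = syn.default_count_params(seed=42, n_genes=2000)
    return syn.simulate_counts(params, default_design)


def make_profiles_frame(rng: np.random.Generator, n: int = 44) -> pd.DataFrame:
    """Random valid profile table for brute-force comparisons."""
    tuft = rng.uniform(2000, 12000, n)
    counts = rng.integers(0, 30, n)
    stain = np.where(counts > 0, rng.uniform(0, 0.1, n) * tuft, 0.0)
    return pd.DataFrame(
        {"tuft_area": tuft, "n_wt1": counts, "wt1_stain_area": stain}
    )
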