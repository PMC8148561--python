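import numpy as np
import pandas as pd
import pytest

from droughtscreen import synthetic_trial as st


@pytest.fixture
def small_design():
    """4 genotypes x 2 seasons x 2 regimes x 3 reps, three traits including
    a designated yield trait and a stress-increasing trait."""
    traits = (
        st.TraitSpec("GY", grand_mean=5.0, sigma2_g=0.4, sigma2_gxe=0.1,
                     sigma2_e=0.1, stress_shift=1.0, yield_correlation=1.0),
        st.TraitSpec("GLA", grand_mean=90.0, sigma2_g=140.0, sigma2_gxe=30.0,
                     sigma2_e=15.0, stress_shift=25.0, yield_correlation=0.5),
        st.TraitSpec("CT", grand_mean=17.5, sigma2_g=2.5, sigma2_gxe=0.6,
                     sigma2_e=0.1, stress_direction="increases",
                     stress_shift=2.5, yield_correlation=-0.6),
    )
    return st.TrialDesign(n_genotypes=4, traits=traits)


@pytest.fixture
def small_trial(small_design):
    table, manifest = st.generate_trial(small_design, seed=7)
    return table, manifest


def make_noise_free_design(**overrides):
    """Single-trait design with all variance components zero."""
    spec = dict(
        name="T", grand_mean=10.0, sigma2_g=0.0, sigma2_gxe=0.0, sigma2_e=0.0,
        stress_shift=2.0,
    )
    spec.update(overrides)
    return st.TrialDesign(n_genotypes=3, traits=(st.TraitSpec(**spec),))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def grouped_gaussians(rng):
    """Well-separated 3-group Gaussian data: (scores, groups)."""
    centers = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(rng.normal(size=(10, 2)) * 0.5 + c)
        labels += [f"g{i}"] * 10
    scores = pd.DataFrame(
        np.vstack(rows), columns=["t1", "t2"],
        index=[f"item{i}" for i in range(30)],
    )
    return scores, pd.Series(labels, index=scores.index)
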