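import numpy as np
import pandas as pd
import pytest

from apa_rhythm.pas_calling import SampleInfo
from apa_rhythm.synthetic_data import SimConfig, circadian_design, full_design


@pytest.fixture
def small_config():
    return SimConfig(
        seed=7,
        n_genes=40,
        frac_cycling_24=0.25,
        frac_cycling_12=0.1,
        frac_sd_affected=0.2,
        tag_jitter_sd_nt=0.0,
    )


@pytest.fixture
def circ_samples():
    return circadian_design(seed=7)


@pytest.fixture
def all_samples():
    return full_design(seed=7)


@pytest.fixture
def de_samples():
    """Two 5-replicate groups for a single contrast."""
    return [
        SampleInfo(f"R0_r{i}", "R0", i, 2_000_000) for i in range(1, 6)
    ] + [SampleInfo(f"ZT6_r{i}", "ZT6", i, 2_000_000) for i in range(1, 6)]


def nb_matrix(rng, mu, alpha, n_rows, columns):
    """NB count DataFrame with constant mean; helper for null simulations."""
    npar = 1.0 / alpha
    Y = rng.negative_binomial(npar, npar / (npar + mu), size=(n_rows, len(columns)))
    return pd.DataFrame(
        Y.astype(float), columns=columns, index=[f"P{i}" for i in range(n_rows)]
    )


@pytest.fixture
def nb_null_matrix(circ_samples):
    rng = np.random.default_rng(123)
    return nb_matrix(rng, 100.0, 0.05, 400, [s.sample_id for s in circ_samples])
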