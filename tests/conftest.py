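import numpy as np
import pandas as pd
import pytest

from lungsig.containers import ExpressionMatrix
from lungsig.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across tests (120 samples, 80 genes)."""
    cfg = SimConfig(
        n_samples=120, n_genes=80, n_prognostic_genes=8, n_response_genes=8, seed=42
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def trained_prognostic():
    """A stage-1 model trained on a full-size cohort (shared, expensive)."""
    from lungsig.pipeline import train_prognostic
    from lungsig.select import SelectionConfig

    expr, clinical, truth = simulate_cohort(SimConfig(n_samples=332, seed=20120702))
    model, selection, report = train_prognostic(
        expr, clinical, SelectionConfig(seed=7)
    )
    return model, selection, report, truth


@pytest.fixture()
def tiny_expr():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
        index=["gA", "gB"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values)


def make_survival_frame(rng, n, lp=None, scale=40.0, censor=60.0):
    """Exponential survival frame for direct statistical tests."""
    lp = np.zeros(n) if lp is None else np.asarray(lp)
    t = rng.exponential(scale=scale * np.exp(-lp))
    c = np.minimum(rng.exponential(scale=80.0, size=n), censor)
    return pd.DataFrame(
        {
            "followup_months": np.minimum(t, c),
            "dss_event": (t <= c).astype(int),
        }
    )
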