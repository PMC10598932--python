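import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chemogram import (
    DoseResponseProfile,
    ScoreMatrix,
    load_default_panel,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


def make_profiles(viability_by_pdo: dict[str, tuple], drug: str = "drugA"):
    """Shorthand: one profile per PDO for a single drug."""
    return [
        DoseResponseProfile(pdo_id=pdo, drug=drug, viability=tuple(v))
        for pdo, v in viability_by_pdo.items()
    ]


def make_score_matrix(final: dict[str, dict[str, float]], threshold: float = 1.9):
    """Build a ScoreMatrix from {pdo: {drug: final_score}} (NaN = missing).

    The sensitivity component is set to 0 and the AUC component to the final
    score, keeping the final = auc + sensitivity identity trivially true.
    """
    final_df = pd.DataFrame(final).T.astype(float)
    auc = final_df.copy()
    sens = final_df * 0.0
    hit = (final_df > threshold).astype("boolean").mask(final_df.isna())
    return ScoreMatrix(
        auc_score=auc,
        sensitivity_score=sens,
        final_score=final_df,
        hit=hit,
        threshold=threshold,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230825)
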