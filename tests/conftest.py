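import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigreverse.io import ExpressionMatrix, GeneSet, RankDatabase

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples (2 case, 2 control) with a strong planted effect
    in g_up/g_dn and a constant gene."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 1.0, 5.0, 2.0],
            "s2": [11.0, 2.0, 5.0, 2.5],
            "s3": [1.0, 10.0, 5.0, 2.2],
            "s4": [2.0, 11.0, 5.0, 1.9],
        },
        index=["g_up", "g_dn", "g_flat", "g_null"],
    )
    groups = pd.Series({"s1": "case", "s2": "case", "s3": "control", "s4": "control"})
    return ExpressionMatrix(values=values, groups=groups)


def make_rank_db(perms: dict[str, list[int]], genes: list[str] | None = None,
                 compounds: dict[str, str] | None = None) -> RankDatabase:
    """Small rank database from explicit per-instance permutations."""
    n = len(next(iter(perms.values())))
    genes = genes or [f"g{i}" for i in range(1, n + 1)]
    ranks = pd.DataFrame(perms, index=genes, dtype=np.int64)
    compounds = compounds or {inst: f"cpd_{inst}" for inst in perms}
    meta = pd.DataFrame(
        {
            "instance_id": list(perms),
            "compound": [compounds[i] for i in perms],
            "dose": "10uM",
            "cell_line": "SYN1",
        }
    ).set_index("instance_id")
    return RankDatabase(ranks=ranks, metadata=meta)


@pytest.fixture
def rank_db_factory():
    return make_rank_db
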