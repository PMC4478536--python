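import numpy as np
import pandas as pd
import pytest

from dosagecomp import normalization, simulate


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (full published design) shared by the suite."""
    return simulate.simulate_study(seed=11)


@pytest.fixture(scope="session")
def normalized_study(study):
    sf = normalization.compute_size_factors(
        study.counts, feature_classes=study.annotation["feature_class"]
    )
    expr = normalization.normalize(study.counts, sf)
    return study, sf, expr


def two_group_design(n_rep: int = 3) -> pd.DataFrame:
    """Minimal two-genotype XX design used for null DE simulations."""
    return pd.DataFrame(
        [
            {
                "sample_id": f"{g}.r{r}",
                "genotype": g,
                "df_id": None,
                "karyotype": "XX",
                "tra2": False,
                "replicate": r,
            }
            for g in ("ctlA", "ctlB")
            for r in range(1, n_rep + 1)
        ]
    )


def empty_df_intervals() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["df_id", "chrom", "start", "end", "extent_bp"]
    ).set_index(pd.Index([]))
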