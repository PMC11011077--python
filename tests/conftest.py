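import numpy as np
import pandas as pd
import pytest

from gbmsize import generate_cohort, null_config, paper_like_config


@pytest.fixture(scope="session")
def paper_cohort() -> pd.DataFrame:
    """One paper_like cohort at the canonical seed."""
    return generate_cohort(paper_like_config(seed=0))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    """A cohort with no covariate effect on the hazard."""
    return generate_cohort(null_config(seed=0))


@pytest.fixture()
def tiny_cohort_factory():
    """Small hand-rolled cohort tables with full control of time/event/size."""

    def make(times, events, sizes, **extra) -> pd.DataFrame:
        n = len(times)
        base = {
            "age": np.full(n, 60.0),
            "sex": ["male"] * n,
            "surgery": ["biopsy"] * n,
            "oncology": ["no_stupp"] * n,
            "mgmt": ["unmethylated"] * n,
            "diameter_cm": np.asarray(sizes, dtype=float),
            "cv_cm3": np.asarray(sizes, dtype=float),
            "wv_cm3": np.asarray(sizes, dtype=float),
            "time_months": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=np.int64),
        }
        base.update(extra)
        return pd.DataFrame(base)

    return make
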