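import numpy as np
import pandas as pd
import pytest

from ballatac import synthetic_data as sd
from ballatac.io_formats import CountMatrix


@pytest.fixture(scope="session")
def annotations():
    """Deterministic toy annotated genome shared across region/network tests."""
    return sd.simulate_annotations(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-subtype cohort small enough for exhaustive checks."""
    return sd.simulate_cohort(
        n_subtypes=4, n_per_subtype=6, n_regions=2000, enriched_fraction=0.02, seed=11
    )


def make_counts(values, region_ids=None, sample_ids=None, groups=None, group_col="subtype"):
    """Assemble a CountMatrix from a plain nested list."""
    values = np.asarray(values)
    region_ids = region_ids or [f"chr1:{1000 * i}-{1000 * i + 500}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    meta = {group_col: groups} if groups is not None else {}
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(pd.DataFrame(values, index=region_ids, columns=sample_ids), samples)
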