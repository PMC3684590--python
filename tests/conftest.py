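import numpy as np
import pandas as pd
import pytest

import dysconnect as d


@pytest.fixture(scope="session")
def small_cohort():
    """12+12 cohort with 5 planted edges on a 30-ROI parcellation."""
    cohort = d.generate_cohort(12, 12, seed=3)
    effects = d.PlantedEffectMap.default(30, n_planted=5, seed=3)
    features = d.generate_edge_data(cohort, 30, effects, seed=3)
    return cohort, effects, features


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Fitted discrimination model on the small planted cohort."""
    cohort, effects, features = small_cohort
    model = d.ConnectivityDiscrimination.from_dataframes(cohort, features)
    return model.fit(p_level=0.05, n_permutations=200, tau=(1.0, 0.9), seed=3)


@pytest.fixture(scope="session")
def atlas30():
    return d.generate_atlas(30, seed=3)
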