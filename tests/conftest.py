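import numpy as np
import pandas as pd
import pytest

import tmbsim as tm
from tmbsim.cohort_io import Cohort


@pytest.fixture(scope="session")
def luad_dist() -> tm.HistologyDistribution:
    """Kernel density fit of a heavy-tailed lung-adeno-like cohort."""
    cohort = tm.generate_synthetic_cohort("luad_like", 4000, 1)
    return tm.fit_histology_distribution(cohort, "LUAD")


@pytest.fixture(scope="session")
def brca_dist() -> tm.HistologyDistribution:
    """Kernel density fit of a low-burden breast-like cohort."""
    cohort = tm.generate_synthetic_cohort("low_tmb_like", 4000, 2)
    return tm.fit_histology_distribution(cohort, "BRCA")


@pytest.fixture(scope="session")
def lusc_dist() -> tm.HistologyDistribution:
    cohort = tm.generate_synthetic_cohort("lusc_like", 4000, 3)
    return tm.fit_histology_distribution(cohort, "LUSC")


@pytest.fixture(scope="session")
def uniform_dist() -> tm.HistologyDistribution:
    return tm.HistologyDistribution.uniform(0.0, 20.0)


@pytest.fixture
def small_cohort_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "histology": ["LUAD", "LUAD", "BRCA"],
            "tmb_wes": [4.0, 12.5, 1.2],
            "tmb_panel": [np.nan, 11.0, np.nan],
            "response": [1, 0, np.nan],
        }
    )


def make_paired_cohort(n: int, panel: tm.PanelModel, preset: str = "luad_like",
                       cohort_seed: int = 3, noise_seed: int = 4) -> Cohort:
    cohort = tm.generate_synthetic_cohort(preset, n, cohort_seed)
    return tm.attach_panel_readouts(cohort, panel, seed=noise_seed)
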