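import numpy as np
import pandas as pd
import pytest

from panelforge.matrix import CohortMatrix
from panelforge.simulate import SimStudyConfig, simulate_cohort


@pytest.fixture
def toy_matrix():
    """3 proteins x 4 subjects, raw scale, no missing values."""
    data = pd.DataFrame(
        [[8.0, 16.0, 4.0, 8.0],
         [2.0, 2.0, 2.0, 4.0],
         [1.0, 2.0, 4.0, 8.0]],
        index=["GFAP", "NPTX2", "SMOC1"],
        columns=["s1", "s2", "s3", "s4"])
    return CohortMatrix("toy", "mass_spec", data)


@pytest.fixture
def labeled_cohort():
    """One simulated cohort with 5 planted markers, z-scored, plus labels."""
    from panelforge.preprocess import zscore_standardize

    cfg = SimStudyConfig(cohort_id="fix", n_case=40, n_control=40, n_proteins=60,
                         seed=42, planted_markers=[(f"MK{i}", 1.2) for i in range(5)],
                         noise_sd=0.5, missing_beta=(0.0, 0.0))
    m, subjects, truth = simulate_cohort(cfg)
    m = zscore_standardize(m)
    labels = {s.subject_id: ("case" if s.is_at_positive else "control")
              for s in subjects}
    return m, labels, truth


def rng(seed=0):
    return np.random.default_rng(seed)
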