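import pytest
from hypothesis import settings

from methaging import synthio
from methaging.core import CONTROL

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """600-site cohort with a CR arm, small n per group — fast shared fixture."""
    design = synthio.CohortDesign(
        n_sites=600, n_per_group=3, seed=5,
        cr=synthio.CRDesign(n_per_group=3),
    )
    matrix, sheet, truth = synthio.generate_cohort(design)
    return design, matrix, sheet, truth


@pytest.fixture(scope="session")
def control_view(small_cohort):
    _, matrix, sheet, _ = small_cohort
    ctrl = sheet[sheet["group"] == CONTROL]
    cmat = matrix.subset_samples(ctrl["sample_id"].tolist())
    return cmat, ctrl["age"].to_numpy()
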