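import pytest

from pufval.puf_engine import build_pufs
from pufval.qc import find_exclusions
from pufval.synthetic_data import GeneratorConfig, generate, make_study_fixture


@pytest.fixture(scope="session")
def study_cohort():
    """The 61-respondent study-emulation cohort (synthetic)."""
    return make_study_fixture(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-calibration cohort for pipeline tests."""
    return generate(GeneratorConfig(n=60, seed=123))


@pytest.fixture(scope="session")
def small_pufs(small_cohort):
    excluded = {rid for rid, _ in find_exclusions(small_cohort)}
    return build_pufs([r for r in small_cohort if r.id not in excluded])
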