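import pytest
from hypothesis import settings

from charmrisk import RunConfig, classify_study, generate_paper_like_study

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def paper_bundle():
    """The reconstructed 36-substance all-CMR study."""
    return generate_paper_like_study(seed=1)


@pytest.fixture(scope="session")
def paper_report(paper_bundle):
    return classify_study(
        paper_bundle.substances,
        paper_bundle.profiles,
        paper_bundle.measurements,
        paper_bundle.summaries,
        RunConfig(seed=1),
    )
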