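import pytest

from tglisten.corpus_model import (
    Platform,
    PlatformType,
    RawPost,
    RawResponse,
    bundled_lexicon,
)
from tglisten.synthgen import ContaminationConfig, GeneratorConfig, generate

NO_CONTAMINATION = ContaminationConfig(
    duplicate_rate=0.0, ad_rate=0.0, science_rate=0.0, low_tg_rate=0.0
)


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon("en")


@pytest.fixture
def post_factory():
    def make(
        post_id="p1",
        text="",
        platform_type="qa_search",
        platform_name="test platform",
        year=2015,
        responses=(),
    ):
        return RawPost(
            post_id=post_id,
            platform=Platform(name=platform_name, platform_type=PlatformType(platform_type)),
            year=year,
            query_text=text,
            responses=[
                RawResponse(response_id=f"{post_id}r{i}", text=t)
                for i, t in enumerate(responses)
            ],
        )

    return make


@pytest.fixture(scope="session")
def clean_corpus():
    """200 clean synthetic posts (no contamination), with ground truth."""
    config = GeneratorConfig(n_posts=200, seed=11, contamination=NO_CONTAMINATION)
    posts, truth = generate(config)
    return posts, truth, config


@pytest.fixture(scope="session")
def mixed_corpus():
    """400 clean posts plus default 5% contamination of each kind."""
    config = GeneratorConfig(n_posts=400, seed=3)
    posts, truth = generate(config)
    return posts, truth, config
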