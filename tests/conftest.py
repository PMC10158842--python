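from datetime import datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from barrier_miner.corpus import Post
from barrier_miner.fixtures import load_fixture

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def seed_lexicon():
    return load_fixture("seed_lexicon")


@pytest.fixture(scope="session")
def templates():
    return load_fixture("templates")


@pytest.fixture(scope="session")
def example_posts():
    return load_fixture("example_posts")


def make_post(post_id="p1", text="hello world", subreddit="suboxone",
              kind="submission", parent_id=None,
              created=datetime(2020, 1, 1, tzinfo=timezone.utc)):
    return Post(post_id=post_id, subreddit=subreddit, created=created,
                kind=kind, parent_id=parent_id, text=text)


@pytest.fixture
def post_factory():
    return make_post
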