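import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from opirisk.corpus_io import Post
from opirisk.preprocessing import TokenizedDocument, tokenize_post
from opirisk.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A compact four-group corpus with moderate separability."""
    cfg = GeneratorConfig(
        seed=11,
        n_posts_per_group={"suicidewatch": 120, "depression": 120,
                           "control": 120, "opiates": 120},
        separability=0.9,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def sw_control_docs(small_corpus):
    """Tokenized suicidewatch-vs-control documents with binary labels."""
    posts, _ = small_corpus
    subset = [p for p in posts if p.group in ("suicidewatch", "control")]
    docs = [tokenize_post(p) for p in subset]
    labels = [int(p.group == "suicidewatch") for p in subset]
    return docs, labels


@pytest.fixture
def toy_docs():
    return [
        TokenizedDocument("d0", "the cat sat on the mat".split(), "control"),
        TokenizedDocument("d1", "the dog sat".split(), "control"),
        TokenizedDocument("d2", "a cat and a dog".split(), "control"),
    ]


def make_post(pid="p0", community="opiates", title="t", body="b", **kw):
    return Post(id=pid, community=community, title=title, body=body, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
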