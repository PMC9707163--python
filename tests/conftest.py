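import numpy as np
import pytest

from stylemap.corpus_io import Comment
from stylemap.lexicon import parse_dictionary

TOY_DIC = """%
1\tarticle
2\tipron
3\thappy
%
the\t1
a\t1
it\t2
it*\t2
happ*\t3
happily\t3
"""


@pytest.fixture(scope="session")
def toy_lexicon():
    return parse_dictionary(TOY_DIC, source="toy")


def make_comment(body, *, id="c1", author="alice", created_utc=1_600_000_000, group="g"):
    return Comment(id=id, author=author, body=body, created_utc=created_utc, group=group)


@pytest.fixture
def long_body():
    # 60 distinct tokens, no dictionary matches
    return " ".join(f"tok{i}" for i in range(60))


@pytest.fixture(scope="session")
def planar_points():
    rng = np.random.default_rng(42)
    return rng.normal(size=(6, 2))
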