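import numpy as np
import pytest
from hypothesis import settings

import agreedent as ag

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_matrix(rows, categories, method_id="T"):
    """RatingMatrix from a list of per-unit rating lists (None = NA)."""
    scheme = ag.StagingScheme(method_id, tuple(categories), False, frozenset({38}))
    cells = np.array([list(r) for r in rows], dtype=object)
    return ag.RatingMatrix(
        list(range(len(rows))), list(range(len(rows[0]))), cells, scheme
    )


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the default (published-design) configuration."""
    return ag.generate_study(ag.StudyConfig(seed=202))


@pytest.fixture()
def four_unit_matrix():
    """The worked 2-rater example: (A,A), (A,A), (B,B), (A,B)."""
    return make_matrix([["A", "A"], ["A", "A"], ["B", "B"], ["A", "B"]], "AB")


@pytest.fixture()
def paradox_pairs():
    """20 rating pairs with a dominant stage: 18 x (H,H), (H,G), (G,H)."""
    return [("H", "H")] * 18 + [("H", "G"), ("G", "H")]
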