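import numpy as np
import pytest

from pfspeller import GridLayout, build_language_model


@pytest.fixture
def grid() -> GridLayout:
    return GridLayout()


@pytest.fixture
def tiny_model():
    """'THE THE CAT' model with no smoothing: exact count ratios."""
    return build_language_model("THE THE CAT", smoothing_floor=0.0)


@pytest.fixture
def small_grid() -> GridLayout:
    """2x2 grid over {A, B, C, space}: rows AB / C_, columns AC / B_."""
    return GridLayout(characters="ABC ", n_rows=2, n_cols=2)


def random_corpus(rng: np.random.Generator, n_words: int, alphabet="ABC") -> str:
    words = [
        "".join(rng.choice(list(alphabet), size=rng.integers(1, 5)))
        for _ in range(n_words)
    ]
    return " ".join(words)
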