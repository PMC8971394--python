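import numpy as np
import pandas as pd
import pytest

from affectmap.core import TERMS, ClassificationDataset
from affectmap.synthetic import default_lexicon, generate_classification


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_dataset(lexicon):
    """60-participant synthetic classification dataset (1200 rows)."""
    return generate_classification(lexicon, 60, seed=11)


@pytest.fixture(scope="session")
def medium_dataset(lexicon):
    """200-participant synthetic classification dataset."""
    return generate_classification(lexicon, 200, seed=12)


def make_dataset(rows):
    """Build a ClassificationDataset from (pid, term, v, a) tuples."""
    df = pd.DataFrame(rows, columns=["participant_id", "term", "valence", "arousal"])
    return ClassificationDataset(df, require_balanced=False)


@pytest.fixture
def two_participant_dataset():
    rng = np.random.default_rng(3)
    rows = []
    for pid in ("a", "b"):
        for t in TERMS:
            v, a = rng.uniform(50, 450, 2)
            rows.append((pid, t, v, a))
    return make_dataset(rows)
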