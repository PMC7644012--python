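import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper module

from doubleyolk import (DoubleYolkClassifier, generate_population, load_classifier)


@pytest.fixture(scope="session")
def worked_clf() -> DoubleYolkClassifier:
    """Classifier under which the documented worked example evaluates exactly."""
    return load_classifier("worked_example")


@pytest.fixture(scope="session")
def case3_clf() -> DoubleYolkClassifier:
    return load_classifier("case3")


@pytest.fixture(scope="session")
def default_population():
    """The default seeded 180 SY / 99 DY synthetic population."""
    return generate_population()
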