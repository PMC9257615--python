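import pytest

from crowddx import (
    DiseaseCategoryClassifier,
    build_term_index,
    bundled_lexicon,
    default_rules,
)


@pytest.fixture(scope="session")
def lexicon():
    return bundled_lexicon()


@pytest.fixture(scope="session")
def index(lexicon):
    return build_term_index(lexicon)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def clf(lexicon, rules):
    return DiseaseCategoryClassifier(lexicon=lexicon, rules=rules).fit()
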