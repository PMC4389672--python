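"""Shared fixtures: the worked single-DS training group and models built on it."""

import pytest

from domsign import synthetic as syn
from domsign import training as tr


@pytest.fixture(scope="session")
def worked_corpus():
    """100 proteins sharing one DS: 1.1.1.1 x43, 1.1.1.2 x42, 1.1.2.1 x3,
    1.2.1.1 x2, 2.1.1.1 x10 — dominant fractions 90/88/85/43 per level."""
    enzymes, nonenzymes = syn.generate(syn.WORKED_EXAMPLE_SPEC)
    return enzymes, nonenzymes


@pytest.fixture(scope="session")
def worked_model(worked_corpus):
    enzymes, nonenzymes = worked_corpus
    return tr.train(enzymes, nonenzymes)


@pytest.fixture(scope="session")
def worked_signature(worked_corpus):
    enzymes, _ = worked_corpus
    return enzymes[0].signature
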