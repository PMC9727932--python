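import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from abagkit import (  # noqa: E402
    Annotation,
    Document,
    SynthConfig,
    filter_lexicon,
    generate_corpus,
    generate_lexicon,
)


def random_annotations(rng: random.Random, doc_id: str, text_len: int,
                       max_n: int = 8) -> set:
    """Random possibly-overlapping typed spans over a dummy text."""
    out = set()
    for _ in range(rng.randrange(max_n + 1)):
        start = rng.randrange(text_len - 1)
        end = rng.randrange(start + 1, min(text_len, start + 12) + 1)
        etype = rng.choice(("Antibody", "Antigen"))
        out.add(Annotation(doc_id, start, end, etype, "x" * (end - start)))
    return out


@pytest.fixture(scope="session")
def small_lexicon():
    lex, traps = generate_lexicon(25, 40, seed=11, n_compounds=4)
    return filter_lexicon(lex), traps


@pytest.fixture(scope="session")
def small_corpus(small_lexicon):
    lex, _ = small_lexicon
    docs, ledger = generate_corpus(lex, SynthConfig(n_docs=40, seed=17))
    return docs, ledger


@pytest.fixture()
def abcc6_doc():
    """The 'mEChC6 targets human ABCC6' example document."""
    text = "mEChC6 targets human ABCC6"
    return Document(
        doc_id="d0",
        text=text,
        annotations={"gold": {
            Annotation("d0", 0, 6, "Antibody", "mEChC6"),
            Annotation("d0", 15, 26, "Antigen", "human ABCC6"),
        }},
    )
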