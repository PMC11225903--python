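import random

import pytest

from emat import (EMATAction, EquivalenceSet, Taxonomy, Lexicon,
                  generate_toy_taxonomy)


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """Deterministic 15-action taxonomy over a controlled vocabulary."""
    return generate_toy_taxonomy(3, vocab_seed=7)


@pytest.fixture()
def poacher_taxonomy() -> Taxonomy:
    """Hand-built two-action taxonomy around the arrest/sentence scenario."""
    arrest = EMATAction(
        action_id="1", label="Arrest poachers", category="militaristic",
        archetypal_actors=("rangers",),
        verb_set=EquivalenceSet("verb", (("arrest",), ("arrested",))),
        object_set=EquivalenceSet("direct_object",
                                  (("poachers",), ("five", "poachers"))),
        prep_set=EquivalenceSet("prepositional", (("in", "the", "park"),)))
    sentence = EMATAction(
        action_id="2", label="Sentence offenders", category="militaristic",
        verb_set=EquivalenceSet("verb", (("sentenced",),)),
        object_set=EquivalenceSet("direct_object", (("offenders",),)),
        prep_set=EquivalenceSet("prepositional", (("to", "prison"),)))
    return Taxonomy({"1": arrest, "2": sentence})


@pytest.fixture()
def groups_lexicon() -> Lexicon:
    return Lexicon(("Kenya Wildlife Services", "SANParks Scientific Services"))


@pytest.fixture()
def regions_lexicon() -> Lexicon:
    return Lexicon(("Tsavo", "Laikipia", "Kruger"))


PRINTED_SENTENCE = ("Five poachers were arrested on June 10, 2019 and "
                    "sentenced to prison on August 8, 2019.")


@pytest.fixture()
def printed_sentence() -> str:
    return PRINTED_SENTENCE


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(12345)
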