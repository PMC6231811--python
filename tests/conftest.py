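import pytest

from dvmh.corpus_io import Narrative
from dvmh.gazetteers import default_gazetteers
from dvmh.icd_mapper import default_schema
from dvmh.pipeline import extract_mentions
from dvmh.rule_engine import load_default_rules


@pytest.fixture(scope="session")
def gaz():
    return default_gazetteers()


@pytest.fixture(scope="session")
def rules(gaz):
    return load_default_rules(gaz)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def extract(gaz, rules):
    """Run the extractor on a single piece of text."""

    def _extract(text, event_id="E1", narrative_id="E1-1"):
        return extract_mentions(Narrative(event_id, narrative_id, text), gaz, rules)

    return _extract
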