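import pytest

from ndtrials.config import load_rules
from ndtrials.curation import annotations_to_frame, typed_annotation_frame
from ndtrials.pipeline import annotate_records
from ndtrials.synthetic import (GeneratorConfig, default_lookup_tables,
                                generate_registry)


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def lookups():
    return default_lookup_tables()


@pytest.fixture(scope="session")
def small_result():
    """A small synthetic registry (about 600 records) with ground truth."""
    return generate_registry(GeneratorConfig(seed=7, trials_per_year=30))


@pytest.fixture(scope="session")
def small_annotations(small_result, rules):
    trials = annotate_records(small_result.records, small_result.lookups,
                              rules, small_result.cues)
    frame = typed_annotation_frame(annotations_to_frame(trials))
    return trials, frame
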