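import numpy as np
import pytest

import crcsmine as cm


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down generator spec (fast) with the standard plants."""
    return cm.GeneratorSpec(
        n1=120, n2=80, n_questions=40, options_per_question=5,
        n_missing_outcome=2, plants=cm.standard_plants(), seed=7,
    )


@pytest.fixture(scope="session")
def small_run(small_spec):
    """Generated table, codebook and encoded transactions for the small spec."""
    table, truth = cm.generate(small_spec)
    codebook = cm.default_codebook(small_spec)
    dataset = cm.encode_responses(
        table, codebook, outcome="adherence", id_column="participant_id"
    )
    return table, truth, codebook, dataset
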