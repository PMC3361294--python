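import pytest

from miwsd import GeneratorSpec, PreprocessConfig, generate_corpus
from miwsd.toy import toy_corpus


@pytest.fixture
def toy():
    """10-instance two-sense worked-example corpus (context words wp, wq)."""
    return toy_corpus()


@pytest.fixture
def config():
    return PreprocessConfig()


@pytest.fixture
def separable_corpus():
    """Perfectly separable synthetic corpus: p_in=1, p_out=0."""
    return generate_corpus(
        GeneratorSpec(p_in=1.0, p_out=0.0, instances_per_sense=20, seed=42)
    )


@pytest.fixture
def noisy_corpus():
    """Default study-condition corpus: planted signal plus background noise."""
    return generate_corpus(GeneratorSpec(seed=7))
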