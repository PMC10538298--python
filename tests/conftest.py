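import numpy as np
import pytest

from mitocub import (
    CodonCounts,
    SynthSpec,
    generate_cds_set,
    get_genetic_code,
)


@pytest.fixture(scope="session")
def code5():
    """Invertebrate mitochondrial code (NCBI table 5)."""
    return get_genetic_code(5)


@pytest.fixture(scope="session")
def code1():
    """Standard genetic code."""
    return get_genetic_code(1)


@pytest.fixture(scope="session")
def fixture_records():
    """Default synthetic study set: 5 species x 13 mito PCGs, AT-rich,
    moderate AT-ending selection."""
    return generate_cds_set(SynthSpec(seed=20230925))


def random_counts(rng: np.random.Generator, code, scale: int = 200) -> CodonCounts:
    """Random codon count vector over the sense codons of a code."""
    counts = {c: int(rng.integers(0, scale)) for c in code.sense_codons}
    if sum(counts.values()) == 0:
        counts[code.sense_codons[0]] = 1
    return CodonCounts(counts)


def random_cds(rng: np.random.Generator, code, n_codons: int = 120) -> str:
    """Random stop-free in-frame nucleotide string."""
    sense = list(code.sense_codons)
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)
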