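import numpy as np
import pytest

from cubkit.genetic_code import SCORED_CODONS, SYN_FAMILIES
from cubkit.codon_metrics import CodonCounts
from cubkit.seq_io import CodingSequence, validate_cds


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def one_of_each_cds():
    """A CDS containing each of the 59 informative codons exactly once."""
    return validate_cds(
        CodingSequence(id="one_of_each", seq="".join(SCORED_CODONS))
    )


def random_counts(rng, max_count=50) -> CodonCounts:
    """Random codon counts over the scored set (every family observed)."""
    counts = {}
    for codons in SYN_FAMILIES.values():
        vals = rng.integers(0, max_count, size=len(codons))
        if vals.sum() == 0:
            vals[rng.integers(len(codons))] = 1
        counts.update({c: int(v) for c, v in zip(codons, vals) if v > 0})
    return CodonCounts(counts=counts, scope="random")


def random_cds(rng, n_codons=60, seq_id="rand") -> CodingSequence:
    """A random in-frame, stop-free CDS."""
    from cubkit.genetic_code import SENSE_CODONS

    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return validate_cds(
        CodingSequence(id=seq_id, seq="".join(SENSE_CODONS[i] for i in idx))
    )
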