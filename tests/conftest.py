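import numpy as np
import pytest

from xstrkit.genotypes import AlleleLabel, GenotypeTable, Sample


def make_table(records, loci):
    """records: list of (sample_id, sex, {locus: "10" or "10/25.1" or None})."""
    samples = []
    calls = {}
    for sid, sex, locus_calls in records:
        samples.append(Sample(sid, sex))
        for locus, text in locus_calls.items():
            if text is None:
                continue
            calls[(sid, locus)] = tuple(
                AlleleLabel.parse(t) for t in text.split("/")
            )
    return GenotypeTable(samples=samples, loci=list(loci), calls=calls)


@pytest.fixture
def toy_table():
    """One hemizygous male and one diploid female at a single locus."""
    return make_table(
        [("m1", "male", {"LOC": "10"}), ("f1", "female", {"LOC": "10/25.1"})],
        ["LOC"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
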