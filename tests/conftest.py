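import numpy as np
import pytest
from hypothesis import settings

import tandemscout as ts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_pipeline():
    """One modest synthetic run shared by integration-level tests:
    150 kb genome, two satellite families (~8% and ~4%), 7.5X reads."""
    spec = ts.GenomeSpec(
        length=150_000,
        gc=0.47,
        families=[
            ts.RepeatFamilySpec(
                name="satA", monomer_length=180, n_arrays=2, copies_per_array=33,
            ),
            ts.RepeatFamilySpec(
                name="satB", monomer_length=350, n_arrays=1, copies_per_array=17,
            ),
        ],
        seed=11,
    )
    return ts.run_synthetic(spec, n_reads=7500)


def cyclic_edit_distance(a: str, b: str) -> int:
    """Edit distance between cyclic units, strand-insensitive: best infix
    alignment of the shorter against the doubled longer, either strand."""
    import edlib

    if len(a) > len(b):
        a, b = b, a
    d1 = edlib.align(a, b + b, mode="HW")["editDistance"]
    d2 = edlib.align(ts.reverse_complement(a), b + b, mode="HW")["editDistance"]
    return min(d1, d2) + (len(b) - len(a))
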