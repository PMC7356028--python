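import numpy as np
import pytest

from pairiface import msa, synthetic


@pytest.fixture
def tiny_alignment():
    return msa.Alignment(
        rows=(("s1", "ACD-"), ("s2", "AC-E"), ("s3", "ACDE")), name="tiny"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_encoded(rng, n_rows, n_cols, include_gaps=True):
    low = 0 if include_gaps else 1
    return msa.EncodedAlignment(rng.integers(low, 21, size=(n_rows, n_cols)))


@pytest.fixture
def small_complex():
    spec = synthetic.SyntheticComplexSpec(
        M=20, N=16, n_interface=3, coupling=0.9, n_sequences=120, seed=7
    )
    return spec, synthetic.gen_complex(spec)
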