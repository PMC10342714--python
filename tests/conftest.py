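import numpy as np
import pytest
from hypothesis import settings

from ledams import datasets, synthgen

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def elf_table():
    """The six-equation two-isomer characteristic-ratio table."""
    return datasets.elf_ratio_table()


@pytest.fixture
def clean_chromatogram(elf_table):
    """Noise-free equimolar co-eluting run plus its generator truth."""
    params = synthgen.ChromSimParams(table=elf_table, isomer_fractions=(0.5, 0.5),
                                     noise_cv=0.0, seed=11)
    return synthgen.gen_chromatogram(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
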