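import numpy as np
import pytest

import neurosep as ns


@pytest.fixture(scope="session")
def easy_set():
    """The default 392-stimulus easy design."""
    return ns.build_stimulus_set()


@pytest.fixture(scope="session")
def letters_set(easy_set):
    return easy_set.single_letters


@pytest.fixture(scope="session")
def ngrams_set(easy_set):
    return easy_set.ngrams


@pytest.fixture(scope="session")
def small_bank():
    """A small balanced bank for decoding tests."""
    return ns.build_balanced_bank(per_length_count=40, seed=7)


@pytest.fixture(scope="session")
def broad_mult_sum_pop():
    """A broad-tuned multiplicative-attribute sum-rule population."""
    return ns.make_separable_population(
        30, "all-broad", "multiplicative", "sum", True, seed=11)


@pytest.fixture(scope="session")
def noise_free_rm(broad_mult_sum_pop, easy_set):
    return ns.noise_free_responses(broad_mult_sum_pop, easy_set)
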