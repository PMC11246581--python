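import random

import pytest

from varmin import Contig, IndexParams
from varmin.pipeline import run_standard_experiment


def random_seq(rng: random.Random, n: int, n_prob: float = 0.0) -> str:
    return "".join(
        "N" if rng.random() < n_prob else rng.choice("ACGT") for _ in range(n)
    )


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def lex_params():
    return IndexParams(k=4, w=3, hash_scheme="lexicographic")


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """The standard end-to-end experiment, run once per session.

    Plain vs variant-modified index on the 100 kb / 550-variant / 30x
    fixture; the working directory (with both SAM files and the truth
    table) is kept for record-level assertions.
    """
    work = tmp_path_factory.mktemp("standard_e2e")
    result = run_standard_experiment(seed=7, work_dir=work)
    return result, work
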