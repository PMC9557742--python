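import random

import pytest

from lrfdist import random_labeled_tree, worked_example_pair

LABEL_SETS = {
    1: ["speciation"],
    2: ["speciation", "duplication"],
    3: ["speciation", "duplication", "transfer"],
}


def make_pair(rng: random.Random, n_min=4, n_max=25, n_labels=2):
    """Two independent random labeled trees on the same leaf set."""
    n = rng.randint(n_min, n_max)
    labels = LABEL_SETS[n_labels]
    shape = rng.choice(["binary", "multifurcating"])
    t1 = random_labeled_tree(n, labels, seed=rng.randrange(2**30), shape=shape)
    t2 = random_labeled_tree(n, labels, seed=rng.randrange(2**30), shape=shape)
    return t1, t2


@pytest.fixture
def worked_pair():
    return worked_example_pair()


@pytest.fixture
def rng():
    return random.Random(20240917)
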