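import random

import pytest

from mitorearrange import SignedGene, SignedGeneOrder
from mitorearrange import datasets


@pytest.fixture(scope="session")
def annot_table():
    return datasets.polydesmus_table()


@pytest.fixture(scope="session")
def ancestral():
    return datasets.ancestral_order()


@pytest.fixture(scope="session")
def polydesmus():
    return datasets.polydesmus_order()


def random_order(rng: random.Random, n: int, mixed: bool = False,
                 anchor_label: str | None = None) -> SignedGeneOrder:
    """A random signed circular order over labels g0..g{n-1}.

    With mixed=True at least one gene of each polarity is guaranteed.
    """
    labels = [f"g{i}" for i in range(n)]
    rng.shuffle(labels)
    orients = [rng.choice((1, -1)) for _ in labels]
    if mixed:
        orients[0], orients[1] = 1, -1
    genes = tuple(SignedGene(l, o) for l, o in zip(labels, orients))
    return SignedGeneOrder(genes, circular=True, anchor=anchor_label or labels[0])
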