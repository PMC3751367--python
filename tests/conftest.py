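import random

import pytest

from tiim.impact import ImpactDegreeTable
from tiim.synthetic import toy_example
from tiim.transactions import (
    STAGE_DIFFERENTIATED,
    GeneItem,
    TransactionDB,
    differentiate,
    discretize,
    integrate,
)


@pytest.fixture(scope="session")
def toy():
    """The deterministic 5-gene worked-example dataset and its star GRN."""
    return toy_example()


@pytest.fixture(scope="session")
def toy_dbs(toy):
    """Integrated and differentiated DBs of the worked example."""
    dataset, _ = toy
    disc = discretize(dataset)
    c1, c2 = dataset.conditions
    int1, int2 = integrate(disc, c1), integrate(disc, c2)
    diff1, diff2 = differentiate(int1, int2)
    return {"int": {c1: int1, c2: int2}, "diff": {c1: diff1, c2: diff2}}


def make_db(transactions, condition="c", n_replicates=3, stage=STAGE_DIFFERENTIATED):
    """Build a TransactionDB from a list of {GeneItem: quantity} dicts."""
    txs = [dict(t) for t in transactions]
    return TransactionDB(
        condition=condition,
        timepoints=list(range(1, len(txs) + 1)),
        transactions=txs,
        n_replicates=n_replicates,
        stage=stage,
    )


def make_degrees(degrees, default=0):
    return ImpactDegreeTable(degrees=dict(degrees), significant=frozenset(), default=default)


def random_instance(rng: random.Random, max_items=10, max_tx=6, max_q=3, max_d=4):
    """A small random DB + degree table for oracle-equivalence checks."""
    n_items = rng.randint(2, max_items)
    n_tx = rng.randint(1, max_tx)
    items = [GeneItem(f"g{i}", rng.choice(["up", "down"])) for i in range(n_items)]
    txs = []
    for _ in range(n_tx):
        t = {}
        for it in items:
            q = rng.randint(0, max_q)
            if q:
                t[it] = q
        txs.append(t)
    db = make_db(txs)
    degrees = make_degrees({it.gene: rng.randint(0, max_d) for it in items})
    return db, degrees
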