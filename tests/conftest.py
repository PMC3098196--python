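import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toolboxnet.universe import MetabolicUniverse, Reaction

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


class QueuedRNG:
    """Deterministic stand-in for a Generator: integers() pops a queue."""

    def __init__(self, picks):
        self.picks = list(picks)

    def integers(self, high):
        assert self.picks, "queued picks exhausted"
        pick = self.picks.pop(0)
        assert 0 <= pick < high
        return pick


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def and_gate_universe():
    """r1: A->B; r2: A->D; r3: B+D->E; r4: E->F with core {A}."""
    return MetabolicUniverse(
        [
            Reaction("r1", frozenset("A"), frozenset("B")),
            Reaction("r2", frozenset("A"), frozenset("D")),
            Reaction("r3", frozenset(["B", "D"]), frozenset("E")),
            Reaction("r4", frozenset("E"), frozenset("F")),
        ]
    )


def random_toy_universe(rng, n_mets=None, n_rxns=None):
    """Small random reaction universe plus a random non-empty core."""
    n_mets = n_mets or int(rng.integers(5, 13))
    n_rxns = n_rxns or int(rng.integers(4, 31))
    mets = [f"x{i}" for i in range(n_mets)]
    reactions = []
    for r in range(n_rxns):
        subs = set(rng.choice(mets, size=int(rng.integers(1, 4)), replace=False))
        prods = set(rng.choice(mets, size=int(rng.integers(1, 3)), replace=False))
        rx = Reaction.normalized(f"t{r}", subs, prods, bool(rng.random() < 0.3))
        if rx is not None:
            reactions.append(rx)
    core = set(rng.choice(mets, size=int(rng.integers(1, 4)), replace=False))
    return MetabolicUniverse(reactions), frozenset(core)
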