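"""Synthetic layered reaction universes with critical-like scope expansion.

The generator emulates the curated reaction hypergraph on which the branched
toolbox model runs: metabolites are arranged in layers 0..n_layers of roughly
equal size (layer 0 is the designated seed/core set, sized like the central
carbohydrate metabolism plus currency metabolites), and every non-seed
metabolite is the product of at least one reaction whose substrates all lie
in strictly lower layers, with at least one substrate in the immediately
preceding layer.  This guarantees that the scope of the seed layer covers the
whole universe while the cumulative reached-metabolite counts S_n grow
linearly in the expansion step — the algebraic, critical-like growth
(S_{n+1}/S_n -> 1) observed for real metabolic universes.

Substrate/product multiplicities are drawn from the empirical distribution
of irreversible reactions in curated databases (up to 5 substrates and 5
products, the (2 substrates, 2 products) class dominating).  Substrate slots
beyond the mandatory previous-layer one are biased toward the seed layer,
mirroring the ubiquity of currency co-factors (water, ATP, NAD...) among
reaction substrates.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .branching import LayeredTree
from .errors import GenerationError
from .universe import MetabolicUniverse, Reaction

__all__ = [
    "DEFAULT_MULTIPLICITY_WEIGHTS",
    "SyntheticUniverse",
    "generate_synthetic_universe",
    "universe_from_tree",
]

# Empirical (n_substrates, n_products) counts of irreversible reactions in a
# curated metabolic database; used as default sampling weights.
DEFAULT_MULTIPLICITY_WEIGHTS: dict = {
    (1, 1): 157, (1, 2): 141, (1, 3): 4,
    (2, 1): 82, (2, 2): 491, (2, 3): 95, (2, 4): 7,
    (3, 1): 1, (3, 2): 123, (3, 3): 170, (3, 4): 31, (3, 5): 1,
    (4, 2): 10, (4, 3): 73, (4, 4): 15,
    (5, 3): 1,
}


class SyntheticUniverse(NamedTuple):
    universe: MetabolicUniverse
    seed_metabolites: frozenset
    layer_of: dict


def generate_synthetic_universe(
    n_metabolites: int = 2000,
    n_layers: int = 40,
    multiplicity_weights: dict | None = None,
    reversible_fraction: float = 0.5,
    *,
    reactions_per_metabolite: float = 1.5,
    seed_substrate_bias: float = 0.9,
    seed_product_bias: float = 0.95,
    seed=None,
) -> SyntheticUniverse:
    """Generate a layered multi-substrate reaction universe.

    Parameters
    ----------
    n_metabolites, n_layers:
        Total metabolites, split evenly over layers ``0..n_layers``; layer 0
        is the seed set returned alongside the universe.
    multiplicity_weights:
        ``(n_substrates, n_products) -> weight`` sampling table; defaults to
        :data:`DEFAULT_MULTIPLICITY_WEIGHTS`.
    reversible_fraction:
        Probability for each reaction to be reversible.
    reactions_per_metabolite:
        Target ratio of reactions to non-seed metabolites (real universes
        have ~1.5 reactions per metabolite).
    seed_substrate_bias:
        Probability that each substrate slot beyond the mandatory
        previous-layer one is filled from the seed layer (currency-like
        usage) rather than uniformly from lower layers.
    seed_product_bias:
        Probability that each product slot beyond the first releases a seed
        metabolite (a recycled currency co-product such as ADP or NAD+)
        rather than another metabolite of the reaction's own layer; this is
        what keeps most minimal pathways free of byproducts.
    """
    if n_layers < 1:
        raise GenerationError("n_layers must be >= 1")
    if n_metabolites < 2 * (n_layers + 1):
        raise GenerationError("need at least two metabolites per layer")
    weights = dict(
        DEFAULT_MULTIPLICITY_WEIGHTS if multiplicity_weights is None else multiplicity_weights
    )
    if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise GenerationError("multiplicity weights must be normalizable")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_metabolites, n_layers + 1)
    sizes = [base + (1 if i < extra else 0) for i in range(n_layers + 1)]
    layers: list[list[str]] = []
    counter = 0
    for ell, sz in enumerate(sizes):
        layers.append([f"m{counter + i:05d}" for i in range(sz)])
        counter += sz
    layer_of = {m: ell for ell, group in enumerate(layers) for m in group}

    pairs = sorted(weights)
    pw = np.array([weights[p] for p in pairs], dtype=float)
    pw /= pw.sum()
    max_sub = max(p[0] for p in pairs)
    if any(sz < max_sub for sz in sizes[:1]):
        raise GenerationError("seed layer smaller than the maximum multiplicity")

    reactions = []
    rcount = 0
    lower_pool: list[str] = list(layers[0])  # metabolites in layers < current
    for ell in range(1, n_layers + 1):
        here = layers[ell]
        n_rxn = max(1, int(np.ceil(len(here) * reactions_per_metabolite)))
        # shuffled coverage queue: every metabolite of this layer must be a
        # product of at least one reaction
        queue = list(here)
        rng.shuffle(queue)
        made = 0
        while queue or made < n_rxn:
            n_s, n_p = pairs[int(rng.choice(len(pairs), p=pw))]
            n_p = min(n_p, len(here) + len(layers[0]))
            prods = set()
            if queue:
                prods.add(queue.pop())
            else:
                prods.add(here[int(rng.integers(len(here)))])
            # co-product slots: mostly recycled seed/currency metabolites,
            # otherwise further metabolites of this layer
            while len(prods) < n_p:
                if rng.random() < seed_product_bias:
                    prods.add(layers[0][int(rng.integers(len(layers[0])))])
                else:
                    cand = here[int(rng.integers(len(here)))]
                    if cand in queue:
                        queue.remove(cand)
                    prods.add(cand)
            prev = layers[ell - 1]
            chain = prev[int(rng.integers(len(prev)))]
            for _ in range(100):
                if chain not in prods:
                    break
                chain = prev[int(rng.integers(len(prev)))]
            subs = {chain}
            n_s = min(n_s, len(layers[0]) if ell == 1 else len(lower_pool))
            attempts = 0
            while len(subs) < n_s and attempts < 200:
                attempts += 1
                if rng.random() < seed_substrate_bias or ell == 1:
                    pool = layers[0]
                else:
                    pool = lower_pool
                cand = pool[int(rng.integers(len(pool)))]
                if cand not in prods:
                    subs.add(cand)
            if subs & prods:
                queue.extend(p for p in prods if p in here)  # keep coverage
                continue  # tiny universes: retry this reaction draw
            reversible = bool(rng.random() < reversible_fraction)
            reactions.append(
                Reaction(f"R{rcount:05d}", frozenset(subs), frozenset(prods), reversible)
            )
            rcount += 1
            made += 1
        lower_pool.extend(here)

    universe = MetabolicUniverse(reactions, metabolites=layer_of)
    return SyntheticUniverse(
        universe=universe,
        seed_metabolites=frozenset(layers[0]),
        layer_of=layer_of,
    )


def universe_from_tree(tree: LayeredTree) -> SyntheticUniverse:
    """Anabolic single-substrate universe mirroring a universal tree.

    Every tree edge parent -> child becomes an irreversible (1, 1) reaction,
    with the root as the sole seed metabolite.  Running the branched toolbox
    model on this universe with targets restricted to sinks reproduces the
    tree toolbox model exactly.
    """
    labels = tree.labels or [f"n{i}" for i in range(tree.n_nodes)]
    reactions = []
    for child in range(1, tree.n_nodes):
        parent = int(tree.parents[child])
        reactions.append(
            Reaction(
                f"E{child:05d}",
                frozenset([labels[parent]]),
                frozenset([labels[child]]),
                False,
            )
        )
    universe = MetabolicUniverse(reactions)
    layer_of = {labels[i]: int(tree.depths[i]) for i in range(tree.n_nodes)}
    return SyntheticUniverse(
        universe=universe,
        seed_metabolites=frozenset([labels[0]]),
        layer_of=layer_of,
    )
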