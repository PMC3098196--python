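"""Scope expansion with AND-gated reactions and minimal-pathway backtracking.

The *scope* of a metabolite set is everything synthesizable from it under the
rule that a reaction fires only once **all** of its substrates are available.
Expansion proceeds in layers: layer ``n`` holds every directed reaction
instance whose substrates are all covered by the core plus the products of
layers ``< n``.  The expansion is deterministic; only the backtracking step,
which extracts a minimal pathway for one target from the layered structure,
uses randomness (uniform tie-breaks among equal-layer producers).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import UnreachableTargetError
from .universe import MetabolicUniverse

__all__ = [
    "ScopeExpansion",
    "Pathway",
    "PathwayGeometry",
    "expand_scope",
    "expansion_profile",
    "backtrack_pathway",
    "pathway_geometry",
    "shortest_distance_to_core",
]


@dataclass
class ScopeExpansion:
    """Layered reachability structure produced by :func:`expand_scope`.

    ``layers[n-1]`` lists the instance indices fired at step ``n``;
    ``first_layer[m]`` is the step at which metabolite ``m`` first becomes
    producible (0 for the core); ``S[n]`` the cumulative number of reached
    metabolites after step ``n``.
    """

    universe: MetabolicUniverse
    core: frozenset
    layers: list
    first_layer: dict
    inst_layer: dict
    S: np.ndarray
    target: str | None = None

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def reached(self) -> frozenset:
        return frozenset(self.first_layer)

    def producers_in_first_layer(self, m) -> list:
        """Instances producing ``m`` exactly at its first layer."""
        lay = self.first_layer[m]
        return [
            i
            for i in self.universe.producers.get(m, [])
            if self.inst_layer.get(i) == lay
        ]


def expand_scope(
    universe: MetabolicUniverse,
    core: Iterable,
    target: str | None = None,
    *,
    _need=None,
    _enabled=None,
) -> ScopeExpansion:
    """Layer-by-layer fixed point of AND-gated reachability.

    With ``target`` given, expansion stops at the first layer producing it
    and raises :class:`UnreachableTargetError` if the fixed point is reached
    first.  ``_need``/``_enabled`` allow a caller that tracks substrate
    availability incrementally (the branched simulator) to skip the initial
    core scan; results are identical to the from-scratch computation.
    """
    core = frozenset(core)
    if not core:
        raise ValueError("core must be non-empty")
    instances = universe.instances
    consumers = universe.consumers
    if _need is None:
        need = universe.base_need.copy()
        for m in core:
            for i in consumers.get(m, ()):
                need[i] -= 1
        current = [i for i in range(len(instances)) if need[i] == 0]
    else:
        need = _need
        current = list(_enabled)
    fired = np.zeros(len(instances), dtype=bool)
    first_layer = dict.fromkeys(core, 0)
    inst_layer: dict = {}
    layers: list = []
    S = [len(core)]
    n = 0
    target_found = target is not None and target in core
    while current and not target_found:
        n += 1
        layer = []
        new_mets = []
        for i in current:
            if fired[i]:
                continue
            fired[i] = True
            inst_layer[i] = n
            layer.append(i)
            for p in instances[i].products:
                if p not in first_layer:
                    first_layer[p] = n
                    new_mets.append(p)
        if not layer:
            break
        layers.append(layer)
        S.append(S[-1] + len(new_mets))
        if target is not None and target in first_layer:
            target_found = True
            break
        nxt = []
        for m in new_mets:
            for i in consumers.get(m, ()):
                need[i] -= 1
                if need[i] == 0:
                    nxt.append(i)
        current = nxt
    if target is not None and target not in first_layer:
        raise UnreachableTargetError(
            f"target {target!r} is outside the scope of the core"
        )
    return ScopeExpansion(
        universe=universe,
        core=core,
        layers=layers,
        first_layer=first_layer,
        inst_layer=inst_layer,
        S=np.array(S, dtype=np.int64),
        target=target,
    )


def expansion_profile(expansion: ScopeExpansion) -> np.ndarray:
    """Consecutive ratios ``S[n+1]/S[n]`` of reached-metabolite counts.

    The critical-like comparison curve is
    :func:`toolboxnet.branching.algebraic_growth_curve`.
    """
    if expansion.n_layers < 1:
        raise ValueError("degenerate expansion: no layers")
    S = expansion.S.astype(float)
    return S[1:] / S[:-1]


@dataclass
class Pathway:
    """A minimal acquired pathway: reaction instances with expansion layers.

    ``layer[i]`` is the expansion step at which instance ``i`` fired;
    reactions form a DAG from base substrates (in the core) up to the target,
    each non-core metabolite having exactly one producing reaction except
    where a byproduct of an earlier reaction is reused.
    """

    universe: MetabolicUniverse
    target: str
    instance_ids: tuple
    layer: dict
    length: int
    core: frozenset = field(repr=False, default=frozenset())

    @property
    def n_reactions(self) -> int:
        return len(self.instance_ids)

    @property
    def metabolites(self) -> frozenset:
        mets: set = set()
        for i in self.instance_ids:
            inst = self.universe.instances[i]
            mets.update(inst.substrates)
            mets.update(inst.products)
        return frozenset(mets)

    @property
    def new_metabolites(self) -> frozenset:
        """Metabolites of the pathway outside the core (incl. the target)."""
        return self.metabolites - self.core

    @property
    def reaction_ids(self) -> tuple:
        return tuple(self.universe.instances[i].rid for i in self.instance_ids)


def is_feasible(
    universe: MetabolicUniverse, instance_ids, core: frozenset, target: str
) -> bool:
    """Can ``target`` be produced from ``core`` using only these instances?

    Order-free fixed point; the independent definition of AND-feasibility
    used both by the pruning step and by tests.
    """
    ids = set(instance_ids)
    avail = set(core)
    if target in avail:
        return True
    changed = True
    while changed:
        changed = False
        for i in list(ids):
            inst = universe.instances[i]
            if all(s in avail for s in inst.substrates):
                ids.discard(i)
                for p in inst.products:
                    if p not in avail:
                        avail.add(p)
                        changed = True
                if target in avail:
                    return True
    return False


def backtrack_pathway(
    expansion: ScopeExpansion, target: str, rng: np.random.Generator
) -> Pathway:
    """Trace a minimal reaction set for ``target`` back through the layers.

    Starting from the target, pick uniformly among its producers in its
    first layer; every substrate of a chosen reaction that is neither in the
    core nor already provided by a previously chosen reaction at a strictly
    lower layer is recursed on at its own (strictly lower) first layer.  Two
    directions of one reversible reaction never co-occur.  A final greedy
    pass removes redundant reactions, which (by monotonicity of
    AND-feasibility) makes the result subset-minimal.
    """
    if target not in expansion.first_layer:
        raise UnreachableTargetError(f"target {target!r} not reached by expansion")
    universe = expansion.universe
    core = expansion.core
    if target in core:
        return Pathway(universe, target, (), {}, 0, core)
    twins = universe.reverse_twin
    chosen_set: set = set()
    provided_at: dict = {}  # metabolite -> lowest layer of a chosen producer
    # needs are processed from the deepest layer down so that byproducts of
    # already-chosen deep reactions can satisfy shallower demands
    heap = [(-expansion.first_layer[target], target)]
    while heap:
        _, m = heapq.heappop(heap)
        # a producer at or below m's first layer satisfies every possible
        # consumer (which always sits at a strictly higher layer)
        if provided_at.get(m, np.inf) <= expansion.first_layer[m]:
            continue
        options = [
            i
            for i in expansion.producers_in_first_layer(m)
            if i not in chosen_set and twins.get(i) not in chosen_set
        ]
        if not options:
            # all first-layer producers are blocked by the no-both-directions
            # rule; fall back to the shallowest unblocked producer
            options = sorted(
                (
                    i
                    for i in universe.producers.get(m, [])
                    if expansion.inst_layer.get(i) is not None
                    and i not in chosen_set
                    and twins.get(i) not in chosen_set
                ),
                key=lambda i: expansion.inst_layer[i],
            )
            if not options:
                raise UnreachableTargetError(
                    f"no admissible producer for {m!r} during backtracking"
                )
            options = [i for i in options if
                       expansion.inst_layer[i] == expansion.inst_layer[options[0]]]
        pick = options[int(rng.integers(len(options)))]
        lay = expansion.inst_layer[pick]
        chosen_set.add(pick)
        inst = universe.instances[pick]
        for p in inst.products:
            if provided_at.get(p, np.inf) > lay:
                provided_at[p] = lay
        for s in inst.substrates:
            if s in core:
                continue
            if provided_at.get(s, np.inf) < lay:
                continue  # already produced strictly below this reaction
            heapq.heappush(heap, (-expansion.first_layer[s], s))
    # greedy redundancy prune (deepest first); a single pass suffices because
    # AND-feasibility is monotone in the reaction set, so a reaction that is
    # not removable now never becomes removable later
    kept = sorted(chosen_set, key=lambda i: -expansion.inst_layer[i])
    for i in sorted(chosen_set, key=lambda i: -expansion.inst_layer[i]):
        trial = [j for j in kept if j != i]
        if is_feasible(universe, trial, core, target):
            kept = trial
    assert is_feasible(universe, kept, core, target), "backtracking lost feasibility"
    kept = sorted(kept, key=lambda i: expansion.inst_layer[i])
    layer = {i: expansion.inst_layer[i] for i in kept}
    return Pathway(
        universe=universe,
        target=target,
        instance_ids=tuple(kept),
        layer=layer,
        length=expansion.first_layer[target],
        core=core,
    )


@dataclass
class PathwayGeometry:
    """Position of an acquired pathway relative to the metabolic core."""

    target: str
    n_reactions: int  # N_R_path
    n_metabolites: int  # N_M_path: pathway metabolites outside the core
    length: int  # expansion layers from core to target
    n_border_rxn: int  # reactions touching >=1 core metabolite
    n_base: int  # core metabolites consumed by the pathway
    n_feedback: int  # core metabolites produced by the pathway
    n_byproduct: int  # terminal non-core, non-target products
    shortest_distance: int | None = None


def pathway_geometry(
    pathway: Pathway,
    core: Iterable,
    *,
    currency: Iterable = (),
    shortest_distance: int | None = None,
) -> PathwayGeometry:
    """Border/base/feedback/byproduct statistics of one pathway.

    Byproducts are products of pathway reactions that no pathway reaction
    consumes and that are neither core metabolites nor the target; a core
    metabolite produced by the pathway counts as feedback, never as a
    byproduct.  Currency metabolites (ubiquitously recycled co-factors) are
    excluded from the byproduct count.
    """
    core = frozenset(core)
    currency = frozenset(currency)
    universe = pathway.universe
    consumed: set = set()
    produced: set = set()
    n_border = 0
    for i in pathway.instance_ids:
        inst = universe.instances[i]
        consumed.update(inst.substrates)
        produced.update(inst.products)
        if core & (set(inst.substrates) | set(inst.products)):
            n_border += 1
    byproducts = produced - consumed - core - {pathway.target} - currency
    return PathwayGeometry(
        target=pathway.target,
        n_reactions=pathway.n_reactions,
        n_metabolites=len((consumed | produced) - core),
        length=pathway.length,
        n_border_rxn=n_border,
        n_base=len(core & consumed),
        n_feedback=len(core & produced),
        n_byproduct=len(byproducts),
        shortest_distance=shortest_distance,
    )


def shortest_distance_to_core(
    universe: MetabolicUniverse, core: Iterable, target: str
) -> int:
    """Multi-source BFS hop count from the core on the simple-graph
    projection (AND constraints ignored)."""
    core = set(core)
    if target in core:
        return 0
    adjacency = universe.adjacency
    dist = dict.fromkeys(core, 0)
    q = [m for m in core]
    d = 0
    while q:
        d += 1
        nxt = []
        for m in q:
            for v in adjacency.get(m, ()):
                if v not in dist:
                    dist[v] = d
                    if v == target:
                        return d
                    nxt.append(v)
        q = nxt
    raise UnreachableTargetError(
        f"target {target!r} unreachable from the core on the simple graph"
    )
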