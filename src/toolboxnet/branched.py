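"""The branched toolbox model: evolution by minimal-pathway acquisition.

Starting from a seed core (central metabolism plus currency metabolites),
the organism repeatedly picks a random metabolite it cannot yet synthesize
from the scope of the seed set, expands the scope of its *current* core
until the target first appears, backtracks a minimal AND-feasible pathway,
and horizontally acquires those reactions.  Each acquisition is one pathway
with one dedicated transcriptional regulator, so N_L counts acquisitions
while N_M counts core metabolites; the run ends when the organism owns the
entire scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError, ScopeExhaustedError
from .scope import (
    Pathway,
    backtrack_pathway,
    expand_scope,
    pathway_geometry,
    shortest_distance_to_core,
)
from .trajectory import Trajectory
from .universe import MetabolicUniverse

__all__ = ["OrganismState", "init_state", "acquire_target", "simulate_evolution",
           "BranchedResult", "write_pathway_table"]

PATHWAY_COLUMNS = [
    "target", "N_R_path", "N_M_path", "length", "n_border_rxn", "n_base",
    "n_feedback", "n_byproduct", "shortest_distance",
]


@dataclass
class OrganismState:
    """Evolving organism: core metabolites plus acquired reactions.

    The core is maintained as the closure of the seed under the acquired
    reaction set, so "cannot yet be synthesized" is exact; it grows
    monotonically and every acquired reaction was AND-feasible when acquired.
    """

    universe: MetabolicUniverse
    seed: frozenset
    core: set
    scope: frozenset
    acquired: set = field(default_factory=set)  # instance indices
    n_l: int = 0
    pathways: list = field(default_factory=list)
    geometries: list = field(default_factory=list)
    target_pool: str = "all"
    currency: frozenset = frozenset()
    # substrate-availability counters w.r.t. the current core, all instances
    _need: np.ndarray | None = None
    _enabled: set = field(default_factory=set)  # instances with need == 0
    _candidates: list = field(default_factory=list)
    _cand_pos: dict = field(default_factory=dict)

    @property
    def n_m(self) -> int:
        return len(self.core)

    @property
    def remaining_targets(self) -> int:
        return len(self._candidates)

    def n_m_counted(self, include_seed: bool = True) -> int:
        return len(self.core) - (0 if include_seed else len(self.seed))


def _sinks(universe: MetabolicUniverse) -> frozenset:
    return frozenset(universe.metabolites - set(universe.consumers))


def init_state(
    universe: MetabolicUniverse,
    seed_metabolites: Iterable,
    *,
    target_pool: str = "all",
    currency: Iterable = (),
) -> OrganismState:
    """Set up the organism with its seed core and precomputed full scope.

    ``target_pool`` chooses the candidate targets: ``"all"`` scope
    metabolites (the standard rule) or only ``"sinks"`` (metabolites no
    reaction consumes — the leaves of a tree-shaped anabolic universe).
    """
    seed = frozenset(seed_metabolites)
    if not seed:
        raise ConfigError("seed metabolite set must be non-empty", "seed_metabolites")
    unknown = seed - universe.metabolites
    if unknown:
        raise ConfigError(f"unknown seed metabolites {sorted(unknown)[:5]}", "seed_metabolites")
    if target_pool not in ("all", "sinks"):
        raise ConfigError(f"unknown target pool {target_pool!r}", "target_pool")
    full = expand_scope(universe, seed)
    scope = full.reached
    pool = scope - seed
    if target_pool == "sinks":
        pool &= _sinks(universe)
    state = OrganismState(
        universe=universe,
        seed=seed,
        core=set(seed),
        scope=scope,
        target_pool=target_pool,
        currency=frozenset(currency),
    )
    state._need = universe.base_need.copy()
    for m in seed:
        for i in universe.consumers.get(m, ()):
            state._need[i] -= 1
    state._enabled = {i for i in range(len(universe.instances)) if state._need[i] == 0}
    state._candidates = sorted(pool)
    state._cand_pos = {m: k for k, m in enumerate(state._candidates)}
    return state


def _drop_candidate(state: OrganismState, m) -> None:
    pos = state._cand_pos.pop(m, None)
    if pos is None:
        return
    last = state._candidates.pop()
    if last != m:
        state._candidates[pos] = last
        state._cand_pos[last] = pos


def _absorb(state: OrganismState, pathway: Pathway) -> set:
    """Acquire the pathway's reactions and close the core under them.

    Returns the set of metabolites newly added to the core (the target,
    intermediates, byproducts, and any cross-pathway synergy products).
    """
    universe = state.universe
    queue = []
    for i in pathway.instance_ids:
        if i in state.acquired:
            continue
        state.acquired.add(i)
        if state._need[i] == 0:
            queue.extend(p for p in universe.instances[i].products if p not in state.core)
    new_mets: set = set()
    while queue:
        m = queue.pop()
        if m in state.core:
            continue
        state.core.add(m)
        new_mets.add(m)
        _drop_candidate(state, m)
        for i in universe.consumers.get(m, ()):
            state._need[i] -= 1
            if state._need[i] == 0:
                state._enabled.add(i)
                if i in state.acquired:
                    queue.extend(
                        p for p in universe.instances[i].products if p not in state.core
                    )
    return new_mets


def acquire_target(
    state: OrganismState,
    rng: np.random.Generator,
    *,
    record_distance: bool = True,
) -> Pathway:
    """One evolutionary step: random target, minimal pathway, acquisition."""
    if not state._candidates:
        raise ScopeExhaustedError("every scope metabolite is already synthesizable")
    target = state._candidates[int(rng.integers(len(state._candidates)))]
    expansion = expand_scope(
        state.universe,
        state.core,
        target=target,
        _need=state._need.copy(),
        _enabled=state._enabled,
    )
    pathway = backtrack_pathway(expansion, target, rng)
    distance = (
        shortest_distance_to_core(state.universe, state.core, target)
        if record_distance
        else None
    )
    geometry = pathway_geometry(
        pathway, state.core, currency=state.currency, shortest_distance=distance
    )
    _absorb(state, pathway)
    state.n_l += 1
    state.pathways.append(pathway)
    state.geometries.append(geometry)
    return pathway


@dataclass
class BranchedResult:
    trajectory: Trajectory
    pathway_table: pd.DataFrame
    state: OrganismState


def simulate_evolution(
    universe: MetabolicUniverse,
    seed_metabolites: Iterable,
    seed=None,
    *,
    target_pool: str = "all",
    currency: Iterable = (),
    include_seed_in_nm: bool = True,
    record_distance: bool = True,
    max_steps: int | None = None,
) -> BranchedResult:
    """Run acquisitions until the organism's network reaches the full scope.

    Returns the (N_L, N_M) trajectory plus a per-pathway geometry table with
    columns ``target, N_R_path, N_M_path, length, n_border_rxn, n_base,
    n_feedback, n_byproduct, shortest_distance``.
    """
    rng = np.random.default_rng(seed)
    state = init_state(
        universe, seed_metabolites, target_pool=target_pool, currency=currency
    )
    n_l, n_m, rows = [], [], []
    while state._candidates:
        acquire_target(state, rng, record_distance=record_distance)
        n_l.append(state.n_l)
        n_m.append(state.n_m_counted(include_seed_in_nm))
        g = state.geometries[-1]
        rows.append(
            (g.target, g.n_reactions, g.n_metabolites, g.length, g.n_border_rxn,
             g.n_base, g.n_feedback, g.n_byproduct, g.shortest_distance)
        )
        if max_steps is not None and state.n_l >= max_steps:
            break
    table = pd.DataFrame(rows, columns=PATHWAY_COLUMNS)
    traj = Trajectory(
        np.array(n_l), np.array(n_m),
        meta={"seed": seed, "n_metabolites": universe.n_metabolites,
              "scope_size": len(state.scope), "target_pool": target_pool},
    )
    return BranchedResult(trajectory=traj, pathway_table=table, state=state)


def write_pathway_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
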