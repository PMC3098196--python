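"""Reaction universes: KEGG map-formula parsing and hypergraph containers.

A :class:`MetabolicUniverse` is a boolean reaction hypergraph: each reaction
converts a substrate set into a product set, reversible reactions contribute
two directed instances.  Stoichiometric coefficients are ignored (the model
only asks whether a metabolite is available) and a metabolite listed on both
sides of one reaction is dropped from the substrate side, where it is vacuous
under boolean semantics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, NamedTuple

import networkx as nx

from .errors import MapFormulaParseError

__all__ = [
    "Reaction",
    "ReactionInstance",
    "MetabolicUniverse",
    "parse_mapformula",
    "remove_currency",
    "default_currency_metabolites",
    "project_simple_graph",
    "write_universe",
    "read_universe",
]


def default_currency_metabolites() -> list:
    """Ids from the shipped currency-metabolite config file."""
    from importlib.resources import files

    text = files("toolboxnet").joinpath("data/currency_kegg.txt").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


@dataclass(frozen=True)
class Reaction:
    """One reaction: substrate set -> product set, optionally reversible."""

    id: str
    substrates: frozenset
    products: frozenset
    reversible: bool = False

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.id}: both sides must be non-empty")
        if self.substrates & self.products:
            raise ValueError(
                f"reaction {self.id}: substrate/product sets must be disjoint "
                "after normalization"
            )

    @staticmethod
    def normalized(rid, substrates, products, reversible=False):
        """Drop two-sided metabolites from the substrate side; None if a side
        empties out."""
        substrates = frozenset(substrates)
        products = frozenset(products)
        substrates = substrates - products
        if not substrates or not products:
            return None
        return Reaction(rid, substrates, products, reversible)


class ReactionInstance(NamedTuple):
    """A directed firing of a reaction (reversible ones appear twice)."""

    rid: str
    forward: bool
    substrates: tuple
    products: tuple


class MetabolicUniverse:
    """Immutable-by-convention container of reactions over metabolite ids.

    Directed instances, consumer/producer indexes and the simple-graph
    adjacency are built lazily and cached; they are ordered deterministically
    (sorted by reaction id, forward before reverse) so that seeded
    simulations are reproducible.
    """

    def __init__(self, reactions: Iterable[Reaction], metabolites: Iterable = ()):
        self.reactions: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in self.reactions:
                raise ValueError(f"duplicate reaction id {r.id}")
            self.reactions[r.id] = r
        mets = set(metabolites)  # isolated metabolites are allowed
        for r in self.reactions.values():
            mets |= r.substrates | r.products
        self.metabolites: frozenset = frozenset(mets)

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @cached_property
    def instances(self) -> list[ReactionInstance]:
        out = []
        for rid in sorted(self.reactions):
            r = self.reactions[rid]
            subs = tuple(sorted(r.substrates))
            prods = tuple(sorted(r.products))
            out.append(ReactionInstance(rid, True, subs, prods))
            if r.reversible:
                out.append(ReactionInstance(rid, False, prods, subs))
        return out

    @cached_property
    def consumers(self) -> dict:
        """metabolite -> indices of instances consuming it as a substrate."""
        idx: dict = {}
        for i, inst in enumerate(self.instances):
            for m in inst.substrates:
                idx.setdefault(m, []).append(i)
        return idx

    @cached_property
    def producers(self) -> dict:
        """metabolite -> indices of instances producing it."""
        idx: dict = {}
        for i, inst in enumerate(self.instances):
            for m in inst.products:
                idx.setdefault(m, []).append(i)
        return idx

    @cached_property
    def base_need(self):
        """Number of distinct substrates per instance (expansion counters)."""
        import numpy as np

        return np.array([len(inst.substrates) for inst in self.instances], dtype=np.int64)

    @cached_property
    def reverse_twin(self) -> dict:
        """instance index -> index of the opposite direction, if reversible."""
        by_rid: dict = {}
        for i, inst in enumerate(self.instances):
            by_rid.setdefault(inst.rid, []).append(i)
        twin = {}
        for idxs in by_rid.values():
            if len(idxs) == 2:
                twin[idxs[0]] = idxs[1]
                twin[idxs[1]] = idxs[0]
        return twin

    @cached_property
    def adjacency(self) -> dict:
        """Simple-graph successors: substrate -> sorted tuple of products."""
        adj: dict = {}
        for inst in self.instances:
            for s in inst.substrates:
                adj.setdefault(s, set()).update(inst.products)
        return {m: tuple(sorted(v)) for m, v in adj.items()}


_LINE_RE = re.compile(r"^\s*(\S+):\s*(\S+):\s*(.*\S)\s*$")
_ARROWS = ("<=>", "=>", "<=")


def _parse_side(side: str, line_no: int):
    mets = []
    for token in side.split("+"):
        token = token.strip()
        if not token:
            raise MapFormulaParseError("empty metabolite token", line_no)
        parts = token.split()
        mets.append(parts[-1])  # drop a leading stoichiometric coefficient
    return mets


def parse_mapformula(stream) -> MetabolicUniverse:
    """Parse the KEGG ``reaction_mapformula.lst`` dialect.

    Lines read ``RID: MAPID: C00001 + C00002 => C00003``.  Left-pointing
    reactions are normalized by swapping sides; a reaction id observed with
    ``<=>`` or with conflicting directions across maps becomes reversible,
    and its sides are merged by union in the first-seen orientation.
    """
    if isinstance(stream, str):
        stream = iter(stream.splitlines())
    acc: dict = {}  # rid -> [substrates, products, reversible]
    order: list = []
    for line_no, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise MapFormulaParseError(f"unparsable line {line!r}", line_no)
        rid, _map_id, formula = m.groups()
        rid = rid.rstrip(":")
        arrow = next((a for a in _ARROWS if f" {a} " in f" {formula} "), None)
        if arrow is None:
            raise MapFormulaParseError(
                f"missing direction token in {formula!r}", line_no
            )
        left, _, right = formula.partition(arrow)
        subs = _parse_side(left, line_no)
        prods = _parse_side(right, line_no)
        reversible = arrow == "<=>"
        if arrow == "<=":
            subs, prods = prods, subs
        if rid not in acc:
            acc[rid] = [set(subs), set(prods), reversible]
            order.append(rid)
        else:
            entry = acc[rid]
            same = set(subs) & entry[0] or set(prods) & entry[1]
            opposite = set(subs) & entry[1] or set(prods) & entry[0]
            if opposite and not same:
                subs, prods = prods, subs
                entry[2] = True  # conflicting directions across maps
            entry[0] |= set(subs)
            entry[1] |= set(prods)
            entry[2] = entry[2] or reversible
    reactions = []
    for rid in order:
        subs, prods, rev = acc[rid]
        r = Reaction.normalized(rid, subs, prods, rev)
        if r is not None:
            reactions.append(r)
    return MetabolicUniverse(reactions)


def remove_currency(
    universe: MetabolicUniverse,
    currency: Iterable = (),
    degree_threshold: int | None = None,
):
    """Delete currency metabolites (listed and/or above a participation
    degree) from all reactions.

    Returns ``(new_universe, report)`` where the report lists removed
    metabolite ids and reactions dropped because a side emptied out.
    Removing an absent id is a no-op.
    """
    remove = set(currency) & universe.metabolites
    if degree_threshold is not None:
        degree: dict = {}
        for r in universe.reactions.values():
            for m in r.substrates | r.products:
                degree[m] = degree.get(m, 0) + 1
        remove |= {m for m, k in degree.items() if k > degree_threshold}
    kept, dropped = [], []
    for r in universe.reactions.values():
        nr = Reaction.normalized(
            r.id, r.substrates - remove, r.products - remove, r.reversible
        )
        if nr is None:
            dropped.append(r.id)
        else:
            kept.append(nr)
    report = {
        "removed_metabolites": sorted(remove),
        "dropped_reactions": sorted(dropped),
    }
    return MetabolicUniverse(kept), report


def project_simple_graph(universe: MetabolicUniverse) -> nx.DiGraph:
    """Directed substrate -> product graph, parallel edges collapsed.

    Reversible reactions contribute edges in both directions.  This loses
    the AND semantics of multi-substrate reactions and is used only for
    linearization and shortest-distance baselines.
    """
    g = nx.DiGraph()
    g.add_nodes_from(sorted(universe.metabolites))
    for inst in universe.instances:
        for s in inst.substrates:
            for p in inst.products:
                g.add_edge(s, p)
    return g


def write_universe(universe: MetabolicUniverse, path_or_buf, meta: dict | None = None):
    """TSV: reaction_id, direction, substrates (comma-sep), products."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# meta: {json.dumps(meta or {}, sort_keys=True)}\n")
        fh.write("reaction_id\tdirection\tsubstrates\tproducts\n")
        for rid in sorted(universe.reactions):
            r = universe.reactions[rid]
            fh.write(
                f"{rid}\t{'reversible' if r.reversible else 'irreversible'}\t"
                f"{','.join(sorted(r.substrates))}\t{','.join(sorted(r.products))}\n"
            )
    finally:
        if own:
            fh.close()


def read_universe(path_or_buf):
    """Inverse of :func:`write_universe`; returns (universe, meta)."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        meta: dict = {}
        reactions = []
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# meta:"):
                    meta = json.loads(line[len("# meta:"):])
                continue
            if not header_seen:
                header_seen = True
                continue
            rid, direction, subs, prods = line.split("\t")
            reactions.append(
                Reaction(
                    rid,
                    frozenset(subs.split(",")),
                    frozenset(prods.split(",")),
                    direction == "reversible",
                )
            )
    finally:
        if own:
            fh.close()
    return MetabolicUniverse(reactions), meta
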