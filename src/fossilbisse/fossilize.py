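"""Fossil sampling and the two observable views of a complete tree.

Fossil occurrences fall on the complete tree as a Poisson process with
rate psi along every branch, each occurrence stamped with the lineage's
trait states at that moment. Two observable trees are then derived:

* the *extant* view — extinct lineages pruned, yielding an ultrametric
  binary tree of the present-day species;
* the *FBD* view — unsampled extinct lineages pruned, and each extinct
  lineage truncated at its last fossil. A fossil with no sampled material
  anywhere below it becomes a terminal *fossil tip*; every other fossil is
  a degree-2 *sampled ancestor* node on the path to younger samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sim import FOCAL_TRAIT, CompleteTree

__all__ = [
    "FossilOccurrence",
    "SNode",
    "SampledTree",
    "sample_fossils",
    "prune_to_extant",
    "build_fbd_tree",
    "strip_fossils",
]

EXTANT = "extant"
FOSSIL_TIP = "fossil_tip"
SAMPLED_ANCESTOR = "sampled_ancestor"
INTERNAL = "internal"


@dataclass(frozen=True)
class FossilOccurrence:
    """A point fossil sample on a lineage of the complete tree."""

    lineage: int
    time: float  # forward clock of the simulator
    states: dict[str, int] = field(compare=False)

    @property
    def state(self) -> int:
        return self.states[FOCAL_TRAIT]


def sample_fossils(
    tree: CompleteTree, psi: float, rng: np.random.Generator
) -> list[FossilOccurrence]:
    """Poisson(psi) fossil occurrences along every branch of the tree.

    Occurrence times are uniform over each lineage's lifespan given the
    count; each occurrence is stamped with every trait's state at its
    time. Returned sorted by (lineage, time).
    """
    if psi < 0:
        raise ValueError("psi must be >= 0")
    out: list[FossilOccurrence] = []
    if psi == 0:
        return out
    for k in range(tree.n_lineages):
        span = tree.branch_length(k)
        n = rng.poisson(psi * span)
        if n == 0:
            continue
        times = np.sort(tree.birth[k] + span * rng.random(n))
        for t in times:
            t = float(t)
            states = {name: tree.state_at(name, k, t) for name in tree.traits}
            out.append(FossilOccurrence(k, t, states))
    out.sort(key=lambda o: (o.lineage, o.time))
    return out


class SNode:
    """Node of a sampled (observable) tree.

    ``time`` is on the simulator's forward clock; ages (time before
    present) are derived by the owning :class:`SampledTree`. ``kind`` is
    one of extant / fossil_tip / sampled_ancestor / internal. Sample nodes
    carry ``lineage`` and per-trait ``states`` so states can be re-stamped
    when a neutral trait is resimulated.
    """

    __slots__ = ("label", "time", "kind", "lineage", "states", "children", "parent")

    def __init__(self, label, time, kind, lineage=-1, states=None):
        self.label = label
        self.time = time
        self.kind = kind
        self.lineage = lineage
        self.states = dict(states) if states else {}
        self.children: list[SNode] = []
        self.parent: SNode | None = None

    def add(self, child: "SNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_sample(self) -> bool:
        return self.kind in (EXTANT, FOSSIL_TIP, SAMPLED_ANCESTOR)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SNode({self.label!r}, t={self.time:.4g}, {self.kind})"


@dataclass
class SampledTree:
    """An observable tree view (extant-only or FBD)."""

    root: SNode
    present: float  # forward-clock time of the present
    view: str  # "extant" | "fbd"

    def nodes(self) -> list[SNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def postorder(self) -> list[SNode]:
        out: list[SNode] = []

        def walk(n: SNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def tips(self) -> list[SNode]:
        return [n for n in self.nodes() if not n.children]

    def samples(self) -> list[SNode]:
        """All sampled nodes: extant tips, fossil tips and sampled ancestors."""
        return [n for n in self.nodes() if n.is_sample]

    def age(self, node: SNode) -> float:
        return self.present - node.time

    def edge_length(self, node: SNode) -> float:
        return 0.0 if node.parent is None else node.time - node.parent.time

    def total_length(self) -> float:
        return sum(self.edge_length(n) for n in self.nodes())

    @property
    def root_age(self) -> float:
        return self.age(self.root)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return all(abs(self.age(t)) <= tol for t in self.tips())

    def state_frequencies(self, trait: str) -> tuple[float, float]:
        """Frequency of each state among the sampled nodes of this view."""
        states = [n.states[trait] for n in self.samples()]
        n1 = sum(states)
        return (1 - n1 / len(states), n1 / len(states))

    def stamp_states(self, tree: CompleteTree, trait: str) -> None:
        """(Re-)evaluate a trait's states at every sample node."""
        for n in self.samples():
            t = min(n.time, tree.end_time(n.lineage))
            n.states[trait] = tree.state_at(trait, n.lineage, t)


# ---------------------------------------------------------------------------
# Construction of the observable views
# ---------------------------------------------------------------------------


def _build_views(
    tree: CompleteTree, occurrences: list[FossilOccurrence], view: str
) -> SampledTree:
    """Shared surgery: build the complete event graph, prune, suppress."""
    children: dict[int, list[int]] = {k: [] for k in range(tree.n_lineages)}
    for k in range(tree.n_lineages):
        p = tree.parent[k]
        if p >= 0:
            children[p].append(k)
    occs_by_lin: dict[int, list[FossilOccurrence]] = {}
    for o in occurrences:
        if not 0 <= o.lineage < tree.n_lineages:
            raise ValueError(f"occurrence references unknown lineage {o.lineage}")
        if not tree.birth[o.lineage] <= o.time <= tree.end_time(o.lineage):
            raise ValueError(
                f"occurrence at t={o.time} outside lifespan of lineage {o.lineage}"
            )
        occs_by_lin.setdefault(o.lineage, []).append(o)

    fossil_counter = [0]

    def build_lineage(k: int) -> SNode | None:
        """Chain of events along lineage k, already pruned to sampled parts."""
        events: list[tuple[float, str, object]] = []
        for c in children[k]:
            events.append((tree.birth[c], "spec", c))
        for o in occs_by_lin.get(k, []):
            events.append((o.time, "fossil", o))
        events.sort(key=lambda e: e[0])

        # terminal sample of the lineage itself
        terminal: SNode | None = None
        if tree.is_extant(k):
            terminal = SNode(f"t{k}", tree.stop_time, EXTANT, lineage=k)

        # walk events from the youngest backwards, keeping only the part of
        # the chain that leads to some sample
        head: SNode | None = terminal
        for t, kind, payload in reversed(events):
            if kind == "spec":
                sub = build_lineage(payload)
                if sub is None and head is None:
                    continue
                if sub is None:
                    continue  # unsampled side branch: no node needed
                if head is None:
                    head = sub  # lineage's own future is unsampled; child takes over
                else:
                    node = SNode(None, t, INTERNAL, lineage=k)
                    node.add(head)
                    node.add(sub)
                    head = node
            else:  # fossil
                o: FossilOccurrence = payload
                fossil_counter[0] += 1
                kind_ = SAMPLED_ANCESTOR if head is not None else FOSSIL_TIP
                node = SNode(f"f{o.lineage}_{fossil_counter[0]}", t, kind_, lineage=k, states=o.states)
                if head is not None:
                    node.add(head)
                head = node
        return head

    root = build_lineage(0)
    if root is None:
        raise ValueError("no sampled material: cannot form a tree")
    n_tips = sum(1 for n in _iter(root) if not n.children)
    if n_tips < 2:
        raise ValueError("fewer than 2 tips after pruning: cannot form a tree")
    st = SampledTree(root=root, present=tree.stop_time, view=view)
    _relabel_internal(st)
    for trait in tree.traits:
        st.stamp_states(tree, trait)
    return st


def _iter(root: SNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _relabel_internal(st: SampledTree) -> None:
    i = 0
    for n in st.postorder():
        if n.kind == INTERNAL:
            n.label = f"n{i}"
            i += 1


def prune_to_extant(tree: CompleteTree) -> SampledTree:
    """The ultrametric extant-species view of a complete tree."""
    if tree.n_extant < 2:
        raise ValueError("need >= 2 extant lineages to form an extant tree")
    return _build_views(tree, [], "extant")


def build_fbd_tree(
    tree: CompleteTree, occurrences: list[FossilOccurrence]
) -> SampledTree:
    """The FBD view: extant tips plus fossil tips and sampled ancestors."""
    return _build_views(tree, occurrences, "fbd")


def strip_fossils(fbd: SampledTree) -> SampledTree:
    """Drop fossil samples from an FBD view, recovering the extant view.

    Fossil tips are removed, sampled ancestors suppressed, and resulting
    degree-2 internal nodes merged. Used as a consistency check against
    :func:`prune_to_extant`.
    """

    def rebuild(n: SNode) -> SNode | None:
        kids = [rebuild(c) for c in n.children]
        kids = [k for k in kids if k is not None]
        if n.kind == EXTANT:
            return _copy(n, kids)
        if n.kind in (FOSSIL_TIP, SAMPLED_ANCESTOR):
            return kids[0] if kids else None
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _copy(n, kids)

    def _copy(n: SNode, kids: list[SNode]) -> SNode:
        m = SNode(n.label, n.time, n.kind, n.lineage, n.states)
        for k in kids:
            m.add(k)
        return m

    root = rebuild(fbd.root)
    if root is None or not root.children and root.kind != EXTANT:
        raise ValueError("no extant material in FBD view")
    st = SampledTree(root=root, present=fbd.present, view="extant")
    _relabel_internal(st)
    return st
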