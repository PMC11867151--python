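"""On-disk format for simulation replicates.

A replicate directory contains plain-text files only:

* ``meta.yaml``        scenario, psi, seed, present time, rejection counts
* ``lineages.tsv``     complete-tree lineage table (parent, birth, death)
* ``traits.tsv``       trait change points (lineage, time, trait, state)
* ``occurrences.tsv``  fossil occurrences with per-trait state stamps
* ``complete.nwk``     complete tree as annotated Newick (export only)
* ``extant.nex`` / ``fbd.nex``  observable views, Newick in a NEXUS container
* ``nodes_extant.tsv`` / ``nodes_fbd.tsv``  node metadata sidecars

Sampled ancestors are written using the zero-length-branch-tip convention
(a tip with edge length 0 attached at the ancestor's position); the node
kind lives in the sidecar TSV so the Newick stays dialect-safe.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import yaml

from .fossilize import (
    EXTANT,
    FOSSIL_TIP,
    INTERNAL,
    SAMPLED_ANCESTOR,
    FossilOccurrence,
    SampledTree,
    SNode,
)
from .replicate import ReplicateDataset
from .sim import CompleteTree

__all__ = ["serialize_dataset", "read_dataset", "write_tree_nexus", "read_tree_nexus"]

_SA_SUFFIX = "@sa"


def _fmt(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# Sampled-tree <-> NEXUS
# ---------------------------------------------------------------------------


def _to_dendropy(tree: SampledTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dt = dendropy.Tree(taxon_namespace=taxa)

    def build(n: SNode, parent_dn) -> None:
        if n.kind == SAMPLED_ANCESTOR:
            # bifurcation carrying a zero-length pseudo-tip
            dn = parent_dn.new_child(edge_length=_edge(tree, n))
            dn.label = n.label
            pseudo = dn.new_child(edge_length=0.0)
            pseudo.taxon = taxa.new_taxon(label=n.label + _SA_SUFFIX)
            for c in n.children:
                build(c, dn)
        elif n.children:
            dn = parent_dn.new_child(edge_length=_edge(tree, n))
            dn.label = n.label
            for c in n.children:
                build(c, dn)
        else:
            dn = parent_dn.new_child(edge_length=_edge(tree, n))
            dn.taxon = taxa.new_taxon(label=n.label)

    root = tree.root
    if root.kind == SAMPLED_ANCESTOR:
        dt.seed_node.label = root.label
        pseudo = dt.seed_node.new_child(edge_length=0.0)
        pseudo.taxon = taxa.new_taxon(label=root.label + _SA_SUFFIX)
        for c in root.children:
            build(c, dt.seed_node)
    else:
        dt.seed_node.label = root.label
        for c in root.children:
            build(c, dt.seed_node)
    return dt


def _edge(tree: SampledTree, n: SNode) -> float:
    return tree.edge_length(n)


def write_tree_nexus(tree: SampledTree, path: Path, header: str = "") -> None:
    dt = _to_dendropy(tree)
    text = dt.as_string(
        schema="nexus",
        real_value_format_specifier=".17g",
        suppress_internal_node_labels=False,
        suppress_rooting=False,
    )
    if header:
        lines = text.splitlines()
        lines.insert(1, f"[{header}]")
        text = "\n".join(lines) + "\n"
    Path(path).write_text(text)


def _node_rows(tree: SampledTree, traits: list[str]):
    for n in tree.postorder():
        states = [str(n.states.get(t, "")) for t in traits]
        yield [
            n.label,
            n.kind,
            _fmt(tree.age(n)),
            str(n.lineage),
            _fmt(n.time),
            _fmt(tree.edge_length(n)),
        ] + states


def _write_nodes_tsv(tree: SampledTree, traits: list[str], path: Path, header: str) -> None:
    cols = ["label", "kind", "age", "lineage", "time", "edge_length"] + [
        f"state_{t}" for t in traits
    ]
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("\t".join(cols) + "\n")
        for row in _node_rows(tree, traits):
            fh.write("\t".join(row) + "\n")


def read_tree_nexus(path: Path, nodes_tsv: Path, present: float, view: str) -> SampledTree:
    dt = dendropy.Tree.get(path=str(path), schema="nexus")
    meta: dict[str, dict] = {}
    traits: list[str] = []
    with open(nodes_tsv) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if not traits and parts[0] == "label":
                traits = [c[len("state_"):] for c in parts[6:]]
                continue
            states = {
                t: int(s) for t, s in zip(traits, parts[6:]) if s != ""
            }
            meta[parts[0]] = {
                "kind": parts[1],
                "lineage": int(parts[3]),
                "time": float(parts[4]),
                "states": states,
            }

    def convert(dn) -> SNode:
        label = dn.taxon.label if dn.taxon is not None else dn.label
        kids = list(dn.child_nodes())
        # zero-length pseudo-tip marks its parent as a sampled ancestor
        pseudo = [k for k in kids if k.taxon is not None and k.taxon.label.endswith(_SA_SUFFIX)]
        if pseudo:
            label = pseudo[0].taxon.label[: -len(_SA_SUFFIX)]
            m = meta[label]
            node = SNode(label, m["time"], SAMPLED_ANCESTOR, m["lineage"], m["states"])
            for k in kids:
                if k not in pseudo:
                    node.add(convert(k))
            return node
        m = meta[label]
        node = SNode(label, m["time"], m["kind"], m["lineage"], m["states"])
        for k in kids:
            node.add(convert(k))
        return node

    root = convert(dt.seed_node)
    return SampledTree(root=root, present=present, view=view)


# ---------------------------------------------------------------------------
# Complete tree as annotated Newick (export only)
# ---------------------------------------------------------------------------


def complete_tree_newick(tree: CompleteTree) -> str:
    """Extended Newick of the complete tree; extinct tips carry a comment."""
    children: dict[int, list[int]] = {k: [] for k in range(tree.n_lineages)}
    for k in range(tree.n_lineages):
        if tree.parent[k] >= 0:
            children[tree.parent[k]].append(k)

    def lineage_str(k: int, start: float) -> str:
        # events along lineage k after `start`: speciations, then terminal
        ev = sorted(children[k], key=lambda c: tree.birth[c])
        ev = [c for c in ev if tree.birth[c] > start]
        if ev:
            c = ev[0]
            t = tree.birth[c]
            left = lineage_str(k, t)
            right = lineage_str(c, t)
            return f"({left},{right}):{_fmt(t - start)}"
        t_end = tree.end_time(k)
        tag = "" if tree.is_extant(k) else "[&extinct=1]"
        return f"L{k}{tag}:{_fmt(t_end - start)}"

    return lineage_str(0, 0.0) + ";"


# ---------------------------------------------------------------------------
# Replicate directory
# ---------------------------------------------------------------------------


def serialize_dataset(
    dataset: ReplicateDataset, directory: Path, seed: int | None = None
) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    header = f"scenario={dataset.scenario_id} psi={dataset.psi:g} seed={seed}"
    traits = dataset.trait_names
    tree = dataset.complete

    meta = {
        "scenario": dataset.scenario_id,
        "psi": dataset.psi,
        "n_extant_stop": dataset.n_extant_stop,
        "seed": seed,
        "present": float(tree.stop_time),
        "traits": traits,
        "rejections": dataset.rejections,
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    with open(d / "lineages.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("lineage\tparent\tbirth\tdeath\n")
        for k in range(tree.n_lineages):
            death = "" if tree.is_extant(k) else _fmt(tree.death[k])
            fh.write(f"{k}\t{tree.parent[k]}\t{_fmt(tree.birth[k])}\t{death}\n")

    with open(d / "traits.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("lineage\ttime\ttrait\tstate\n")
        for name in traits:
            for k, traj in enumerate(tree.traits[name]):
                for t, s in traj:
                    fh.write(f"{k}\t{_fmt(t)}\t{name}\t{s}\n")

    with open(d / "occurrences.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        cols = ["lineage", "time"] + [f"state_{t}" for t in traits]
        fh.write("\t".join(cols) + "\n")
        for o in dataset.occurrences:
            row = [str(o.lineage), _fmt(o.time)] + [str(o.states[t]) for t in traits]
            fh.write("\t".join(row) + "\n")

    (d / "complete.nwk").write_text(f"[{header}]\n" + complete_tree_newick(tree) + "\n")

    write_tree_nexus(dataset.extant, d / "extant.nex", header)
    _write_nodes_tsv(dataset.extant, traits, d / "nodes_extant.tsv", header)
    if dataset.fbd is not None:
        write_tree_nexus(dataset.fbd, d / "fbd.nex", header)
        _write_nodes_tsv(dataset.fbd, traits, d / "nodes_fbd.tsv", header)


def read_dataset(directory: Path) -> ReplicateDataset:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    present = float(meta["present"])
    traits: list[str] = meta["traits"]

    parent, birth, death = [], [], []
    with open(d / "lineages.tsv") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("lineage\t"):
                continue
            _, p, b, dd = line.rstrip("\n").split("\t")
            parent.append(int(p))
            birth.append(float(b))
            death.append(float(dd) if dd else np.nan)

    trajs = {name: [[] for _ in parent] for name in traits}
    with open(d / "traits.tsv") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("lineage\t"):
                continue
            k, t, name, s = line.rstrip("\n").split("\t")
            trajs[name][int(k)].append((float(t), int(s)))
    for name in traits:
        for traj in trajs[name]:
            traj.sort(key=lambda e: e[0])

    tree = CompleteTree(parent, birth, death, present, trajs)

    occurrences: list[FossilOccurrence] = []
    with open(d / "occurrences.tsv") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("lineage\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            states = {t: int(s) for t, s in zip(traits, parts[2:])}
            occurrences.append(FossilOccurrence(int(parts[0]), float(parts[1]), states))

    extant = read_tree_nexus(d / "extant.nex", d / "nodes_extant.tsv", present, "extant")
    fbd = None
    if (d / "fbd.nex").exists():
        fbd = read_tree_nexus(d / "fbd.nex", d / "nodes_fbd.tsv", present, "fbd")

    return ReplicateDataset(
        scenario_id=meta["scenario"],
        psi=float(meta["psi"]),
        n_extant_stop=int(meta["n_extant_stop"]),
        complete=tree,
        occurrences=occurrences,
        extant=extant,
        fbd=fbd,
        rejections=dict(meta.get("rejections") or {}),
    )
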