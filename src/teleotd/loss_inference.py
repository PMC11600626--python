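"""Counting independent character losses (or gains) on a labelled phylogeny.

Given a rooted tree and binary presence/absence leaf labels, the inference
finds the maximal monophyletic clades whose labelled leaves all carry the
target state and maps each to its most recent common ancestor. The number
of such clades is the parsimony-style count of independent events — a
*lower bound*: losses on sister branches, or separated only by unlabelled
leaves, merge into one clade. The same operation counts domain losses
(target state ``absent``) and trait origins (target state ``present``).

Leaves labelled ``unknown`` are transparent: they neither break nor
establish uniformity, but are reported per clade, so low-quality assemblies
do not split otherwise-uniform clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AbsenceClade",
    "EventReport",
    "maximal_absence_clades",
    "count_independent_events",
    "mrca",
    "read_labels",
]

STATES = {"present", "absent", "unknown"}


@dataclass
class AbsenceClade:
    """A maximal monophyletic group whose labelled leaves share the target
    state; the MRCA's parent clade contains at least one other-state leaf."""

    mrca: dendropy.Node
    leaves: tuple[str, ...]          # labelled target-state leaves
    unknown_leaves: tuple[str, ...]  # unlabelled/unknown leaves inside

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass
class EventReport:
    clades: list[AbsenceClade]
    n_events: int
    mixed_nodes: int  # internal nodes whose labelled leaves mix both states

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clade": range(1, len(self.clades) + 1),
                "n_leaves": [c.size for c in self.clades],
                "members": [";".join(c.leaves) for c in self.clades],
                "unknown_members": [
                    ";".join(c.unknown_leaves) for c in self.clades
                ],
            }
        )


def _check_labels(
    tree: dendropy.Tree, labels: dict[str, str]
) -> None:
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(labels) - leaf_names
    if missing:
        raise ValueError(
            f"labelled leaves not in tree: {sorted(missing)}"
        )
    bad = {v for v in labels.values()} - STATES
    if bad:
        raise ValueError(f"unknown label states: {sorted(bad)}")


def maximal_absence_clades(
    tree: dendropy.Tree,
    labels: dict[str, str],
    target_state: str = "absent",
) -> list[AbsenceClade]:
    """Maximal clades whose labelled leaves are uniformly ``target_state``.

    A post-order pass marks each node uniform iff all its labelled
    descendants carry the target state (``unknown`` leaves are transparent
    and clades must contain at least one labelled target leaf); a clade is
    reported iff it is uniform and its parent is not. Singleton leaves
    count. Requires a rooted tree — maximality is undefined without a root.
    """
    if target_state not in {"present", "absent"}:
        raise ValueError("target_state must be 'present' or 'absent'")
    if not tree.is_rooted:
        raise ValueError("loss inference requires a rooted tree")
    _check_labels(tree, labels)
    other = "present" if target_state == "absent" else "absent"
    informative = [v for v in labels.values() if v != "unknown"]
    if not informative:
        raise ValueError("no leaves with known state")

    n_target: dict[dendropy.Node, int] = {}
    n_other: dict[dendropy.Node, int] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            state = labels.get(nd.taxon.label, "unknown")
            n_target[nd] = int(state == target_state)
            n_other[nd] = int(state == other)
        else:
            n_target[nd] = sum(n_target[c] for c in nd.child_nodes())
            n_other[nd] = sum(n_other[c] for c in nd.child_nodes())

    def uniform(nd: dendropy.Node) -> bool:
        return n_target[nd] >= 1 and n_other[nd] == 0

    clades: list[AbsenceClade] = []
    for nd in tree.preorder_node_iter():
        if not uniform(nd):
            continue
        parent = nd.parent_node
        if parent is not None and uniform(parent):
            continue
        members: list[str] = []
        unknowns: list[str] = []
        for lf in nd.leaf_iter():
            state = labels.get(lf.taxon.label, "unknown")
            if state == target_state:
                members.append(lf.taxon.label)
            else:
                unknowns.append(lf.taxon.label)
        clades.append(
            AbsenceClade(
                mrca=nd, leaves=tuple(members),
                unknown_leaves=tuple(unknowns),
            )
        )
    return clades


def event_report(
    tree: dendropy.Tree,
    labels: dict[str, str],
    target_state: str = "absent",
) -> EventReport:
    """Full report: clades, count, and mixed internal nodes."""
    clades = maximal_absence_clades(tree, labels, target_state)
    mixed = 0
    for nd in tree.preorder_internal_node_iter():
        states = {
            labels.get(lf.taxon.label, "unknown")
            for lf in nd.leaf_iter()
        } - {"unknown"}
        if len(states) == 2:
            mixed += 1
    return EventReport(clades=clades, n_events=len(clades),
                       mixed_nodes=mixed)


def count_independent_events(
    tree: dendropy.Tree,
    labels: dict[str, str],
    target_state: str = "absent",
) -> int:
    """Number of maximal uniform-state clades (independent events)."""
    return len(maximal_absence_clades(tree, labels, target_state))


def mrca(tree: dendropy.Tree, leaf_labels) -> dendropy.Node:
    """Lowest node ancestral to all given leaves (the leaf itself for a
    singleton set)."""
    leaf_labels = list(leaf_labels)
    if not leaf_labels:
        raise ValueError("empty leaf set")
    by_name = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter()
    }
    unknown = set(leaf_labels) - set(by_name)
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(leaf_labels) == 1:
        return by_name[leaf_labels[0]]
    node = tree.mrca(taxon_labels=leaf_labels)
    if node is None:
        raise ValueError("no common ancestor found")
    return node


def read_labels(path: str) -> dict[str, str]:
    """Read a two-column (leaf, state) TSV into a label mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["leaf", "state"],
                     comment="#")
    labels = dict(zip(df["leaf"].astype(str), df["state"].astype(str)))
    bad = set(labels.values()) - STATES
    if bad:
        raise ValueError(f"unknown label states in {path}: {sorted(bad)}")
    return labels
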