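"""Branch-length-based phylogenetic diversity (PD) and PD gain.

PD of a tip set is the sum of edge lengths of the minimal spanning subtree
connecting the tips, rooted at the set's most recent common ancestor; the
edge above the MRCA is excluded by default (Faith-PD, unrooted-within-clade
convention) and can be included with ``include_stem=True``. PD gain
measures how much new genomes expand the diversity of a reference set,
reported both absolutely and as percent growth over the reference PD.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import dendropy


class NonMonophyleticError(ValueError):
    """A tip set expected to be a clade contains or excludes intruders."""


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None:
            raise ValueError("tree has unlabeled tips")
        if label in out:
            raise ValueError(f"duplicate tip label {label!r}")
        out[label] = leaf
    return out


def _resolve_tips(
    tree: dendropy.Tree, tipset: Iterable[str]
) -> list[dendropy.Node]:
    tips = list(tipset)
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tips in input: {dup}")
    leaves = _leaf_map(tree)
    missing = sorted(set(tips) - set(leaves))
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    return [leaves[t] for t in tips]


def _mrca(nodes: Sequence[dendropy.Node]) -> dendropy.Node:
    paths = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path[::-1])  # root -> node
    mrca = None
    for ancestors in zip(*paths):
        first = ancestors[0]
        if all(a is first for a in ancestors):
            mrca = first
        else:
            break
    assert mrca is not None
    return mrca


def pd(
    tree: dendropy.Tree,
    tipset: Iterable[str],
    include_stem: bool = False,
) -> float:
    """Phylogenetic diversity of ``tipset`` (substitutions/site).

    A single tip has zero spanning subtree; it returns 0 with a warning
    (stem length with ``include_stem``).
    """
    nodes = _resolve_tips(tree, tipset)
    if not nodes:
        raise ValueError("empty tip set")
    mrca = _mrca(nodes)
    if len(nodes) == 1:
        warnings.warn("PD of a single tip is 0 (no spanning subtree)")
        return float(mrca.edge.length or 0.0) if include_stem else 0.0
    total = 0.0
    visited: set[int] = set()
    for node in nodes:
        cur = node
        while cur is not mrca:
            if id(cur) in visited:
                break
            visited.add(id(cur))
            total += float(cur.edge.length or 0.0)
            cur = cur.parent_node
    if include_stem:
        total += float(mrca.edge.length or 0.0)
    return total


#: spelled-out alias (``pd`` mirrors the field's PD shorthand)
phylogenetic_diversity = pd


def pd_gain(
    tree: dendropy.Tree,
    reference_tips: Iterable[str],
    added_tips: Iterable[str],
    include_stem: bool = False,
) -> tuple[float, float]:
    """(gain, pct_gain): the PD increase from adding tips to a reference set.

    ``pct_gain`` is growth relative to the reference PD. The reference must
    be non-empty and disjoint from the added set; an empty added set yields
    (0, 0).
    """
    reference = list(reference_tips)
    added = list(added_tips)
    if not reference:
        raise ValueError("empty reference tip set")
    overlap = set(reference) & set(added)
    if overlap:
        raise ValueError(f"reference and added tips overlap: {sorted(overlap)[:5]}")
    if not added:
        return 0.0, 0.0
    pd_ref = pd(tree, reference, include_stem=include_stem)
    pd_total = pd(tree, reference + added, include_stem=include_stem)
    gain = pd_total - pd_ref
    pct = 100.0 * gain / pd_ref if pd_ref > 0 else float("nan")
    return gain, pct


def stem_branch_length(tree: dendropy.Tree, clade_tips: Iterable[str]) -> float:
    """Length of the edge subtending the MRCA of a monophyletic tip set.

    Raises :class:`NonMonophyleticError` naming the intruding tips when the
    set is not a clade. For the whole tree this is the root edge length
    (0 when absent).
    """
    nodes = _resolve_tips(tree, clade_tips)
    if not nodes:
        raise ValueError("empty clade tip set")
    mrca = _mrca(nodes)
    clade = {t for t in clade_tips}
    under = {
        leaf.taxon.label for leaf in mrca.leaf_iter()
    }
    intruders = sorted(under - clade)
    if intruders:
        raise NonMonophyleticError(
            f"tip set is not monophyletic; MRCA subtree also contains "
            f"{intruders[:10]}"
        )
    return float(mrca.edge.length or 0.0)
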