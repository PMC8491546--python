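"""Rooted taxonomy with rank-aware lineage and lowest-common-ancestor queries.

The tree follows the NCBI convention: every node stores (parent, rank, name),
the root is its own parent, and lineages may interleave "no rank" nodes at any
depth.  Ranks are free strings drawn from the NCBI rank vocabulary plus
"no rank"; the five ranks the pipeline aggregates at are listed in
:data:`AGGREGATION_RANKS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

#: Ranks at which contig lineages and abundance tables are aggregated,
#: ordered from shallow to deep.
AGGREGATION_RANKS = ("phylum", "class", "order", "family", "genus")

#: Rank vocabulary accepted by rank-aware queries.
KNOWN_RANKS = frozenset(
    {
        "superkingdom",
        "kingdom",
        "phylum",
        "subphylum",
        "class",
        "subclass",
        "order",
        "suborder",
        "family",
        "subfamily",
        "genus",
        "subgenus",
        "species",
        "subspecies",
        "strain",
        "no rank",
    }
)


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: map taxid -> node, with the root its own parent."""

    nodes: Dict[int, TaxonNode] = field(default_factory=dict)
    root: int = 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[int, int, str]],
        names: Optional[Dict[int, str]] = None,
    ) -> "TaxonomyTree":
        """Build a tree from (taxid, parent_taxid, rank) triples.

        The root is the unique node that is its own parent.  Raises
        ``ValueError`` on duplicate taxids, orphan parents, missing root,
        or cycles.
        """
        names = names or {}
        nodes: Dict[int, TaxonNode] = {}
        root: Optional[int] = None
        for taxid, parent, rank in edges:
            if taxid in nodes:
                raise ValueError(f"duplicate taxid {taxid}")
            nodes[taxid] = TaxonNode(taxid, parent, rank, names.get(taxid, str(taxid)))
            if taxid == parent:
                if root is not None and root != taxid:
                    raise ValueError(f"multiple roots: {root} and {taxid}")
                root = taxid
        if root is None:
            raise ValueError("no root node (a node that is its own parent)")
        orphans = sorted(
            t for t, n in nodes.items() if n.parent not in nodes
        )
        if orphans:
            raise ValueError(f"orphan taxids (parent absent): {orphans}")
        tree = cls(nodes=nodes, root=root)
        tree._check_acyclic()
        return tree

    def _check_acyclic(self) -> None:
        safe: set[int] = set()
        for start in self.nodes:
            path: List[int] = []
            on_path: set[int] = set()
            t = start
            while t not in safe:
                if t in on_path:
                    raise ValueError(f"cycle in taxonomy involving taxid {t}")
                path.append(t)
                on_path.add(t)
                parent = self.nodes[t].parent
                if parent == t:  # reached root
                    break
                t = parent
            safe.update(path)

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid].parent

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name


def lineage(tree: TaxonomyTree, taxid: int) -> List[Tuple[int, str]]:
    """Root-to-taxid path as (taxid, rank) pairs.

    The first element is the root, the last the query itself.
    """
    if taxid not in tree:
        raise KeyError(f"unknown taxid {taxid}")
    path = []
    t = taxid
    while True:
        node = tree.nodes[t]
        path.append((t, node.rank))
        if node.parent == t:
            break
        t = node.parent
    path.reverse()
    return path


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty set of taxids.

    Multiplicity is ignored: the LCA of a multiset equals the LCA of its
    support.
    """
    taxid_set = set(taxids)
    if not taxid_set:
        raise ValueError("lca of an empty taxid set is undefined")
    for t in taxid_set:
        if t not in tree:
            raise KeyError(f"unknown taxid {t}")
    it = iter(taxid_set)
    common = [t for t, _ in lineage(tree, next(it))]
    for t in it:
        path = [x for x, _ in lineage(tree, t)]
        n = min(len(common), len(path))
        k = 0
        while k < n and common[k] == path[k]:
            k += 1
        common = common[:k]
    return common[-1]


def ancestor_at_rank(tree: TaxonomyTree, taxid: int, rank: str) -> Optional[int]:
    """The unique ancestor-or-self of ``taxid`` with the given rank, or None.

    "no rank" nodes are transparent: they are walked through, never returned.
    """
    if rank not in KNOWN_RANKS or rank == "no rank":
        raise ValueError(f"unknown or unusable rank {rank!r}")
    if taxid not in tree:
        raise KeyError(f"unknown taxid {taxid}")
    t = taxid
    while True:
        node = tree.nodes[t]
        if node.rank == rank:
            return t
        if node.parent == t:
            return None
        t = node.parent


def lineage_at_ranks(
    tree: TaxonomyTree, taxid: int, ranks: Iterable[str] = AGGREGATION_RANKS
) -> Dict[str, int]:
    """Map each requested rank to the lineage member with that rank (if any)."""
    out: Dict[str, int] = {}
    by_rank = {r: t for t, r in lineage(tree, taxid)}
    for r in ranks:
        if r in by_rank:
            out[r] = by_rank[r]
    return out
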