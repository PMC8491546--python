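"""Shared fixtures: small taxonomies and alignment-hit builders."""

import numpy as np
import pytest

from forefield.formats_io import AlignmentHit
from forefield.taxonomy import TaxonomyTree


@pytest.fixture
def small_tree() -> TaxonomyTree:
    """root(1) -> Bacteria(2) -> P1(3)/P2(4); P1 -> F(5) -> gA(6), gB(7);
    P2 -> gC(8).  Ranks: phylum, family, genus."""
    edges = [
        (1, 1, "no rank"),
        (2, 1, "superkingdom"),
        (3, 2, "phylum"),
        (4, 2, "phylum"),
        (5, 3, "family"),
        (6, 5, "genus"),
        (7, 5, "genus"),
        (8, 4, "genus"),
    ]
    names = {1: "root", 2: "Bacteria", 3: "P1", 4: "P2", 5: "F", 6: "gA", 7: "gB", 8: "gC"}
    return TaxonomyTree.from_edges(edges, names)


def random_tree(rng: np.random.Generator, n: int) -> TaxonomyTree:
    """Random rooted tree: node i's parent is uniform over earlier nodes."""
    ranks = ["no rank", "phylum", "class", "order", "family", "genus"]
    edges = [(1, 1, "no rank")]
    for i in range(2, n + 1):
        parent = int(rng.integers(1, i))
        edges.append((i, parent, ranks[int(rng.integers(0, len(ranks)))]))
    return TaxonomyTree.from_edges(edges)


def make_hit(
    contig="c1",
    start=0,
    end=100,
    strand="+",
    acc="a1",
    taxid=6,
    bitscore=100.0,
    label="geneX",
    go=(),
    identity=90.0,
):
    return AlignmentHit(
        query_id=contig,
        q_start=start,
        q_end=end,
        strand=strand,
        subject_acc=acc,
        subject_taxid=taxid,
        pct_identity=identity,
        evalue=1e-30,
        bitscore=bitscore,
        gene_label=label,
        go_terms=frozenset(go),
    )


from hypothesis import settings as _settings

_settings.register_profile("deterministic", derandomize=True, deadline=None)
_settings.load_profile("deterministic")
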