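"""Contig annotation from ranged protein alignments.

Four steps turn a contig's alignment hits into an annotation:

1. :func:`build_regions` — merge overlapping/nearby same-strand hits into
   gene-coding regions; each region's label comes from its best-bitscore hit
   and its taxon from a lowest-common-ancestor over all hits scoring within a
   configurable fraction of the best (mirroring an aligner's top-percentage
   retention window).
2. :func:`detect_chimera` — flag mis-assembled contigs whose adjacent regions
   disagree at a high rank (default phylum) with sufficient flanking support,
   and place split points in the inter-region gaps.
3. :func:`split_contig` — cut a chimeric contig into children, reassigning
   (and where necessary truncating) its regions.
4. :func:`assign_contig_taxonomy` — length-weighted strict-majority vote per
   rank, giving a possibly partial contig lineage (classified at phylum,
   unclassified at genus is an expected outcome).

All tie-breaks are deterministic (lexicographic) so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formats_io import AlignmentHit
from .taxonomy import AGGREGATION_RANKS, TaxonomyTree, ancestor_at_rank, lca

DEFAULT_MERGE_GAP = 30
DEFAULT_TOP_FRACTION = 0.1
DEFAULT_CONFLICT_RANK = "phylum"
DEFAULT_MIN_FLANK = 1000


@dataclass
class GeneRegion:
    """A gene-coding region on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_label: str
    go_terms: frozenset = frozenset()
    region_taxid: Optional[int] = None
    support: List[int] = field(default_factory=list)  # indices of contributing hits
    best_bitscore: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ContigAnnotation:
    contig_id: str
    length: int
    regions: List[GeneRegion]
    contig_lineage: Dict[str, int] = field(default_factory=dict)
    chimeric: bool = False
    split_points: List[int] = field(default_factory=list)


@dataclass
class ChimeraSplitResult:
    parent_id: str
    children: List[Tuple[str, Tuple[int, int]]]  # (child_id, parent interval)
    child_regions: Dict[str, List[GeneRegion]] = field(default_factory=dict)


def build_regions(
    hits: Sequence[AlignmentHit],
    merge_gap: int = DEFAULT_MERGE_GAP,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    tree: Optional[TaxonomyTree] = None,
) -> List[GeneRegion]:
    """Merge a contig's hits into gene-coding regions.

    Same-strand hits whose intervals overlap or lie within ``merge_gap``
    bases are merged; the region interval is the hull of its hits.  The
    region's ``gene_label`` and GO terms come from the max-bitscore hit
    (ties broken by lexicographically smallest label), and ``region_taxid``
    is the LCA over hits with bitscore >= (1 - top_fraction) * best within
    the region (hits without a resolved taxid are skipped for taxonomy but
    still support the region).
    """
    if not hits:
        return []
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    contig_ids = {h.query_id for h in hits}
    if len(contig_ids) > 1:
        raise ValueError(f"hits from mixed contigs: {sorted(contig_ids)}")
    contig_id = hits[0].query_id

    regions: List[GeneRegion] = []
    for strand in ("+", "-"):
        strand_hits = sorted(
            ((i, h) for i, h in enumerate(hits) if h.strand == strand),
            key=lambda ih: (ih[1].q_start, ih[1].q_end),
        )
        cluster: List[Tuple[int, AlignmentHit]] = []
        cluster_end = None
        for i, h in strand_hits:
            if cluster and h.q_start > cluster_end + merge_gap:
                regions.append(_finalize_region(contig_id, strand, cluster, top_fraction, tree))
                cluster = []
                cluster_end = None
            cluster.append((i, h))
            cluster_end = h.q_end if cluster_end is None else max(cluster_end, h.q_end)
        if cluster:
            regions.append(_finalize_region(contig_id, strand, cluster, top_fraction, tree))
    regions.sort(key=lambda r: (r.start, r.end, r.strand))
    return regions


def _finalize_region(
    contig_id: str,
    strand: str,
    cluster: List[Tuple[int, "AlignmentHit"]],
    top_fraction: float,
    tree: Optional[TaxonomyTree],
) -> GeneRegion:
    start = min(h.q_start for _, h in cluster)
    end = max(h.q_end for _, h in cluster)
    best = max(h.bitscore for _, h in cluster)
    # deterministic label: among max-bitscore hits, smallest gene_label
    best_hits = [h for _, h in cluster if h.bitscore == best]
    label_hit = min(best_hits, key=lambda h: h.gene_label)
    threshold = (1.0 - top_fraction) * best
    lca_taxids = {
        h.subject_taxid
        for _, h in cluster
        if h.subject_taxid is not None and h.bitscore >= threshold
    }
    taxid = lca(tree, lca_taxids) if (tree is not None and lca_taxids) else None
    return GeneRegion(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        gene_label=label_hit.gene_label,
        go_terms=frozenset(label_hit.go_terms),
        region_taxid=taxid,
        support=sorted(i for i, _ in cluster),
        best_bitscore=best,
    )


def detect_chimera(
    contig_length: int,
    regions: Sequence[GeneRegion],
    tree: TaxonomyTree,
    conflict_rank: str = DEFAULT_CONFLICT_RANK,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> List[int]:
    """Split points for a chimeric contig (empty list = not chimeric).

    Adjacent runs of regions sharing an ancestor at ``conflict_rank`` are
    compared; a split point is emitted between two runs with different
    ancestors when each run spans at least ``min_flank`` bases.  Regions
    unresolved at the rank are transparent.  The split coordinate is the
    floor midpoint of the inter-run gap (the shared boundary if the runs
    abut).
    """
    resolved: List[Tuple[GeneRegion, int]] = []
    for r in sorted(regions, key=lambda r: r.start):
        if r.region_taxid is None:
            continue
        anc = ancestor_at_rank(tree, r.region_taxid, conflict_rank)
        if anc is not None:
            resolved.append((r, anc))
    if len(resolved) < 2:
        return []
    # group into maximal runs of the same rank-ancestor
    runs: List[Tuple[int, int, int]] = []  # (ancestor, span_start, span_end)
    cur_anc = resolved[0][1]
    cur_start = resolved[0][0].start
    cur_end = resolved[0][0].end
    for r, anc in resolved[1:]:
        if anc == cur_anc:
            cur_end = max(cur_end, r.end)
        else:
            runs.append((cur_anc, cur_start, cur_end))
            cur_anc, cur_start, cur_end = anc, r.start, r.end
    runs.append((cur_anc, cur_start, cur_end))

    splits: List[int] = []
    for (anc_l, s_l, e_l), (anc_r, s_r, e_r) in zip(runs, runs[1:]):
        if e_l - s_l >= min_flank and e_r - s_r >= min_flank:
            point = (e_l + s_r) // 2
            if 0 < point < contig_length:
                splits.append(point)
    return splits


def split_contig(
    contig_id: str,
    contig_length: int,
    split_points: Sequence[int],
    regions: Sequence[GeneRegion] = (),
) -> ChimeraSplitResult:
    """Partition a contig at the given points into children ``<id>_1 ...``.

    Children tile ``[0, length)`` so total child length equals the parent
    length.  Regions move to the child containing them, in child-local
    coordinates; a region straddling a split point is truncated at the point
    on both sides (each child keeps its part).
    """
    pts = sorted(split_points)
    for p in pts:
        if not 0 < p < contig_length:
            raise ValueError(f"split point {p} outside (0, {contig_length})")
    if len(set(pts)) != len(pts):
        raise ValueError("duplicate split points")
    bounds = [0] + pts + [contig_length]
    children: List[Tuple[str, Tuple[int, int]]] = []
    child_regions: Dict[str, List[GeneRegion]] = {}
    for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        child_id = contig_id if not pts else f"{contig_id}_{k}"
        children.append((child_id, (lo, hi)))
        child_regions[child_id] = []
    for r in regions:
        for child_id, (lo, hi) in children:
            s = max(r.start, lo)
            e = min(r.end, hi)
            if s < e:
                child_regions[child_id].append(
                    replace(r, contig_id=child_id, start=s - lo, end=e - lo)
                )
    return ChimeraSplitResult(contig_id, children, child_regions)


def assign_contig_taxonomy(
    regions: Sequence[GeneRegion],
    tree: TaxonomyTree,
    ranks: Sequence[str] = AGGREGATION_RANKS,
    majority: float = 0.5,
) -> Dict[str, int]:
    """Length-weighted strict-majority contig lineage, rank by rank.

    At each rank the candidate ancestors of the regions' taxa are weighted by
    region length; the winner is assigned only if its weight exceeds
    ``majority`` of the taxonomically resolved length at that rank.
    Assignments are nested-consistent: a deeper assignment is dropped unless
    every shallower assigned rank is one of its own ancestors.
    """
    assigned: Dict[str, int] = {}
    for rank in ranks:
        weights: Dict[int, float] = {}
        for r in regions:
            if r.region_taxid is None:
                continue
            anc = ancestor_at_rank(tree, r.region_taxid, rank)
            if anc is not None:
                weights[anc] = weights.get(anc, 0.0) + r.length
        total = sum(weights.values())
        if total == 0:
            continue
        # deterministic: max weight, ties to smallest taxid (never a winner
        # under strict majority anyway)
        winner = min(weights, key=lambda t: (-weights[t], t))
        if weights[winner] <= majority * total:
            continue
        consistent = True
        for higher_rank, higher_taxid in assigned.items():
            if ancestor_at_rank(tree, winner, higher_rank) != higher_taxid:
                consistent = False
                break
        if consistent:
            assigned[rank] = winner
    return assigned


def annotate_contig(
    contig_id: str,
    contig_length: int,
    hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    merge_gap: int = DEFAULT_MERGE_GAP,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    conflict_rank: str = DEFAULT_CONFLICT_RANK,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> Tuple[List[ContigAnnotation], Optional[ChimeraSplitResult]]:
    """Full per-contig annotation: regions, chimera check, split, lineage.

    Returns (annotations, split_result): one annotation for a clean contig
    (split_result None), or one per child for a chimeric one (child ids
    ``<parent>_1``, ``<parent>_2``, ...).
    """
    regions = build_regions(hits, merge_gap=merge_gap, top_fraction=top_fraction, tree=tree)
    splits = detect_chimera(contig_length, regions, tree, conflict_rank, min_flank)
    if not splits:
        lineage = assign_contig_taxonomy(regions, tree)
        return (
            [ContigAnnotation(contig_id, contig_length, regions, lineage, False, [])],
            None,
        )
    result = split_contig(contig_id, contig_length, splits, regions)
    annotations = []
    for child_id, (lo, hi) in result.children:
        child_regs = result.child_regions[child_id]
        lineage = assign_contig_taxonomy(child_regs, tree)
        annotations.append(
            ContigAnnotation(child_id, hi - lo, child_regs, lineage, True, list(splits))
        )
    return annotations, result


def annotate_assembly(
    contig_lengths: Dict[str, int],
    hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    **params,
) -> Tuple[Dict[str, ContigAnnotation], Dict[str, ChimeraSplitResult]]:
    """Annotate every contig of an assembly.

    Returns (annotations keyed by post-split contig id, chimera split results
    keyed by parent id).  Contigs without hits get an empty annotation.
    """
    by_contig: Dict[str, List[AlignmentHit]] = {c: [] for c in contig_lengths}
    for h in hits:
        if h.query_id not in contig_lengths:
            raise ValueError(f"alignment hit on unknown contig {h.query_id}")
        by_contig[h.query_id].append(h)

    annotations: Dict[str, ContigAnnotation] = {}
    chimera: Dict[str, ChimeraSplitResult] = {}
    for contig_id in sorted(contig_lengths):
        length = contig_lengths[contig_id]
        anns, split_result = annotate_contig(
            contig_id, length, by_contig[contig_id], tree, **params
        )
        if split_result is not None:
            chimera[contig_id] = split_result
        for a in anns:
            annotations[a.contig_id] = a
    return annotations, chimera
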