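"""Genus-wise profiling of target gene sets along the succession.

The four default sets — nitrogenase, obcA (oxalogenesis), cyanide synthase
and siderophore synthesis/transport — are nitrogen-fixation and
rock-weathering marker genes.  A region joins a set by gene-label pattern
or GO-term membership; each selected region is tagged with its contig's
genus (or "unclassified").  Trends are reported as per-genus weighted gene
coverage per sample, and as the fraction of genera in a distance bin that
possess the set:

    genus_fraction(bin) = genera with set coverage > 0 in >= 1 sample of the
    bin / genera with any abundance > 0 in the bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .annotate import ContigAnnotation, GeneRegion
from .coverage import UNCLASSIFIED
from .formats_io import SampleMeta
from .succession_stats import bin_distance
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class GeneSetDef:
    set_name: str
    name_patterns: Tuple[str, ...] = ()
    go_ids: frozenset = frozenset()

    def __post_init__(self):
        if not self.name_patterns and not self.go_ids:
            raise ValueError(f"gene set {self.set_name!r}: no patterns and no GO ids")

    def matches(self, gene_label: str, go_terms: Iterable[str] = ()) -> bool:
        for pat in self.name_patterns:
            if re.search(pat, gene_label, flags=re.IGNORECASE):
                return True
        return bool(self.go_ids & set(go_terms))


def load_gene_sets(path: Optional[Union[str, Path]] = None) -> Dict[str, GeneSetDef]:
    """Load gene-set definitions from YAML (package defaults when no path)."""
    if path is None:
        text = resources.files("forefield.data").joinpath("gene_sets.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        out[name] = GeneSetDef(
            set_name=name,
            name_patterns=tuple(spec.get("patterns", ())),
            go_ids=frozenset(spec.get("go_ids", ())),
        )
    return out


@dataclass
class TaggedRegion:
    region: GeneRegion
    genus: str  # genus name or "unclassified"


def select_gene_regions(
    annotations: Mapping[str, ContigAnnotation],
    gene_set: GeneSetDef,
    tree: TaxonomyTree,
) -> List[TaggedRegion]:
    """All regions matching the set, each tagged with its contig's genus."""
    selected: List[TaggedRegion] = []
    for contig_id in sorted(annotations):
        ann = annotations[contig_id]
        genus_taxid = ann.contig_lineage.get("genus")
        genus = tree.name(genus_taxid) if genus_taxid is not None else UNCLASSIFIED
        for r in ann.regions:
            if gene_set.matches(r.gene_label, r.go_terms):
                selected.append(TaggedRegion(r, genus))
    return selected


def genus_region_counts(selected: Sequence[TaggedRegion]) -> Dict[str, int]:
    """Number of distinct regions per genus ("unclassified" counted apart)."""
    counts: Dict[str, int] = {}
    for t in selected:
        counts[t.genus] = counts.get(t.genus, 0) + 1
    return counts


@dataclass
class GenusGeneTrend:
    set_name: str
    coverage: pd.DataFrame       # sample x genus weighted set coverage
    n_regions: Dict[str, int]    # genus -> distinct region count
    genus_fraction: pd.Series    # bin label -> fraction (NaN when no genera)


def genus_set_coverage(
    selected: Sequence[TaggedRegion],
    contig_table: pd.DataFrame,
    sample_coverages: pd.Series,
) -> pd.DataFrame:
    """Per (genus, sample) summed weighted coverage of the set's regions.

    Each region contributes its host contig's coverage divided by the
    sample's base coverage; contributions sum over a genus's regions, so a
    genus with more set genes scores proportionally higher.
    """
    genera = sorted({t.genus for t in selected})
    out = pd.DataFrame(0.0, index=contig_table.index, columns=genera)
    for t in selected:
        if t.region.contig_id in contig_table.columns:
            out[t.genus] += contig_table[t.region.contig_id].values
    return out.div(sample_coverages.loc[out.index], axis=0)


def genus_set_trend(
    selected: Sequence[TaggedRegion],
    contig_table: pd.DataFrame,
    sample_coverages: pd.Series,
    abundance: pd.DataFrame,
    metadata: Sequence[SampleMeta],
    set_name: str = "",
) -> GenusGeneTrend:
    """Genus-level trend of a gene set along the distance bins.

    ``abundance`` is the genus-level abundance matrix used to count the
    "total genera" denominator per bin; possession means summed set coverage
    > 0 in at least one sample of the bin.  A bin with zero detected genera
    reports a missing fraction (NaN), not 0.
    """
    cov = genus_set_coverage(selected, contig_table, sample_coverages)
    n_regions = genus_region_counts(selected)

    by_bin: Dict[str, List[str]] = {}
    for m in metadata:
        if m.sample_id in cov.index:
            by_bin.setdefault(bin_distance(m.distance_m), []).append(m.sample_id)

    fractions = {}
    classified = [g for g in cov.columns if g != UNCLASSIFIED]
    for label, sample_ids in sorted(by_bin.items()):
        present = abundance.loc[sample_ids]
        total_genera = {g for g in abundance.columns if present[g].sum() > 0}
        if not total_genera:
            fractions[label] = np.nan
            continue
        possessing = {
            g for g in classified if g in total_genera and cov.loc[sample_ids, g].max() > 0
        }
        fractions[label] = len(possessing) / len(total_genera)
    return GenusGeneTrend(
        set_name=set_name,
        coverage=cov,
        n_regions=n_regions,
        genus_fraction=pd.Series(fractions, dtype=float),
    )


def reporting_filter(trend: GenusGeneTrend, min_regions: int) -> GenusGeneTrend:
    """Keep genera with strictly more than ``min_regions`` set regions."""
    if min_regions < 0:
        raise ValueError("min_regions must be >= 0")
    keep = [g for g in trend.coverage.columns if trend.n_regions.get(g, 0) > min_regions]
    return GenusGeneTrend(
        set_name=trend.set_name,
        coverage=trend.coverage[keep],
        n_regions={g: n for g, n in trend.n_regions.items() if n > min_regions},
        genus_fraction=trend.genus_fraction,
    )
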