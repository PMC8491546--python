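"""Abundance currencies: base coverage per contig, taxon, gene, and the
depth-normalized weighted gene coverage.

Base coverage of an entity is mean mapped bases per assembly base (units
"x").  Aggregation from contigs to taxa or genes is a length-weighted mean
by default (``mode="mean"``), keeping the unit interpretable; a raw
base-count sum is available (``mode="sum"``).  Weighted gene coverage
divides a gene's coverage by the whole-sample base coverage, which makes
samples of different sequencing depth comparable: doubling every read count
in a sample leaves it unchanged.

Tables are pandas DataFrames with samples as rows.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence, Union
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotate import ContigAnnotation, GeneRegion
from .taxonomy import TaxonomyTree

UNCLASSIFIED = "unclassified"

_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x800  # unmapped, secondary, supplementary


def mapped_bases_from_sam(path: Union[str, Path]) -> Dict[str, int]:
    """Total reference-aligned bases per contig from one sample's SAM/BAM.

    Unmapped, secondary and supplementary records are excluded; the aligned
    span on the reference (CIGAR M/=/X/D) is counted.
    """
    out: Dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.flag & _EXCLUDE_FLAGS:
                continue
            if rec.reference_name is None:
                continue
            span = rec.reference_length or 0
            out[rec.reference_name] = out.get(rec.reference_name, 0) + span
    return out


def contig_base_coverage(
    mapped_bases: Mapping[str, Mapping[str, int]],
    contig_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Coverage(sample, contig) = mapped bases / contig length.

    ``mapped_bases`` maps sample -> {contig -> bases} (from SAM files via
    :func:`mapped_bases_from_sam` or a precomputed TSV).  Mapping to a
    contig absent from ``contig_lengths`` is an error.
    """
    samples = sorted(mapped_bases)
    contigs = sorted(contig_lengths)
    unknown = sorted(
        {c for s in samples for c in mapped_bases[s] if c not in contig_lengths}
    )
    if unknown:
        raise ValueError(f"mappings to unknown contigs: {unknown[:10]}")
    lengths = np.array([contig_lengths[c] for c in contigs], dtype=float)
    mat = np.zeros((len(samples), len(contigs)))
    index = {c: j for j, c in enumerate(contigs)}
    for i, s in enumerate(samples):
        for c, bases in mapped_bases[s].items():
            mat[i, index[c]] = bases
    mat /= lengths
    return pd.DataFrame(mat, index=samples, columns=contigs)


def read_mapped_bases_tsv(path: Union[str, Path]) -> Dict[str, Dict[str, int]]:
    """TSV (sample, contig, mapped_bases) -> nested dict."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "contig", "mapped_bases"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: Dict[str, Dict[str, int]] = {}
    for sample, sub in df.groupby("sample"):
        out[str(sample)] = dict(zip(sub["contig"].astype(str), sub["mapped_bases"].astype(int)))
    return out


def sample_base_coverage(
    contig_table: pd.DataFrame, contig_lengths: Mapping[str, int]
) -> pd.Series:
    """Length-weighted mean contig coverage = whole-sample base coverage."""
    if contig_table.shape[1] == 0:
        raise ValueError("empty assembly: no contigs")
    lengths = np.array([contig_lengths[c] for c in contig_table.columns], dtype=float)
    total = lengths.sum()
    return pd.Series(
        (contig_table.values * lengths).sum(axis=1) / total,
        index=contig_table.index,
        name="sample_base_coverage",
    )


def _aggregate(
    contig_table: pd.DataFrame,
    groups: Mapping[str, str],
    contig_lengths: Mapping[str, int],
    mode: str,
) -> pd.DataFrame:
    """Length-weighted aggregation of contig coverage into entity columns."""
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    entities = sorted(set(groups.values()))
    cols = [c for c in contig_table.columns if c in groups]
    if not cols:
        return pd.DataFrame(0.0, index=contig_table.index, columns=entities)
    lengths = np.array([contig_lengths[c] for c in cols], dtype=float)
    weighted = contig_table[cols].values * lengths
    out = np.zeros((contig_table.shape[0], len(entities)))
    idx = {e: j for j, e in enumerate(entities)}
    denom = np.zeros(len(entities))
    for j, c in enumerate(cols):
        k = idx[groups[c]]
        out[:, k] += weighted[:, j]
        denom[k] += lengths[j]
    if mode == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, out / denom, 0.0)
    return pd.DataFrame(out, index=contig_table.index, columns=entities)


def taxon_coverage(
    contig_table: pd.DataFrame,
    annotations: Mapping[str, ContigAnnotation],
    tree: TaxonomyTree,
    rank: str,
    contig_lengths: Mapping[str, int],
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-taxon base coverage at a rank; unassigned contigs pool into
    ``unclassified``."""
    groups: Dict[str, str] = {}
    for contig_id in contig_table.columns:
        ann = annotations.get(contig_id)
        taxid = ann.contig_lineage.get(rank) if ann is not None else None
        groups[contig_id] = tree.name(taxid) if taxid is not None else UNCLASSIFIED
    return _aggregate(contig_table, groups, contig_lengths, mode)


def taxon_abundance(
    contig_table: pd.DataFrame,
    annotations: Mapping[str, ContigAnnotation],
    tree: TaxonomyTree,
    rank: str,
    contig_lengths: Mapping[str, int],
    include_unclassified: bool = False,
    mode: str = "sum",
) -> pd.DataFrame:
    """Relative abundance per taxon at a rank (rows sum to 1).

    ``unclassified`` is excluded from the denominator by default, mirroring
    diversity analyses run on classified taxa only.  A sample with zero total
    coverage keeps an all-zero row.  Abundance defaults to summed base counts
    (``mode="sum"``), under which genus abundances within a phylum add up to
    the phylum's own abundance; the length-weighted mean mode of the coverage
    tables is also accepted.
    """
    from .taxonomy import AGGREGATION_RANKS

    if rank not in AGGREGATION_RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    cov = taxon_coverage(contig_table, annotations, tree, rank, contig_lengths, mode)
    if not include_unclassified and UNCLASSIFIED in cov.columns:
        cov = cov.drop(columns=[UNCLASSIFIED])
    totals = cov.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = cov.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return ab


def gene_coverage(
    contig_table: pd.DataFrame,
    regions: Iterable[GeneRegion],
    mode: str = "mean",
) -> pd.DataFrame:
    """Per-gene base coverage: region-length-weighted mean of the host
    contigs' coverage over all regions sharing a gene label."""
    if mode not in ("mean", "sum"):
        raise ValueError("mode must be 'mean' or 'sum'")
    genes: Dict[str, list] = {}
    for r in regions:
        if r.contig_id in contig_table.columns:
            genes.setdefault(r.gene_label, []).append((r.contig_id, r.length))
    gene_names = sorted(genes)
    out = np.zeros((contig_table.shape[0], len(gene_names)))
    for j, g in enumerate(gene_names):
        total_len = 0.0
        acc = np.zeros(contig_table.shape[0])
        for contig_id, length in genes[g]:
            acc += contig_table[contig_id].values * length
            total_len += length
        out[:, j] = acc / total_len if mode == "mean" and total_len > 0 else acc
    return pd.DataFrame(out, index=contig_table.index, columns=gene_names)


def weighted_gene_coverage(
    gene_table: pd.DataFrame, sample_coverages: pd.Series
) -> pd.DataFrame:
    """Gene coverage divided by whole-sample base coverage (dimensionless)."""
    missing = [s for s in gene_table.index if s not in sample_coverages.index]
    if missing:
        raise ValueError(f"samples without sample coverage: {missing}")
    sc = sample_coverages.loc[gene_table.index]
    zero = sc[sc <= 0]
    if len(zero):
        raise ValueError(f"zero sample base coverage for: {list(zero.index)}")
    return gene_table.div(sc, axis=0)
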