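"""File-level orchestration of the annotation -> abundance -> statistics
workflow, shared by the command-line interface and the example scripts.

Each stage reads and writes plain tab-separated files so intermediate
results are inspectable; the in-memory objects of the underlying modules are
returned as well for programmatic use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from . import coverage as _coverage
from . import formats_io as fio
from . import succession_stats as stats
from . import target_genes as tg
from .taxonomy import TaxonomyTree, lineage

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters with study defaults."""

    min_contig_length: int = 300
    min_identity: float = 50.0
    top_fraction: float = 0.1
    merge_gap: int = 30
    conflict_rank: str = "phylum"
    min_flank: int = 1000
    n_perm: int = 9999
    alpha: float = 0.05
    r_threshold: float = 0.4
    seed: int = 0
    include_ice: bool = False
    gene_sets_path: Optional[str] = None

    _RANGES = {
        "min_contig_length": (0, 10**9),
        "min_identity": (0.0, 100.0),
        "top_fraction": (1e-9, 1.0),
        "merge_gap": (0, 10**9),
        "min_flank": (0, 10**9),
        "n_perm": (1, 10**9),
        "alpha": (0.0, 1.0),
        "r_threshold": (0.0, 1.0),
    }

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Annotation stage
# ---------------------------------------------------------------------------

def run_annotate(
    contigs_fasta: Union[str, Path],
    alignments_tsv: Union[str, Path],
    nodes_dmp: Union[str, Path],
    names_dmp: Union[str, Path],
    acc2taxid_tsv: Union[str, Path],
    gene2go_tsv: Optional[Union[str, Path]],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
):
    """Annotate an assembly from files; writes regions, chimera report and
    contig lineages as TSVs under ``outdir``."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tree = fio.read_taxonomy_dump(nodes_dmp, names_dmp)
    acc_map = fio.read_accession_map(acc2taxid_tsv)
    go_map = fio.read_gene_go_map(gene2go_tsv) if gene2go_tsv else None
    contig_lengths = {
        r.contig_id: r.length
        for r in fio.read_fasta(contigs_fasta, min_length=cfg.min_contig_length, keep_sequence=False)
    }
    result = fio.read_alignments(
        alignments_tsv,
        acc_map,
        taxonomy=tree,
        go_map=go_map,
        min_identity=cfg.min_identity,
        contig_lengths=contig_lengths,
    )
    hits = [h for h in result.hits if h.query_id in contig_lengths]
    annotations, chimera = _annotate.annotate_assembly(
        contig_lengths,
        hits,
        tree,
        merge_gap=cfg.merge_gap,
        top_fraction=cfg.top_fraction,
        conflict_rank=cfg.conflict_rank,
        min_flank=cfg.min_flank,
    )
    logger.info(
        "annotate: %d contigs in, %d chimeric, %d regions called",
        len(contig_lengths),
        len(chimera),
        sum(len(a.regions) for a in annotations.values()),
    )
    write_annotation_tables(annotations, chimera, tree, outdir)
    return annotations, chimera, tree


def write_annotation_tables(
    annotations: Mapping[str, _annotate.ContigAnnotation],
    chimera: Mapping[str, _annotate.ChimeraSplitResult],
    tree: TaxonomyTree,
    outdir: Path,
) -> None:
    region_rows = []
    lineage_rows = []
    for cid in sorted(annotations):
        a = annotations[cid]
        for r in a.regions:
            taxname = tree.name(r.region_taxid) if r.region_taxid is not None else ""
            region_rows.append(
                dict(
                    contig=cid, start=r.start, end=r.end, strand=r.strand,
                    gene_label=r.gene_label, go_terms=",".join(sorted(r.go_terms)),
                    taxid=r.region_taxid if r.region_taxid is not None else "",
                    taxon=taxname,
                )
            )
        lin = ";".join(
            f"{rank}:{tree.name(t)}" for rank, t in a.contig_lineage.items()
        )
        lineage_rows.append(
            dict(contig=cid, length=a.length, chimeric=int(a.chimeric), lineage=lin)
        )
    pd.DataFrame(
        region_rows,
        columns=["contig", "start", "end", "strand", "gene_label", "go_terms", "taxid", "taxon"],
    ).to_csv(outdir / "regions.tsv", sep="\t", index=False)
    pd.DataFrame(lineage_rows, columns=["contig", "length", "chimeric", "lineage"]).to_csv(
        outdir / "contig_lineage.tsv", sep="\t", index=False
    )
    chim_rows = []
    for parent in sorted(chimera):
        res = chimera[parent]
        for child_id, (lo, hi) in res.children:
            chim_rows.append(dict(parent=parent, child=child_id, start=lo, end=hi))
    pd.DataFrame(chim_rows, columns=["parent", "child", "start", "end"]).to_csv(
        outdir / "chimera_report.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Abundance stage
# ---------------------------------------------------------------------------

def expand_coverage_to_children(
    contig_table: pd.DataFrame,
    chimera: Mapping[str, _annotate.ChimeraSplitResult],
    contig_lengths: Mapping[str, int],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Replace split parents' coverage columns with their children.

    Reads map to parent ids; with uniform placement a child's mean coverage
    equals the parent's, so children inherit the parent's value and the
    length table gains the child lengths.
    """
    lengths = dict(contig_lengths)
    table = contig_table.copy()
    for parent, res in chimera.items():
        if parent not in table.columns:
            continue
        for child_id, (lo, hi) in res.children:
            table[child_id] = table[parent]
            lengths[child_id] = hi - lo
        table = table.drop(columns=[parent])
        lengths.pop(parent, None)
    return table[sorted(table.columns)], lengths


def run_abundance(
    annotations: Mapping[str, _annotate.ContigAnnotation],
    chimera: Mapping[str, _annotate.ChimeraSplitResult],
    tree: TaxonomyTree,
    contig_lengths: Mapping[str, int],
    mapped_bases: Mapping[str, Mapping[str, int]],
    metadata: Sequence[fio.SampleMeta],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
):
    """Coverage and abundance tables from mappings + annotation."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = {m.sample_id for m in metadata}
    stray = sorted(set(mapped_bases) - known)
    if stray:
        raise ValueError(f"samples in mappings absent from metadata: {stray}")

    contig_table = _coverage.contig_base_coverage(mapped_bases, contig_lengths)
    contig_table, lengths = expand_coverage_to_children(contig_table, chimera, contig_lengths)
    sample_cov = _coverage.sample_base_coverage(contig_table, lengths)

    tables: Dict[str, pd.DataFrame] = {"contig_coverage": contig_table}
    for rank in ("phylum", "order", "genus"):
        tables[f"abundance_{rank}"] = _coverage.taxon_abundance(
            contig_table, annotations, tree, rank, lengths
        )
    regions = [r for a in annotations.values() for r in a.regions]
    gene_table = _coverage.gene_coverage(contig_table, regions)
    tables["gene_coverage"] = gene_table
    tables["weighted_gene_coverage"] = _coverage.weighted_gene_coverage(gene_table, sample_cov)

    go_cov = go_weighted_coverage(contig_table, regions, sample_cov)
    tables["go_weighted_coverage"] = go_cov

    sample_cov.to_frame().to_csv(outdir / "sample_coverage.tsv", sep="\t")
    for name, t in tables.items():
        t.to_csv(outdir / f"{name}.tsv", sep="\t")
    return tables, sample_cov, lengths


def go_weighted_coverage(
    contig_table: pd.DataFrame,
    regions: Sequence[_annotate.GeneRegion],
    sample_cov: pd.Series,
) -> pd.DataFrame:
    """Sample x GO-category weighted coverage (region-length-weighted mean
    per GO term, divided by sample coverage)."""
    go_regions: Dict[str, list] = {}
    for r in regions:
        for go in r.go_terms:
            go_regions.setdefault(go, []).append((r.contig_id, r.length))
    cols = sorted(go_regions)
    out = np.zeros((contig_table.shape[0], len(cols)))
    for j, go in enumerate(cols):
        total = 0.0
        acc = np.zeros(contig_table.shape[0])
        for cid, length in go_regions[go]:
            if cid in contig_table.columns:
                acc += contig_table[cid].values * length
                total += length
        if total > 0:
            out[:, j] = acc / total
    df = pd.DataFrame(out, index=contig_table.index, columns=cols)
    return df.div(sample_cov.loc[df.index], axis=0)


# ---------------------------------------------------------------------------
# Statistics stage
# ---------------------------------------------------------------------------

def run_stats(
    tables: Mapping[str, pd.DataFrame],
    metadata: Sequence[fio.SampleMeta],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
):
    """The chronosequence statistics battery.

    Ice samples are excluded unless ``config.include_ice``; PERMANOVA runs
    against the fixed factor forefield on Bray-Curtis (community, diversity,
    gene, GO) and Euclidean (geochemistry) matrices; Mantel relates distance
    and TN+TOC to each dataset, pooled and per forefield; the GO screen
    correlates every category with distance, TN and TOC.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    meta = {m.sample_id: m for m in metadata}
    samples = [
        s
        for s in tables["abundance_genus"].index
        if s in meta and (cfg.include_ice or meta[s].substrate == "soil")
    ]
    if len(samples) < 4:
        raise ValueError("too few samples for the statistics battery")
    forefield = np.array([meta[s].forefield for s in samples])
    distance = np.array([meta[s].distance_m for s in samples])
    tn = np.array([meta[s].tn_mg_g for s in samples])
    toc = np.array([meta[s].toc_mg_g for s in samples])

    genus = tables["abundance_genus"].loc[samples]
    diversity = stats.diversity_table(genus)
    diversity["distance_m"] = distance
    diversity["bin"] = [stats.bin_distance(d) for d in distance]
    diversity.to_csv(outdir / "diversity.tsv", sep="\t")

    datasets: Dict[str, np.ndarray] = {
        "taxonomy_genus": stats.bray_curtis(genus),
        "diversity": stats.bray_curtis(diversity[["shannon", "inv_simpson"]].values),
        "gene": stats.bray_curtis(tables["weighted_gene_coverage"].loc[samples]),
        "go": stats.bray_curtis(tables["go_weighted_coverage"].loc[samples]),
        "geochemistry": stats.euclidean(np.column_stack([tn, toc])),
    }
    for extra_rank in ("phylum", "order"):
        key = f"abundance_{extra_rank}"
        if key in tables:
            datasets[f"taxonomy_{extra_rank}"] = stats.bray_curtis(tables[key].loc[samples])

    rng_seed = cfg.seed

    perm_rows = []
    if len(np.unique(forefield)) >= 2:
        for name, d in datasets.items():
            res = stats.permanova(d, forefield, n_perm=cfg.n_perm, seed=rng_seed)
            perm_rows.append(
                dict(dataset=name, r2=res.r2, pseudo_f=res.pseudo_f, p=res.p,
                     n_perm=res.n_perm, seed=rng_seed)
            )
    else:
        logger.warning("PERMANOVA skipped: fewer than 2 forefield levels")
    pd.DataFrame(perm_rows).to_csv(outdir / "permanova.tsv", sep="\t", index=False)

    dist_mat = stats.euclidean(distance.reshape(-1, 1))
    geo_mat = datasets["geochemistry"]
    mantel_rows = []

    def _mantel_safe(d1, d2, dataset, covariate, scope):
        try:
            res = stats.mantel(d1, d2, n_perm=cfg.n_perm, seed=rng_seed)
        except ValueError as exc:
            logger.warning("Mantel %s/%s (%s) skipped: %s", dataset, covariate, scope, exc)
            return
        mantel_rows.append(
            dict(dataset=dataset, covariate=covariate, scope=scope, r=res.r,
                 p=res.p, n_perm=res.n_perm, seed=rng_seed)
        )

    for name in ("taxonomy_genus", "diversity", "gene", "go"):
        _mantel_safe(datasets[name], dist_mat, name, "distance", "pooled")
        _mantel_safe(datasets[name], geo_mat, name, "TN+TOC", "pooled")
        for ff in sorted(set(forefield)):
            m = forefield == ff
            if m.sum() >= 4:
                sub = datasets[name][np.ix_(m, m)]
                _mantel_safe(sub, dist_mat[np.ix_(m, m)], name, "distance", ff)
                _mantel_safe(sub, geo_mat[np.ix_(m, m)], name, "TN+TOC", ff)
    pd.DataFrame(mantel_rows).to_csv(outdir / "mantel.tsv", sep="\t", index=False)

    corr_rows = []
    for label, y in (("shannon", diversity["shannon"].values),
                     ("inv_simpson", diversity["inv_simpson"].values)):
        for cov_name, cov in (("distance", distance), ("tn", tn), ("toc", toc)):
            res = stats.spearman_perm(cov, y, n_perm=cfg.n_perm, seed=rng_seed)
            corr_rows.append(
                dict(variable=label, covariate=cov_name, rs=res.rs, p=res.p,
                     n_perm=res.n_perm, seed=rng_seed)
            )
    pd.DataFrame(corr_rows).to_csv(outdir / "spearman.tsv", sep="\t", index=False)

    go_screens = {}
    for cov_name, cov in (("distance", distance), ("tn", tn), ("toc", toc)):
        screen = stats.screen_go_correlations(
            tables["go_weighted_coverage"].loc[samples], cov,
            r_threshold=cfg.r_threshold, alpha=cfg.alpha,
            n_perm=cfg.n_perm, seed=rng_seed,
        )
        screen.to_csv(outdir / f"go_screen_{cov_name}.tsv", sep="\t", index=False)
        go_screens[cov_name] = screen

    scores, loadings, varexp = stats.pca(genus.values)
    pd.DataFrame(
        scores[:, : min(5, scores.shape[1])], index=samples,
        columns=[f"PC{i + 1}" for i in range(min(5, scores.shape[1]))],
    ).to_csv(outdir / "pca_scores.tsv", sep="\t")
    pd.Series(varexp, name="variance_explained").to_csv(outdir / "pca_variance.tsv", sep="\t")

    return dict(
        diversity=diversity,
        permanova=pd.DataFrame(perm_rows),
        mantel=pd.DataFrame(mantel_rows),
        spearman=pd.DataFrame(corr_rows),
        go_screens=go_screens,
        pca_variance=varexp,
    )


# ---------------------------------------------------------------------------
# Target-gene stage
# ---------------------------------------------------------------------------

def run_target_genes(
    annotations: Mapping[str, _annotate.ContigAnnotation],
    tree: TaxonomyTree,
    contig_table: pd.DataFrame,
    sample_cov: pd.Series,
    abundance_genus: pd.DataFrame,
    metadata: Sequence[fio.SampleMeta],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
):
    """Genus-wise trends of the four target gene sets."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_sets = tg.load_gene_sets(cfg.gene_sets_path)
    trends = {}
    frac_rows = []
    for name, gs in gene_sets.items():
        selected = tg.select_gene_regions(annotations, gs, tree)
        trend = tg.genus_set_trend(
            selected, contig_table, sample_cov, abundance_genus, metadata, set_name=name
        )
        trends[name] = trend
        trend.coverage.to_csv(outdir / f"trend_{name}.tsv", sep="\t")
        for bin_label, frac in trend.genus_fraction.items():
            frac_rows.append(dict(set=name, bin=bin_label, genus_fraction=frac))
    pd.DataFrame(frac_rows).to_csv(outdir / "genus_fractions.tsv", sep="\t", index=False)
    return trends
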