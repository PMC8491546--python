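"""Synthetic proglacial-chronosequence generator.

Emits every input the pipeline consumes — contigs, ranged protein-alignment
hits, a ranked taxonomy, accession and GO maps, per-sample read mappings and
sample metadata — together with a truth table, so the whole analysis can be
exercised and scored end to end.

What the generator emulates (and its defaults):

* three forefield systems (G, SV, SW) sampled over the 11 ice-edge distance
  bins; G spans all bins, SV reaches ~1,600 m, SW ~350 m, matching the
  systems' real extents; two soil samples per bin plus two ice samples per
  forefield;
* total nitrogen following either a monotone increase in log-distance
  (SV, SW) or a hump peaking in the 150-250 m bin (G), with TOC a noisy
  multiple of TN;
* genus communities from a softmax of per-genus intercept, log-distance
  slope, ice affinity and forefield offset — a handful of early-succession
  dominants with negative slopes and many weakly increasing genera, so
  community evenness (inverse Simpson) rises along the succession;
* per-genus gene content including four target gene sets, with nitrogenase
  assigned to the genera with the steepest positive distance response —
  mostly "late specialists" that are below detection near the ice edge —
  so the fraction of genera carrying nitrogenase rises with distance;
* ~1% chimeric contigs built by concatenating fragments from two phyla;
* alignment hits with configurable identity noise and off-target hits to
  sister genera at lower bitscores.

Every operation is seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .formats_io import (
    AlignmentHit,
    ContigRecord,
    GeneToGoMap,
    SampleMeta,
    to_half_open,
    write_accession_map,
    write_fasta,
    write_gene_go_map,
    write_sample_metadata,
    write_taxonomy_dump,
)
from .succession_stats import DISTANCE_BINS
from .taxonomy import TaxonomyTree


@dataclass
class SimConfig:
    """Study-shaped defaults for the synthetic chronosequence."""

    seed: int = 0
    forefields: Tuple[str, ...] = ("G", "SV", "SW")
    #: number of leading distance bins each forefield spans
    bins_per_forefield: Dict[str, int] = field(
        default_factory=lambda: {"G": 11, "SV": 9, "SW": 4}
    )
    geochem_model: Dict[str, str] = field(
        default_factory=lambda: {"G": "hump", "SV": "monotone", "SW": "monotone"}
    )
    samples_per_bin: int = 2
    ice_samples_per_forefield: int = 2

    # geochemistry (mg per g dry soil)
    tn_intercept: float = 0.2
    tn_slope: float = 0.25          # monotone: TN = a + b log(d+1)
    tn_hump_height: float = 1.6     # hump: TN = floor + h exp(-c (log d - log peak)^2)
    tn_hump_width: float = 0.6
    tn_hump_peak_m: float = 200.0
    tn_floor: float = 0.05
    tn_noise_sd: float = 0.03
    toc_per_tn: float = 3.0
    toc_noise_sd: float = 0.1

    # community
    n_genera: int = 40
    n_phyla: int = 4
    n_early_dominants: int = 5
    early_alpha: float = 4.0
    early_beta: float = -0.45
    late_beta_min: float = 0.05
    late_beta_max: float = 0.10
    n_late_specialists: int = 8
    specialist_alpha: float = -9.0
    specialist_beta: Tuple[float, float] = (0.55, 0.75)
    ice_affinity: float = 2.5
    n_ice_genera: int = 3
    forefield_effect_sd: float = 0.5
    community_noise_sd: float = 0.3

    # assembly
    n_contigs_per_genus: int = 50
    contig_length_range: Tuple[int, int] = (2500, 8000)
    chimera_rate: float = 0.01
    regions_per_contig: Tuple[int, int] = (1, 4)
    region_length_range: Tuple[int, int] = (600, 1500)
    region_gap_range: Tuple[int, int] = (50, 300)

    # gene content
    n_background_genes: int = 300
    genes_per_genus: int = 30
    n_go_categories: int = 60
    n_nif_genera: int = 10
    n_obca_genera: int = 12
    n_cyanide_genera: int = 5
    n_siderophore_genera: int = 15

    # alignment noise
    identity_mean: float = 85.0
    identity_sd: float = 5.0
    bitscore_per_base: float = 0.45
    bitscore_sd: float = 5.0
    off_target_rate: float = 0.5          # sister-genus hits per region
    off_target_bitscore: Tuple[float, float] = (0.70, 0.98)
    cross_phylum_rate: float = 0.05       # low-score far hits per region
    cross_phylum_bitscore: Tuple[float, float] = (0.50, 0.88)

    # sequencing
    depth: float = 2.0                    # target mean sample base coverage (x)
    read_length: int = 100
    contig_effect_sd: float = 0.3         # lognormal per-(sample,contig) effect

    def validate(self) -> None:
        if not 0 <= self.chimera_rate <= 1:
            raise ValueError("chimera_rate must be in [0,1]")
        if self.samples_per_bin < 1 or self.n_genera < 2 or self.n_contigs_per_genus < 1:
            raise ValueError("counts must be >= 1 (n_genera >= 2)")
        if self.contig_length_range[0] > self.contig_length_range[1]:
            raise ValueError("bad contig_length_range")
        for f in self.forefields:
            if self.bins_per_forefield.get(f, 0) < 1:
                raise ValueError(f"forefield {f} spans no bins")
            if self.geochem_model.get(f) not in ("monotone", "hump"):
                raise ValueError(f"forefield {f}: geochem model must be monotone|hump")


@dataclass
class PlantedRegion:
    contig_id: str
    start: int
    end: int
    strand: str
    gene_label: str
    genus: str


@dataclass
class TruthTable:
    contigs: pd.DataFrame       # contig_id, genus, phylum, length, chimeric, breakpoint
    regions: List[PlantedRegion]
    community: pd.DataFrame     # sample x genus true relative abundance
    genus_beta: pd.Series       # per-genus log-distance slope
    gene_sets: Dict[str, List[str]]  # set name -> genera carrying it


@dataclass
class SimBundle:
    config: SimConfig
    metadata: List[SampleMeta]
    tree: TaxonomyTree
    genus_names: List[str]
    genus_taxids: Dict[str, int]
    genus_phylum: Dict[str, str]
    contig_lengths: Dict[str, int]
    alignment_rows: List[Tuple]          # outfmt-6 + subject-title column
    accession_map: Dict[str, int]
    go_map: GeneToGoMap
    truth: TruthTable
    mapped_bases: Dict[str, Dict[str, int]]  # sample -> contig -> bases

    def alignment_hits(self) -> List[AlignmentHit]:
        """The emitted alignment rows as parsed hits (same conversion path
        as the file reader)."""
        hits = []
        for row in self.alignment_rows:
            (qseqid, sseqid, pident, _alen, _mm, _go, qs, qe, _ss, _se, ev, bs, title) = row
            q_start, q_end, strand = to_half_open(qs, qe)
            hits.append(
                AlignmentHit(
                    query_id=qseqid,
                    q_start=q_start,
                    q_end=q_end,
                    strand=strand,
                    subject_acc=sseqid,
                    subject_taxid=self.accession_map.get(sseqid),
                    pct_identity=pident,
                    evalue=ev,
                    bitscore=bs,
                    gene_label=title,
                    go_terms=self.go_map.go_for(title),
                )
            )
        return hits


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimConfig) -> Tuple[TaxonomyTree, List[str], Dict[str, int], Dict[str, str]]:
    """Balanced ranked tree: root -> superkingdom -> phyla -> classes ->
    orders -> families -> genera, genera distributed round-robin."""
    edges: List[Tuple[int, int, str]] = [(1, 1, "no rank"), (2, 1, "superkingdom")]
    names: Dict[int, str] = {1: "root", 2: "Bacteria"}
    next_id = 3
    family_ids: List[int] = []
    family_phylum: List[str] = []
    for p in range(config.n_phyla):
        pid = next_id
        next_id += 1
        edges.append((pid, 2, "phylum"))
        names[pid] = f"Phylum{p + 1:02d}"
        for c in range(2):
            cid = next_id
            next_id += 1
            edges.append((cid, pid, "class"))
            names[cid] = f"Class{p + 1:02d}_{c + 1}"
            oid = next_id
            next_id += 1
            edges.append((oid, cid, "order"))
            names[oid] = f"Order{p + 1:02d}_{c + 1}"
            fid = next_id
            next_id += 1
            edges.append((fid, oid, "family"))
            names[fid] = f"Family{p + 1:02d}_{c + 1}"
            family_ids.append(fid)
            family_phylum.append(names[pid])
    genus_names: List[str] = []
    genus_taxids: Dict[str, int] = {}
    genus_phylum: Dict[str, str] = {}
    for g in range(config.n_genera):
        fam_idx = g % len(family_ids)
        gid = next_id
        next_id += 1
        name = f"Genus{g + 1:03d}"
        edges.append((gid, family_ids[fam_idx], "genus"))
        names[gid] = name
        genus_names.append(name)
        genus_taxids[name] = gid
        genus_phylum[name] = family_phylum[fam_idx]
    tree = TaxonomyTree.from_edges(edges, names)
    return tree, genus_names, genus_taxids, genus_phylum


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def _tn_mean(config: SimConfig, model: str, distance: float) -> float:
    if model == "monotone":
        return config.tn_intercept + config.tn_slope * math.log(distance + 1.0)
    dlog = math.log(distance + 1.0) - math.log(config.tn_hump_peak_m + 1.0)
    return config.tn_floor + config.tn_hump_height * math.exp(
        -config.tn_hump_width * dlog * dlog
    )


def simulate_metadata(config: SimConfig, rng: Optional[np.random.Generator] = None) -> List[SampleMeta]:
    """Sample metadata with the programmed geochemical gradients.

    Soil samples sit uniformly inside each forefield's distance bins (the
    open-ended last bin uses 10-12 km); ice samples sit at distance 0 with
    trace TN/TOC.  TOC is a noisy multiple of TN, so the two are strongly
    rank-correlated by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    samples: List[SampleMeta] = []
    for ff in config.forefields:
        model = config.geochem_model[ff]
        n_bins = config.bins_per_forefield[ff]
        for label, lo, hi in DISTANCE_BINS[:n_bins]:
            hi_eff = min(hi, lo + 2000.0) if math.isinf(hi) else hi
            for k in range(config.samples_per_bin):
                d = float(rng.uniform(lo, hi_eff))
                tn = max(0.01, _tn_mean(config, model, d) + rng.normal(0, config.tn_noise_sd))
                toc = max(0.01, config.toc_per_tn * tn + rng.normal(0, config.toc_noise_sd))
                samples.append(
                    SampleMeta(
                        sample_id=f"{ff}_{label.replace(',', '').replace('>', 'gt')}_{k + 1}",
                        forefield=ff,
                        substrate="soil",
                        distance_m=round(d, 1),
                        tn_mg_g=round(tn, 4),
                        toc_mg_g=round(toc, 4),
                    )
                )
        for k in range(config.ice_samples_per_forefield):
            tn = max(0.005, rng.normal(0.05, 0.02))
            samples.append(
                SampleMeta(
                    sample_id=f"{ff}_ice_{k + 1}",
                    forefield=ff,
                    substrate="ice",
                    distance_m=0.0,
                    tn_mg_g=round(tn, 4),
                    toc_mg_g=round(max(0.005, config.toc_per_tn * tn + rng.normal(0, 0.02)), 4),
                )
            )
    return samples


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def _genus_parameters(config: SimConfig, rng: np.random.Generator, genus_names: Sequence[str]):
    n = len(genus_names)
    n_dom = config.n_early_dominants
    n_spec = min(config.n_late_specialists, n - n_dom)
    alpha = np.zeros(n)
    beta = np.zeros(n)
    alpha[:n_dom] = config.early_alpha
    beta[:n_dom] = config.early_beta
    # late specialists: effectively absent near the ice edge, common far out
    alpha[n_dom : n_dom + n_spec] = config.specialist_alpha
    beta[n_dom : n_dom + n_spec] = rng.uniform(*config.specialist_beta, n_spec)
    beta[n_dom + n_spec :] = rng.uniform(
        config.late_beta_min, config.late_beta_max, n - n_dom - n_spec
    )
    ice = np.zeros(n)
    ice_idx = rng.choice(config.n_early_dominants, size=min(config.n_ice_genera, config.n_early_dominants), replace=False)
    ice[ice_idx] = config.ice_affinity
    return alpha, beta, ice


def simulate_community(
    config: SimConfig,
    metadata: Sequence[SampleMeta],
    rng: Optional[np.random.Generator] = None,
    genus_names: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """True genus relative abundances per sample (rows sum to 1).

    Softmax of alpha_g + beta_g log(d+1) + ice_g [substrate=ice] +
    forefield offset + noise.  Returns (community, per-genus beta).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if genus_names is None:
        genus_names = [f"Genus{g + 1:03d}" for g in range(config.n_genera)]
    alpha, beta, ice = _genus_parameters(config, rng, genus_names)
    ff_effect = {
        ff: rng.normal(0, config.forefield_effect_sd, len(genus_names))
        for ff in config.forefields
    }
    rows = {}
    for m in metadata:
        logit = (
            alpha
            + beta * math.log(m.distance_m + 1.0)
            + ice * (1.0 if m.substrate == "ice" else 0.0)
            + ff_effect[m.forefield]
            + rng.normal(0, config.community_noise_sd, len(genus_names))
        )
        e = np.exp(logit - logit.max())
        rows[m.sample_id] = e / e.sum()
    community = pd.DataFrame.from_dict(rows, orient="index", columns=list(genus_names))
    return community, pd.Series(beta, index=list(genus_names))


# ---------------------------------------------------------------------------
# Gene content, contigs and alignments
# ---------------------------------------------------------------------------

_SET_LABELS = {
    "nitrogenase": "nitrogenase iron protein nifH",
    "obcA": "oxalate biosynthetic component A obcA",
    "cyanide_synthase": "cyanide synthase hcnA",
    "siderophore": "siderophore biosynthesis protein",
}


def _assign_gene_sets(
    config: SimConfig, rng: np.random.Generator, genus_names: Sequence[str], beta: pd.Series
) -> Dict[str, List[str]]:
    """Nitrogenase goes to the genera with the largest log-distance slopes
    (late-succession taxa), the other sets to random genera."""
    by_beta = list(beta.sort_values(ascending=False).index)
    sets = {"nitrogenase": by_beta[: config.n_nif_genera]}
    pool = list(genus_names)
    for name, n in (
        ("obcA", config.n_obca_genera),
        ("cyanide_synthase", config.n_cyanide_genera),
        ("siderophore", config.n_siderophore_genera),
    ):
        sets[name] = sorted(rng.choice(pool, size=min(n, len(pool)), replace=False))
    return sets


def simulate_contigs_and_alignments(
    config: SimConfig,
    community: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimBundle:
    """Contigs with planted gene regions, their alignment hits, taxonomy,
    accession and GO maps, and the truth table.

    Chimeric contigs (rate ``chimera_rate``) concatenate two fragments from
    genera in different phyla; every fragment carries at least two regions so
    the discordance is in principle detectable.  Each planted region yields
    one on-target hit plus, at configured rates, off-target hits to a sister
    genus (same family) and low-score cross-phylum hits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    tree, genus_names, genus_taxids, genus_phylum = simulate_taxonomy(config)
    # beta must match simulate_community's draw for the same config/seed:
    # regenerate deterministically from the community stream prefix
    com_rng = np.random.default_rng(config.seed + 2)
    _, beta, _ = _genus_parameters(config, com_rng, genus_names)
    beta = pd.Series(beta, index=genus_names)
    gene_sets = _assign_gene_sets(config, rng, genus_names, beta)

    # gene content per genus: background genes + target-set genes
    go_map = GeneToGoMap()
    go_pool = [f"GO:{i + 1:07d}" for i in range(config.n_go_categories)]
    background = [f"hypothetical protein gene{i + 1:04d}" for i in range(config.n_background_genes)]
    for i, g in enumerate(background):
        go_map.gene_to_go[g] = {go_pool[i % len(go_pool)]}
    for set_name, label in _SET_LABELS.items():
        go_map.gene_to_go[label] = (
            {"GO:0009399"} if set_name == "nitrogenase" else set()
        )
    genus_genes: Dict[str, List[str]] = {}
    for genus in genus_names:
        picks = rng.choice(len(background), size=config.genes_per_genus, replace=False)
        genes = [background[i] for i in picks]
        for set_name, members in gene_sets.items():
            if genus in members:
                genes.append(_SET_LABELS[set_name])
        genus_genes[genus] = genes

    # sister map: genera sharing a family
    family_of: Dict[str, List[str]] = {}
    for genus in genus_names:
        fam = genus_taxids[genus]  # use parent family id via tree
        fam = tree.parent(fam)
        family_of.setdefault(fam, []).append(genus)

    accession_map: Dict[str, int] = {}
    acc_counter = 0

    def accession_for(genus: str) -> str:
        nonlocal acc_counter
        acc_counter += 1
        acc = f"P{acc_counter:06d}"
        accession_map[acc] = genus_taxids[genus]
        return acc

    contig_lengths: Dict[str, int] = {}
    rows: List[Tuple] = []
    planted: List[PlantedRegion] = []
    contig_truth_rows = []

    def plant_fragment(
        contig_id: str,
        genus: str,
        frag_lo: int,
        frag_hi: int,
        n_regions: int,
        min_first_len: int = 0,
    ):
        """Plant regions in [frag_lo, frag_hi) and emit their hits.

        ``min_first_len`` guarantees the fragment's leading region (hence its
        taxonomic run) spans at least that many bases — used for chimera
        fragments so the discordant blocks carry enough flanking support.
        """
        pos = frag_lo + int(rng.integers(50, 200))
        for i in range(n_regions):
            rlen = int(rng.integers(*config.region_length_range))
            if i == 0 and rlen < min_first_len:
                rlen = min_first_len
            if pos + rlen > frag_hi - 50:
                break
            start, end = pos, pos + rlen
            strand = "+" if rng.random() < 0.5 else "-"
            label = genus_genes[genus][int(rng.integers(len(genus_genes[genus])))]
            planted.append(PlantedRegion(contig_id, start, end, strand, label, genus))
            _emit_hits(contig_id, genus, start, end, strand, label)
            pos = end + int(rng.integers(*config.region_gap_range))

    def _emit_hits(contig_id, genus, start, end, strand, label):
        rlen = end - start
        best_bs = max(30.0, config.bitscore_per_base * rlen + rng.normal(0, config.bitscore_sd))
        qs, qe = (start + 1, end) if strand == "+" else (end, start + 1)
        ident = float(np.clip(rng.normal(config.identity_mean, config.identity_sd), 50, 100))
        rows.append(
            (contig_id, accession_for(genus), round(ident, 1), rlen // 3, 0, 0,
             qs, qe, 1, rlen // 3, 1e-30, round(best_bs, 1), label)
        )
        fam = tree.parent(genus_taxids[genus])
        sisters = [g for g in family_of[fam] if g != genus]
        if sisters and rng.random() < config.off_target_rate:
            sis = sisters[int(rng.integers(len(sisters)))]
            frac = rng.uniform(*config.off_target_bitscore)
            jitter = int(rng.integers(0, 30))
            qs2, qe2 = (start + 1 + jitter, end) if strand == "+" else (end, start + 1 + jitter)
            rows.append(
                (contig_id, accession_for(sis), round(ident - 5, 1), rlen // 3, 0, 0,
                 qs2, qe2, 1, rlen // 3, 1e-20, round(best_bs * frac, 1), label)
            )
        if rng.random() < config.cross_phylum_rate:
            far = [g for g in genus_names if genus_phylum[g] != genus_phylum[genus]]
            fg = far[int(rng.integers(len(far)))]
            frac = rng.uniform(*config.cross_phylum_bitscore)
            rows.append(
                (contig_id, accession_for(fg), round(max(50.0, ident - 15), 1), rlen // 3, 0, 0,
                 qs, qe, 1, rlen // 3, 1e-10, round(best_bs * frac, 1), label)
            )

    n_total = 0
    for genus in genus_names:
        for k in range(config.n_contigs_per_genus):
            n_total += 1
            contig_id = f"ctg{n_total:06d}"
            is_chimera = rng.random() < config.chimera_rate
            if is_chimera:
                others = [g for g in genus_names if genus_phylum[g] != genus_phylum[genus]]
                other = others[int(rng.integers(len(others)))]
                l1 = int(rng.integers(2200, 4200))
                l2 = int(rng.integers(2200, 4200))
                length = l1 + l2
                contig_lengths[contig_id] = length
                flank = 1100  # a single leading region already satisfies the
                # default 1,000-base flank rule of chimera detection
                plant_fragment(contig_id, genus, 0, l1, int(rng.integers(2, 4)), flank)
                plant_fragment(contig_id, other, l1, length, int(rng.integers(2, 4)), flank)
                contig_truth_rows.append(
                    dict(contig_id=contig_id, genus=genus, phylum=genus_phylum[genus],
                         length=length, chimeric=True, breakpoint=l1, second_genus=other)
                )
            else:
                length = int(rng.integers(*config.contig_length_range))
                contig_lengths[contig_id] = length
                plant_fragment(contig_id, genus, 0, length, int(rng.integers(*config.regions_per_contig)) )
                contig_truth_rows.append(
                    dict(contig_id=contig_id, genus=genus, phylum=genus_phylum[genus],
                         length=length, chimeric=False, breakpoint=-1, second_genus="")
                )

    truth = TruthTable(
        contigs=pd.DataFrame(contig_truth_rows).set_index("contig_id"),
        regions=planted,
        community=community if community is not None else pd.DataFrame(),
        genus_beta=beta,
        gene_sets=gene_sets,
    )
    return SimBundle(
        config=config,
        metadata=[],
        tree=tree,
        genus_names=genus_names,
        genus_taxids=genus_taxids,
        genus_phylum=genus_phylum,
        contig_lengths=contig_lengths,
        alignment_rows=rows,
        accession_map=accession_map,
        go_map=go_map,
        truth=truth,
        mapped_bases={},
    )


# ---------------------------------------------------------------------------
# Mappings
# ---------------------------------------------------------------------------

def simulate_mappings(
    config: SimConfig,
    bundle: SimBundle,
    community: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Dict[str, int]]:
    """Per-sample mapped bases per contig.

    Expected contig coverage = depth * genus abundance * n_genera * lognormal
    contig effect (so the assembly-wide mean tracks ``depth``); read counts
    are Poisson, each read contributing ``read_length`` aligned bases.
    Chimeric contigs average their two source genera.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    n_genera = len(bundle.genus_names)
    truth = bundle.truth.contigs
    contig_ids = list(truth.index)
    genus_idx = {g: j for j, g in enumerate(community.columns)}
    g1 = np.array([genus_idx[g] for g in truth["genus"]])
    chim = truth["chimeric"].values.astype(bool)
    g2 = np.array(
        [genus_idx.get(g, -1) for g in truth["second_genus"]]
    )
    lengths = np.array([bundle.contig_lengths[c] for c in contig_ids], dtype=float)
    out: Dict[str, Dict[str, int]] = {}
    for sample in community.index:
        ab = community.loc[sample].values
        p = ab[g1]
        mix = chim & (g2 >= 0)
        p[mix] = 0.5 * (p[mix] + ab[g2[mix]])
        effects = rng.lognormal(0.0, config.contig_effect_sd, len(contig_ids))
        lam = config.depth * p * n_genera * effects * lengths / config.read_length
        n_reads = rng.poisson(np.clip(lam, 0, None))
        nz = np.nonzero(n_reads)[0]
        out[sample] = {
            contig_ids[j]: int(n_reads[j]) * config.read_length for j in nz
        }
    return out


def write_sam(
    path: Union[str, Path],
    contig_lengths: Dict[str, int],
    per_contig_bases: Dict[str, int],
    read_length: int,
    rng: np.random.Generator,
) -> None:
    """One sample's mappings as a plain-text SAM with uniform read placement."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid in sorted(contig_lengths):
            fh.write(f"@SQ\tSN:{cid}\tLN:{contig_lengths[cid]}\n")
        read_no = 0
        for cid in sorted(per_contig_bases):
            n_reads = per_contig_bases[cid] // read_length
            length = contig_lengths[cid]
            max_pos = max(1, length - read_length + 1)
            for _ in range(n_reads):
                read_no += 1
                pos = int(rng.integers(1, max_pos + 1))
                span = min(read_length, length - pos + 1)
                seq = "A" * span
                fh.write(
                    f"r{read_no:08d}\t0\t{cid}\t{pos}\t60\t{span}M\t*\t0\t0\t{seq}\t*\n"
                )


# ---------------------------------------------------------------------------
# Whole-study simulation and serialization
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimBundle:
    """Generate the complete synthetic study: metadata, community, assembly,
    alignments and mappings, with the truth table filled in."""
    metadata = simulate_metadata(config)
    community, _beta = simulate_community(config, metadata)
    bundle = simulate_contigs_and_alignments(config, community)
    bundle.metadata = metadata
    bundle.truth.community = community
    bundle.mapped_bases = simulate_mappings(config, bundle, community)
    return bundle


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def write_bundle(bundle: SimBundle, outdir: Union[str, Path], sam: bool = False) -> Dict[str, Path]:
    """Serialize a bundle into the exact formats the pipeline reads.

    Returns a manifest name -> path.  ``sam=True`` writes per-sample SAM
    files instead of the mapped-bases TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(bundle.config.seed + 5)
    paths: Dict[str, Path] = {}

    records = [
        ContigRecord(cid, length, _random_sequence(rng, length))
        for cid, length in sorted(bundle.contig_lengths.items())
    ]
    paths["contigs"] = outdir / "contigs.fasta"
    write_fasta(paths["contigs"], records)

    paths["alignments"] = outdir / "alignments.tsv"
    with open(paths["alignments"], "w") as fh:
        for row in bundle.alignment_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    paths["nodes"] = outdir / "nodes.dmp"
    paths["names"] = outdir / "names.dmp"
    write_taxonomy_dump(bundle.tree, paths["nodes"], paths["names"])

    paths["acc2taxid"] = outdir / "acc2taxid.tsv"
    write_accession_map(paths["acc2taxid"], bundle.accession_map)

    paths["gene2go"] = outdir / "gene2go.tsv"
    write_gene_go_map(paths["gene2go"], bundle.go_map)

    paths["metadata"] = outdir / "metadata.tsv"
    write_sample_metadata(paths["metadata"], bundle.metadata)

    if sam:
        samdir = outdir / "sam"
        samdir.mkdir(exist_ok=True)
        for sample, per_contig in sorted(bundle.mapped_bases.items()):
            p = samdir / f"{sample}.sam"
            write_sam(p, bundle.contig_lengths, per_contig, bundle.config.read_length, rng)
            paths[f"sam:{sample}"] = p
    else:
        paths["mapped_bases"] = outdir / "mapped_bases.tsv"
        with open(paths["mapped_bases"], "w") as fh:
            fh.write("sample\tcontig\tmapped_bases\n")
            for sample in sorted(bundle.mapped_bases):
                for cid, bases in sorted(bundle.mapped_bases[sample].items()):
                    fh.write(f"{sample}\t{cid}\t{bases}\n")

    # truth tables
    paths["truth_contigs"] = outdir / "truth_contigs.tsv"
    bundle.truth.contigs.to_csv(paths["truth_contigs"], sep="\t")
    paths["truth_community"] = outdir / "truth_community.tsv"
    bundle.truth.community.to_csv(paths["truth_community"], sep="\t")
    paths["truth_regions"] = outdir / "truth_regions.tsv"
    pd.DataFrame([vars(r) for r in bundle.truth.regions]).to_csv(
        paths["truth_regions"], sep="\t", index=False
    )
    return paths
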