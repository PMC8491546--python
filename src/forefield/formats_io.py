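"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally; the 1-based inclusive
convention of BLAST tabular files is converted exactly once, here, at the
file boundary.  Parsers never silently drop rows: every drop is counted on
the returned object or reported through the module logger.

Dialects handled:

* FASTA (via Biopython) for assembled contigs;
* BLAST tabular ``-outfmt 6`` (12+ columns) for ranged protein alignments;
* NCBI taxonomy dump (``nodes.dmp`` / ``names.dmp``, pipe-and-tab delimited);
* accession -> taxid two-column TSV;
* gene label -> GO ids TSV;
* sample metadata TSV (forefield, substrate, distance, TN, TOC).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Set, TextIO, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

FOREFIELDS = ("G", "SV", "SW")
SUBSTRATES = ("ice", "soil")

_GO_RE = re.compile(r"^GO:\d{7}$")
_SEQ_RE = re.compile(r"^[ACGTNacgtn]*$")


class FormatError(ValueError):
    """A file violated its declared dialect."""


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id}: non-positive length")
        if any(c.isspace() for c in self.contig_id):
            raise ValueError(f"contig id {self.contig_id!r} contains whitespace")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.contig_id}: sequence length "
                f"{len(self.sequence)} != declared {self.length}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One ranged protein-alignment record on a contig.

    ``q_start``/``q_end`` are 0-based half-open on the contig, strand
    normalized (always ``q_start < q_end``); the original orientation is in
    ``strand``.  ``subject_taxid`` is None when the accession did not resolve
    through the accession map (such hits still carry functional labels).
    """

    query_id: str
    q_start: int
    q_end: int
    strand: str
    subject_acc: str
    subject_taxid: Optional[int]
    pct_identity: float
    evalue: float
    bitscore: float
    gene_label: str = ""
    go_terms: frozenset = frozenset()

    def __post_init__(self):
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(
                f"bad interval [{self.q_start},{self.q_end}) on {self.query_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    forefield: str
    substrate: str
    distance_m: float
    tn_mg_g: float
    toc_mg_g: float

    def __post_init__(self):
        if self.forefield not in FOREFIELDS:
            raise ValueError(
                f"sample {self.sample_id}: unknown forefield {self.forefield!r}"
            )
        if self.substrate not in SUBSTRATES:
            raise ValueError(
                f"sample {self.sample_id}: unknown substrate {self.substrate!r}"
            )
        for name, v in (
            ("distance_m", self.distance_m),
            ("tn_mg_g", self.tn_mg_g),
            ("toc_mg_g", self.toc_mg_g),
        ):
            if v < 0:
                raise ValueError(f"sample {self.sample_id}: negative {name}")


@dataclass
class GeneToGoMap:
    """Flat gene_label -> GO ids mapping plus GO id -> category name."""

    gene_to_go: Dict[str, Set[str]] = field(default_factory=dict)
    go_names: Dict[str, str] = field(default_factory=dict)

    def go_for(self, gene_label: str) -> frozenset:
        return frozenset(self.gene_to_go.get(gene_label, ()))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: Union[str, Path], min_length: int = 0, keep_sequence: bool = True
) -> Iterator[ContigRecord]:
    """Stream contigs from a FASTA file, in file order.

    ``min_length`` keeps only contigs of at least that many bases (the
    assembly retrieval filter; 300 in the study configuration).  Characters
    outside {A,C,G,T,N} (case-insensitive) raise :class:`FormatError`.
    """
    path = Path(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not _SEQ_RE.match(seq):
            bad = next(c for c in seq if c.upper() not in "ACGTN")
            raise FormatError(
                f"{path}: contig {rec.id}: illegal sequence character {bad!r}"
            )
        if len(seq) == 0:
            raise FormatError(f"{path}: contig {rec.id}: empty sequence")
        if len(seq) < min_length:
            continue
        yield ContigRecord(rec.id, len(seq), seq if keep_sequence else None)


def write_fasta(path: Union[str, Path], records: Iterable[ContigRecord]) -> None:
    seq_records = []
    for r in records:
        if r.sequence is None:
            raise ValueError(f"contig {r.contig_id} has no sequence to write")
        seq_records.append(SeqRecord(Seq(r.sequence), id=r.contig_id, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BLAST tabular alignments
# ---------------------------------------------------------------------------

def to_half_open(start_1based: int, end_1based: int) -> Tuple[int, int, str]:
    """1-based inclusive query coordinates -> (start, end, strand), 0-based
    half-open with start < end.  ``start > end`` on input encodes the minus
    strand (translated-search convention)."""
    if start_1based == end_1based:
        raise ValueError("zero-length interval cannot carry a strand")
    if start_1based < end_1based:
        return start_1based - 1, end_1based, "+"
    return end_1based - 1, start_1based, "-"


def to_one_based(start: int, end: int, strand: str) -> Tuple[int, int]:
    """Inverse of :func:`to_half_open`."""
    if strand == "+":
        return start + 1, end
    return end, start + 1


@dataclass
class AlignmentReadResult:
    hits: List[AlignmentHit]
    n_unresolved_acc: int = 0
    n_identity_filtered: int = 0


def read_alignments(
    path: Union[str, Path],
    accession_map: Dict[str, int],
    taxonomy: Optional[TaxonomyTree] = None,
    gene_labels: Optional[Dict[str, str]] = None,
    go_map: Optional[GeneToGoMap] = None,
    min_identity: Optional[float] = None,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> AlignmentReadResult:
    """Parse a BLAST ``-outfmt 6`` TSV into strand-normalized hits.

    Columns (>=12, extras ignored): qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore.  The subject accession
    is resolved to a taxid through ``accession_map``; unresolvable accessions
    keep taxid None (counted, retained for gene calling, excluded from
    taxonomy).  ``gene_labels`` maps accession -> functional label; when
    absent, the accession itself is the label.
    """
    path = Path(path)
    hits: List[AlignmentHit] = []
    n_unresolved = 0
    n_idfilt = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                qstart = int(fields[6])
                qend = int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}")
            if min_identity is not None and pident < min_identity:
                n_idfilt += 1
                continue
            q_start, q_end, strand = to_half_open(qstart, qend)
            if contig_lengths is not None:
                clen = contig_lengths.get(qseqid)
                if clen is not None and q_end > clen:
                    raise FormatError(
                        f"{path}:{lineno}: hit end {q_end} exceeds contig "
                        f"{qseqid} length {clen}"
                    )
            taxid: Optional[int] = accession_map.get(sseqid)
            if taxid is None:
                n_unresolved += 1
            elif taxonomy is not None and taxid not in taxonomy:
                raise FormatError(
                    f"{path}:{lineno}: taxid {taxid} (accession {sseqid}) "
                    f"absent from taxonomy"
                )
            # gene label priority: subject-title column 13 when present,
            # then the accession -> label map, then the accession itself
            if len(fields) >= 13 and fields[12]:
                label = fields[12]
            else:
                label = (gene_labels or {}).get(sseqid, sseqid)
            go = go_map.go_for(label) if go_map is not None else frozenset()
            hits.append(
                AlignmentHit(
                    query_id=qseqid,
                    q_start=q_start,
                    q_end=q_end,
                    strand=strand,
                    subject_acc=sseqid,
                    subject_taxid=taxid,
                    pct_identity=pident,
                    evalue=evalue,
                    bitscore=bitscore,
                    gene_label=label,
                    go_terms=go,
                )
            )
    if n_unresolved:
        logger.warning(
            "%s: %d hits with unresolvable accessions (kept for gene calling, "
            "excluded from taxonomy)",
            path,
            n_unresolved,
        )
    return AlignmentReadResult(hits, n_unresolved, n_idfilt)


# ---------------------------------------------------------------------------
# NCBI taxonomy dump
# ---------------------------------------------------------------------------

def _parse_dmp_line(line: str) -> List[str]:
    # NCBI dump rows end with "\t|" and separate fields with "\t|\t"
    return [f.strip() for f in line.rstrip("\n").rstrip("|\t").split("\t|\t")]


def read_taxonomy_dump(
    nodes_path: Union[str, Path], names_path: Union[str, Path]
) -> TaxonomyTree:
    """Parse nodes.dmp / names.dmp (pipe-and-tab dialect) into a tree.

    Only "scientific name" rows of names.dmp are used.  Orphans, duplicates
    and cycles raise ``ValueError``.
    """
    edges: List[Tuple[int, int, str]] = []
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise FormatError(f"{nodes_path}:{lineno}: expected taxid|parent|rank")
            try:
                edges.append((int(fields[0]), int(fields[1]), fields[2]))
            except ValueError:
                raise FormatError(f"{nodes_path}:{lineno}: non-integer taxid")
    names: Dict[int, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) >= 4 and fields[3] != "scientific name":
                continue
            names[int(fields[0])] = fields[1]
    return TaxonomyTree.from_edges(edges, names)


def write_taxonomy_dump(
    tree: TaxonomyTree, nodes_path: Union[str, Path], names_path: Union[str, Path]
) -> None:
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{n.parent}\t|\t{n.rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")


# ---------------------------------------------------------------------------
# Small TSV maps
# ---------------------------------------------------------------------------

def read_accession_map(path: Union[str, Path]) -> Dict[str, int]:
    """Two-column TSV: accession, taxid.  A header row is tolerated."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("accession", "acc"):
                continue
            try:
                out[fields[0]] = int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer taxid {fields[1]!r}")
    return out


def write_accession_map(path: Union[str, Path], mapping: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("accession\ttaxid\n")
        for acc in sorted(mapping):
            fh.write(f"{acc}\t{mapping[acc]}\n")


def read_gene_go_map(path: Union[str, Path]) -> GeneToGoMap:
    """TSV: gene_label, comma-separated GO ids[, optional category names]."""
    m = GeneToGoMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("gene_label", "gene"):
                continue
            gos = set()
            if len(fields) > 1 and fields[1]:
                for go in fields[1].split(","):
                    go = go.strip()
                    if not _GO_RE.match(go):
                        raise FormatError(f"{path}:{lineno}: malformed GO id {go!r}")
                    gos.add(go)
            m.gene_to_go[fields[0]] = gos
            if len(fields) > 2 and fields[2]:
                for go, name in zip(sorted(gos), fields[2].split(";")):
                    m.go_names.setdefault(go, name.strip())
    return m


def write_gene_go_map(path: Union[str, Path], m: GeneToGoMap) -> None:
    with open(path, "w") as fh:
        fh.write("gene_label\tgo_ids\n")
        for gene in sorted(m.gene_to_go):
            fh.write(f"{gene}\t{','.join(sorted(m.gene_to_go[gene]))}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["sample_id", "forefield", "substrate", "distance_m", "tn_mg_g", "toc_mg_g"]


def read_sample_metadata(path: Union[str, Path]) -> List[SampleMeta]:
    """Parse the study metadata TSV; enforces unique sample ids and the
    forefield/substrate vocabularies."""
    samples: List[SampleMeta] = []
    seen: Set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _META_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing metadata columns {missing}")
        idx = {c: header.index(c) for c in _META_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            sid = fields[idx["sample_id"]]
            if sid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                rec = SampleMeta(
                    sample_id=sid,
                    forefield=fields[idx["forefield"]],
                    substrate=fields[idx["substrate"]],
                    distance_m=float(fields[idx["distance_m"]]),
                    tn_mg_g=float(fields[idx["tn_mg_g"]]),
                    toc_mg_g=float(fields[idx["toc_mg_g"]]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
            samples.append(rec)
    return samples


def write_sample_metadata(path: Union[str, Path], samples: Iterable[SampleMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.forefield}\t{s.substrate}\t"
                f"{s.distance_m:g}\t{s.tn_mg_g:g}\t{s.toc_mg_g:g}\n"
            )
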