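"""Core data types for annotated prokaryotic genomes.

A genome here is a single circular chromosome treated as a linear sequence,
carrying an ordered gene list (1-based inclusive coordinates on the forward
strand, NCBI convention), optional COG functional categories, operon
membership, and an optional Bergey-style taxonomy code.  These are the raw
materials of the pipeline: ortholog assignment consumes genes, operons and
similarity hits; the barcode stage consumes the nucleotide sequence; the
evaluation stage consumes taxonomy codes.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-"}


class GenomeModelError(ValueError):
    """Raised on malformed genome annotation input."""


@dataclass
class Gene:
    """One protein-coding gene on the chromosome.

    ``index`` is the 0-based rank of the gene in chromosome order (sorted by
    ``start``); ``start``/``end`` are 1-based inclusive bp coordinates.
    """

    id: str
    start: int
    end: int
    strand: str = "+"
    cog: Optional[str] = None
    operon_id: Optional[str] = None
    seq: Optional[str] = None
    index: int = -1

    def __post_init__(self) -> None:
        if self.strand == "−":  # tolerate the typographic minus
            self.strand = "-"
        if self.strand not in _VALID_STRANDS:
            raise GenomeModelError(
                f"gene {self.id!r}: unknown strand symbol {self.strand!r}"
            )
        if self.end < self.start:
            raise GenomeModelError(
                f"gene {self.id!r}: end ({self.end}) < start ({self.start})"
            )

    def overlaps(self, start: int, end: int) -> bool:
        """Any-bp overlap with the 1-based inclusive interval [start, end]."""
        return self.start <= end and self.end >= start


@dataclass
class Operon:
    """A run of contiguous co-transcribed genes (length >= 1)."""

    id: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise GenomeModelError(f"operon {self.id!r} has no genes")


@dataclass
class AnnotatedGenome:
    """A single-chromosome genome with ordered genes and operon structure."""

    id: str
    name: str = ""
    sequence: Optional[str] = None
    genes: list[Gene] = field(default_factory=list)
    operons: list[Operon] = field(default_factory=list)
    bergey_code: Optional["BergeyCode"] = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_genes(
        cls,
        genome_id: str,
        genes: Iterable[Gene],
        *,
        name: str = "",
        sequence: Optional[str] = None,
        operons: Optional[list[Operon]] = None,
    ) -> "AnnotatedGenome":
        """Build a genome, sorting genes by start and assigning indices."""
        gene_list = sorted(genes, key=lambda g: (g.start, g.end, g.id))
        seen: set[str] = set()
        for rank, g in enumerate(gene_list):
            if g.id in seen:
                raise GenomeModelError(f"duplicate gene id {g.id!r} in {genome_id!r}")
            seen.add(g.id)
            g.index = rank
        gen = cls(
            id=genome_id,
            name=name or genome_id,
            sequence=sequence,
            genes=gene_list,
            operons=list(operons or []),
        )
        gen._check_coordinates()
        return gen

    def _check_coordinates(self) -> None:
        if self.sequence is None:
            return
        m = len(self.sequence)
        for g in self.genes:
            if g.start < 1 or g.end > m:
                raise GenomeModelError(
                    f"gene {g.id!r} coordinates [{g.start},{g.end}] outside "
                    f"sequence of length {m} in genome {self.id!r}"
                )

    # -- lookups ----------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._gene_index()[gene_id]
        except KeyError:
            raise GenomeModelError(
                f"unknown gene {gene_id!r} in genome {self.id!r}"
            ) from None

    def _gene_index(self) -> Mapping[str, Gene]:
        cached = getattr(self, "_gene_map", None)
        if cached is None or len(cached) != len(self.genes):
            cached = {g.id: g for g in self.genes}
            object.__setattr__(self, "_gene_map", cached)
        return cached

    def operon_of(self, gene_id: str) -> str:
        """Operon unit of a gene; genes outside any operon are singleton units."""
        g = self.gene(gene_id)
        return g.operon_id if g.operon_id is not None else f"__singleton__{g.id}"


@dataclass(frozen=True)
class SimilarityHit:
    """A directed pairwise gene similarity record (alignment-style)."""

    gene_a: str
    gene_b: str
    score: float
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise GenomeModelError(f"hit {self.gene_a}->{self.gene_b}: score must be > 0")
        if self.evalue < 0:
            raise GenomeModelError(f"hit {self.gene_a}->{self.gene_b}: negative E-value")
        if not 0.0 <= self.identity <= 100.0:
            raise GenomeModelError(
                f"hit {self.gene_a}->{self.gene_b}: identity outside [0,100]"
            )


# ---------------------------------------------------------------------------
# Bergey taxonomy codes
# ---------------------------------------------------------------------------

_BERGEY_RE = re.compile(r"^([AB])(\d+(?:\.\d+)*)$")


@dataclass(frozen=True)
class BergeyCode:
    """A dotted lineage code, e.g. ``B12.2.3.1.3`` = domain Bacteria, phylum
    XII (Proteobacteria), class II, order III, family I, genus III."""

    raw: str
    domain_tag: str
    ranks: tuple[int, ...]

    def __str__(self) -> str:
        return self.raw

    def lineage(self) -> tuple:
        return (self.domain_tag,) + self.ranks


def parse_bergey(code: str) -> BergeyCode:
    m = _BERGEY_RE.match(code.strip())
    if not m:
        raise GenomeModelError(f"malformed Bergey code {code!r}")
    domain, dotted = m.groups()
    ranks = tuple(int(x) for x in dotted.split("."))
    return BergeyCode(raw=code.strip(), domain_tag=domain, ranks=ranks)


def shared_depth(a: BergeyCode, b: BergeyCode) -> int:
    """Length of the longest common prefix of (domain, ranks...)."""
    depth = 0
    for x, y in zip(a.lineage(), b.lineage()):
        if x != y:
            break
        depth += 1
    return depth


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ("gene_id", "start", "end", "strand")


def read_gene_table(path, genome_id: str) -> AnnotatedGenome:
    """Read a tab-separated gene table (header: gene_id, start, end, strand,
    optional cog, seq).  Parsing is strict: a malformed row aborts with its
    row number."""
    genes: list[Gene] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenomeModelError(f"{path}: empty gene table") from None
        header = [h.strip() for h in header]
        for col in _GENE_COLUMNS:
            if col not in header:
                raise GenomeModelError(f"{path}: missing column {col!r}")
        idx = {name: header.index(name) for name in header}
        has_cog = "cog" in idx
        has_seq = "seq" in idx
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                cog = row[idx["cog"]].strip() if has_cog else ""
                seq = row[idx["seq"]].strip() if has_seq else ""
                gene = Gene(
                    id=row[idx["gene_id"]].strip(),
                    start=int(row[idx["start"]]),
                    end=int(row[idx["end"]]),
                    strand=row[idx["strand"]].strip(),
                    cog=cog or None,
                    seq=seq or None,
                )
            except (GenomeModelError, ValueError, IndexError) as exc:
                raise GenomeModelError(f"{path}: row {rownum}: {exc}") from None
            genes.append(gene)
    return AnnotatedGenome.from_genes(genome_id, genes)


def write_gene_table(genome: AnnotatedGenome, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", "start", "end", "strand", "cog", "seq"])
        for g in genome.genes:
            writer.writerow([g.id, g.start, g.end, g.strand, g.cog or "", g.seq or ""])


def read_operon_table(path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Read ``operon_id<TAB>gene1,gene2,...`` rows and stamp operon membership
    onto the genome's genes.

    Operons whose declared genes are not contiguous in chromosome order are
    split into maximal contiguous runs (with a warning) rather than rejected,
    since re-annotation occasionally breaks published operon calls.
    """
    declared: list[tuple[str, list[str]]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise GenomeModelError(f"{path}: row {rownum}: expected 2 columns")
            op_id = row[0].strip()
            gene_ids = [g.strip() for g in row[1].split(",") if g.strip()]
            if not gene_ids:
                raise GenomeModelError(f"{path}: row {rownum}: operon with no genes")
            declared.append((op_id, gene_ids))
    return attach_operons(genome, declared)


def attach_operons(
    genome: AnnotatedGenome, declared: Sequence[tuple[str, Sequence[str]]]
) -> AnnotatedGenome:
    """Validate declared operons against the genome and stamp membership."""
    assigned: dict[str, str] = {}
    operons: list[Operon] = []
    for op_id, gene_ids in declared:
        members = [genome.gene(gid) for gid in gene_ids]  # raises on unknown gene
        for g in members:
            if g.id in assigned:
                raise GenomeModelError(
                    f"gene {g.id!r} declared in two operons "
                    f"({assigned[g.id]!r} and {op_id!r})"
                )
        members.sort(key=lambda g: g.index)
        # split into maximal contiguous runs by gene index
        runs: list[list[Gene]] = [[members[0]]]
        for g in members[1:]:
            if g.index == runs[-1][-1].index + 1:
                runs[-1].append(g)
            else:
                runs.append([g])
        if len(runs) > 1:
            logger.warning(
                "operon %r in genome %r is not contiguous; split into %d runs",
                op_id, genome.id, len(runs),
            )
        for k, run in enumerate(runs):
            run_id = op_id if len(runs) == 1 else f"{op_id}.{k + 1}"
            operons.append(Operon(id=run_id, gene_ids=[g.id for g in run]))
            for g in run:
                g.operon_id = run_id
                assigned[g.id] = run_id
    genome.operons = operons
    return genome


def write_operon_table(genome: AnnotatedGenome, path) -> None:
    with open(path, "w", newline="") as fh:
        for op in genome.operons:
            fh.write(f"{op.id}\t{','.join(op.gene_ids)}\n")


def read_fasta(path, genome: Optional[AnnotatedGenome] = None) -> AnnotatedGenome:
    """Read a one-record FASTA; multi-record files are rejected because the
    pipeline's distance handles single chromosomes only."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise GenomeModelError(f"{path}: no FASTA record")
    if len(records) > 1:
        raise GenomeModelError(
            f"{path}: {len(records)} records; multi-chromosome genomes are "
            "outside the scope of this pipeline (single-chromosome only)"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    if genome is None:
        return AnnotatedGenome(id=rec.id, name=rec.description, sequence=seq)
    genome.sequence = seq
    genome._check_coordinates()
    return genome


def write_fasta(genome: AnnotatedGenome, path) -> None:
    if genome.sequence is None:
        raise GenomeModelError(f"genome {genome.id!r} has no sequence")
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=genome.name)
    SeqIO.write([rec], str(path), "fasta")


def read_similarity_hits(
    path,
    *,
    evalue_max: float = 1e-3,
) -> list[SimilarityHit]:
    """Read tabular similarity hits.

    Two dialects are accepted: the 5-column form
    ``qseqid sseqid bitscore evalue pident`` and the classic 12-column
    blast ``outfmt 6`` (qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore).  The candidate E-value cutoff is
    applied at read time; one (best-score) hit is kept per ordered pair.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip() == "qseqid":  # optional header
                continue
            try:
                if len(row) >= 12:
                    q, s = row[0].strip(), row[1].strip()
                    pident = float(row[2])
                    evalue = float(row[10])
                    score = float(row[11])
                elif len(row) >= 5:
                    q, s = row[0].strip(), row[1].strip()
                    score = float(row[2])
                    evalue = float(row[3])
                    pident = float(row[4])
                else:
                    raise ValueError("expected 5 or 12 columns")
                hit = SimilarityHit(q, s, score=score, evalue=evalue, identity=pident)
            except (ValueError, GenomeModelError) as exc:
                raise GenomeModelError(f"{path}: row {rownum}: {exc}") from None
            if hit.evalue > evalue_max:
                continue
            key = (hit.gene_a, hit.gene_b)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
    return [best[k] for k in sorted(best)]


def write_similarity_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["qseqid", "sseqid", "bitscore", "evalue", "pident"])
        for h in hits:
            writer.writerow([h.gene_a, h.gene_b, f"{h.score:g}", f"{h.evalue:g}",
                             f"{h.identity:.2f}"])


def read_taxonomy(path) -> dict[str, BergeyCode]:
    """Read ``genome_id<TAB>bergey_code`` lines."""
    out: dict[str, BergeyCode] = {}
    with open(path) as fh:
        for rownum, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenomeModelError(f"{path}: row {rownum}: expected 2 columns")
            taxon, code = parts[0].strip(), parts[1].strip()
            if taxon in out:
                raise GenomeModelError(f"{path}: row {rownum}: duplicate taxon {taxon!r}")
            out[taxon] = parse_bergey(code)
    return out


def write_taxonomy(codes: Mapping[str, BergeyCode], path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(codes):
            fh.write(f"{taxon}\t{codes[taxon].raw}\n")
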