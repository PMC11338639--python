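"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions
----------------------
Internally every gene interval is 0-based half-open (``start`` inclusive,
``end`` exclusive).  On-disk GFF3 is 1-based inclusive, as the format
dictates; conversion happens at the IO boundary and nowhere else.  The
annotation side table (gene_id, ko, cog, product) is kept separate from the
GFF3 attributes, mirroring how annotation-tool output is consumed in
practice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
KO_PATTERN = re.compile(r"^K\d{5}$")
COG_PATTERN = re.compile(r"^COG\d{4}$")

TAXONOMY_RANKS = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class GeneRecord:
    """One annotated protein-coding gene.

    ``start``/``end`` are nucleotide positions on the contig, 0-based
    half-open.  ``rank`` is the ordinal of the gene along its contig
    (0-based, ordered by start).  ``ko_ids``/``cog_ids`` hold the full set
    of functional annotations; a gene may carry several KOs and all are
    retained.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank: int = 0
    protein: str = ""
    ko_ids: set[str] = field(default_factory=set)
    cog_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.end - self.start < 3:
            raise ValueError(f"gene {self.gene_id}: interval shorter than one codon")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        bad = set(self.protein) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id}: invalid protein characters {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def annotations(self) -> set[str]:
        return self.ko_ids | self.cog_ids


@dataclass
class GenomeBundle:
    """One genome: contig sequences, ordered gene records and taxonomy."""

    genome_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    contigs: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id in self.contigs and g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of contig {g.contig_id}"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_nucleotide(self, gene_id: str) -> str:
        """Nucleotide sequence of a gene in coding orientation."""
        g = self.gene(gene_id)
        seq = self.contigs[g.contig_id][g.start : g.end]
        return reverse_complement(seq) if g.strand == "-" else seq


@dataclass
class TabularHit:
    """One row of the 12-column tabular homology-search dialect.

    ``q_start`` .. ``s_end`` are 1-based inclusive, as on disk.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Sequences are uppercased; blank lines are tolerated.  Duplicate ids and
    empty sequences raise :class:`FormatError`.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"empty sequence for record {current_id!r}")
        records.append((current_id, seq.upper()))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise FormatError("FASTA header with empty id")
                if current_id in seen:
                    raise FormatError(f"duplicate FASTA id {current_id!r}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
    _flush()
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

_TSV_GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "strand", "ko", "cog"]


def _split_ids(cell: str) -> set[str]:
    return {tok for tok in cell.split(";") if tok and tok != "-"}


def _assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for members in by_contig.values():
        members.sort(key=lambda g: g.start)
        for i, g in enumerate(members):
            g.rank = i
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def read_gene_table(
    path: str | Path, dialect: str, genome_id: str = ""
) -> list[GeneRecord]:
    """Read gene coordinates from GFF3 (1-based inclusive) or TSV.

    The TSV dialect carries columns ``gene_id contig_id start end strand ko
    cog`` with coordinates already 0-based half-open and ';'-separated
    annotation cells.  Ranks are recomputed from sorted starts per contig in
    both dialects.
    """
    if dialect not in {"gff3", "tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        if dialect == "gff3":
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                seqid, _src, ftype, start1, end1, _score, strand, _frame, attrs = cols
                if ftype != "CDS":
                    continue
                m = re.search(r"(?:^|;)ID=([^;]+)", attrs)
                if not m:
                    raise FormatError(f"{path}:{lineno}: CDS without ID attribute")
                start = int(start1) - 1
                end = int(end1)
                if end <= start:
                    raise FormatError(f"{path}:{lineno}: end <= start after conversion")
                genes.append(
                    GeneRecord(
                        gene_id=m.group(1),
                        genome_id=genome_id,
                        contig_id=seqid,
                        start=start,
                        end=end,
                        strand=strand,
                    )
                )
        else:
            header = fh.readline().rstrip("\n").split("\t")
            if header != _TSV_GENE_COLUMNS:
                raise FormatError(
                    f"{path}: TSV gene table header must be {_TSV_GENE_COLUMNS}"
                )
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                if len(cols) != len(_TSV_GENE_COLUMNS):
                    raise FormatError(f"{path}:{lineno}: wrong column count")
                gene_id, contig_id, start, end, strand, ko, cog = cols
                start_i, end_i = int(start), int(end)
                if end_i <= start_i:
                    raise FormatError(f"{path}:{lineno}: end <= start")
                genes.append(
                    GeneRecord(
                        gene_id=gene_id,
                        genome_id=genome_id,
                        contig_id=contig_id,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        ko_ids=_split_ids(ko),
                        cog_ids=_split_ids(cog),
                    )
                )
    return _assign_ranks(genes)


def write_gff3(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "codhscan",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation / taxonomy / counts side tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, tuple[set[str], set[str]]]:
    """Read the annotation TSV (gene_id, ko, cog, product) keyed by gene_id."""
    out: dict[str, tuple[set[str], set[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "ko", "cog"]:
            raise FormatError(f"{path}: annotation header must start gene_id/ko/cog")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: wrong column count")
            out[cols[0]] = (_split_ids(cols[1]), _split_ids(cols[2]))
    return out


def write_annotation_table(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tko\tcog\tproduct\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{';'.join(sorted(g.ko_ids)) or '-'}"
                f"\t{';'.join(sorted(g.cog_ids)) or '-'}\t-\n"
            )


def apply_annotations(
    genes: Sequence[GeneRecord], annotations: Mapping[str, tuple[set[str], set[str]]]
) -> None:
    for g in genes:
        if g.gene_id in annotations:
            ko, cog = annotations[g.gene_id]
            g.ko_ids = set(ko)
            g.cog_ids = set(cog)


def read_taxonomy_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read the taxonomy TSV: genome_id plus the seven rank columns."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["genome_id", *TAXONOMY_RANKS]:
            raise FormatError(f"{path}: bad taxonomy header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            out[cols[0]] = dict(zip(TAXONOMY_RANKS, cols[1:]))
    return out


def write_taxonomy_table(path: str | Path, bundles: Iterable[GenomeBundle]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(TAXONOMY_RANKS) + "\n")
        for b in bundles:
            fh.write(
                b.genome_id
                + "\t"
                + "\t".join(b.taxonomy.get(r, "") for r in TAXONOMY_RANKS)
                + "\n"
            )


def read_counts_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a per-gene counts TSV (gene_id, length_nt, count)."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "length_nt", "count"]:
            raise FormatError(f"{path}: bad counts header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, length_nt, count = line.split("\t")
            out[gene_id] = (int(length_nt), int(count))
    return out


# ---------------------------------------------------------------------------
# Tabular hits
# ---------------------------------------------------------------------------

def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            hits.append(
                TabularHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                )
            )
    return hits


def write_tabular_hits(path: str | Path, hits: Iterable[TabularHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genome bundle directory layout
# ---------------------------------------------------------------------------

def write_genome_bundle(directory: str | Path, bundle: GenomeBundle) -> Path:
    """Write one genome as contigs.fna / proteins.faa / genes.gff3 / annotations.tsv."""
    d = Path(directory) / bundle.genome_id
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(d / "contigs.fna", bundle.contigs.items())
    write_fasta(d / "proteins.faa", [(g.gene_id, g.protein) for g in bundle.genes])
    write_gff3(d / "genes.gff3", bundle.genes)
    write_annotation_table(d / "annotations.tsv", bundle.genes)
    return d


def read_genome_bundle(
    directory: str | Path, taxonomy: Mapping[str, dict[str, str]] | None = None
) -> GenomeBundle:
    d = Path(directory)
    genome_id = d.name
    contigs = dict(read_fasta(d / "contigs.fna"))
    genes = read_gene_table(d / "genes.gff3", "gff3", genome_id=genome_id)
    apply_annotations(genes, read_annotation_table(d / "annotations.tsv"))
    proteins = dict(read_fasta(d / "proteins.faa"))
    for g in genes:
        g.protein = proteins.get(g.gene_id, "")
    tax = dict(taxonomy.get(genome_id, {})) if taxonomy else {}
    return GenomeBundle(genome_id=genome_id, taxonomy=tax, contigs=contigs, genes=genes)


def read_genome_collection(directory: str | Path) -> list[GenomeBundle]:
    """Read every genome bundle under a directory (plus optional taxonomy.tsv)."""
    d = Path(directory)
    tax_path = d / "taxonomy.tsv"
    taxonomy = read_taxonomy_table(tax_path) if tax_path.exists() else {}
    bundles = []
    for sub in sorted(p for p in d.iterdir() if p.is_dir()):
        if (sub / "contigs.fna").exists():
            bundles.append(read_genome_bundle(sub, taxonomy))
    return bundles
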