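"""Read assignment and abundance quantification for metatranscriptomes.

A desk-scale pseudo-mapper replaces an external aligner: reference genes
are indexed by exact 31-mers (both strands) and each read votes with its
k-mers; it is assigned to the gene collecting the most matching k-mers
provided that gene collects at least half of them, and ties are discarded
as ambiguous.  Externally computed per-gene count tables can be supplied
instead, keeping parity with aligner-based workflows.

Abundance measures:

* RPKM_g = count_g / ((length_g / 1e3) * (mapped_reads / 1e6)),
* TPM_g  = RPKM_g * 1e6 / sum(RPKM)  (sums to 1e6 whenever any read maps).

``mapped_reads`` is the number of reads assigned to the provided
reference set, not the total sequenced reads.  Detection of pCODH in a
dataset requires >= 1 assigned read on a pCODH gene.  Covered positions
(depth >= 1) are reported per gene to support cover-length filters
downstream; no filter is applied here.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import reverse_complement

DEFAULT_K = 31
DEFAULT_MIN_HIT_FRACTION = 0.5


@dataclass
class TranscriptQuant:
    dataset_id: str
    counts: dict[str, int]
    lengths: dict[str, int]
    rpkm: dict[str, float]
    tpm: dict[str, float]
    covered_positions: dict[str, int]
    total_reads: int
    mapped_reads: int
    ambiguous_reads: int

    @property
    def unassigned_reads(self) -> int:
        return self.total_reads - self.mapped_reads - self.ambiguous_reads


def build_kmer_index(
    reference_genes: Sequence[tuple[str, str]], k: int = DEFAULT_K
) -> dict[str, set[str]]:
    """Exact k-mer -> gene-id index over both strands."""
    seen: set[str] = set()
    index: dict[str, set[str]] = {}
    for gene_id, seq in reference_genes:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        if len(seq) < k:
            raise ValueError(f"gene {gene_id} shorter than k={k}")
        for strand_seq in (seq, reverse_complement(seq)):
            for i in range(len(strand_seq) - k + 1):
                index.setdefault(strand_seq[i : i + k], set()).add(gene_id)
    return index


def assign_read(
    read: str,
    index: Mapping[str, set[str]],
    k: int = DEFAULT_K,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
) -> str | None:
    """Gene id for one read, or None (unassigned) / "" (ambiguous tie)."""
    n_kmers = len(read) - k + 1
    if n_kmers < 1:
        raise ValueError("read shorter than k")
    votes: dict[str, int] = {}
    for i in range(n_kmers):
        for gid in index.get(read[i : i + k], ()):
            votes[gid] = votes.get(gid, 0) + 1
    if not votes:
        return None
    best = max(votes.values())
    if best < min_hit_fraction * n_kmers:
        return None
    winners = [gid for gid, v in votes.items() if v == best]
    if len(winners) > 1:
        return ""  # ambiguous
    return winners[0]


def assign_reads(
    reads: Iterable[tuple[str, str]],
    reference_genes: Sequence[tuple[str, str]],
    k: int = DEFAULT_K,
    min_hit_fraction: float = DEFAULT_MIN_HIT_FRACTION,
    dataset_id: str = "dataset",
) -> TranscriptQuant:
    """Assign reads to genes and quantify (counts, coverage, RPKM, TPM)."""
    index = build_kmer_index(reference_genes, k)
    gene_seqs = dict(reference_genes)
    counts = {gid: 0 for gid, _ in reference_genes}
    coverage = {gid: np.zeros(len(seq), dtype=bool) for gid, seq in reference_genes}
    total = mapped = ambiguous = 0
    for _rid, seq in reads:
        total += 1
        target = assign_read(seq, index, k, min_hit_fraction)
        if target is None:
            continue
        if target == "":
            ambiguous += 1
            continue
        counts[target] += 1
        mapped += 1
        ref = gene_seqs[target]
        pos = ref.find(seq)
        if pos < 0:
            pos = ref.find(reverse_complement(seq))
        if pos >= 0:
            coverage[target][pos : pos + len(seq)] = True
    lengths = {gid: len(seq) for gid, seq in reference_genes}
    rpkm = compute_rpkm(counts, lengths, mapped)
    return TranscriptQuant(
        dataset_id=dataset_id,
        counts=counts,
        lengths=lengths,
        rpkm=rpkm,
        tpm=compute_tpm(rpkm),
        covered_positions={gid: int(cov.sum()) for gid, cov in coverage.items()},
        total_reads=total,
        mapped_reads=mapped,
        ambiguous_reads=ambiguous,
    )


def quant_from_counts(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    dataset_id: str = "dataset",
) -> TranscriptQuant:
    """Build a quantification from an externally supplied count table."""
    mapped = sum(counts.values())
    rpkm = compute_rpkm(counts, lengths, mapped)
    return TranscriptQuant(
        dataset_id=dataset_id,
        counts=dict(counts),
        lengths=dict(lengths),
        rpkm=rpkm,
        tpm=compute_tpm(rpkm),
        covered_positions={gid: 0 for gid in counts},
        total_reads=mapped,
        mapped_reads=mapped,
        ambiguous_reads=0,
    )


def compute_rpkm(
    counts: Mapping[str, int], lengths: Mapping[str, int], mapped_reads: int
) -> dict[str, float]:
    """Reads per kilobase of transcript per million mapped reads."""
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be >= 0")
    out: dict[str, float] = {}
    for gid, count in counts.items():
        length = lengths[gid]
        if length <= 0:
            raise ValueError(f"gene {gid}: non-positive length")
        if mapped_reads == 0:
            out[gid] = 0.0
        else:
            out[gid] = count / ((length / 1e3) * (mapped_reads / 1e6))
    return out


def compute_tpm(rpkm: Mapping[str, float]) -> dict[str, float]:
    """RPKM renormalized to sum to 1e6 (zero vector stays zero)."""
    total = sum(rpkm.values())
    if total == 0:
        return {gid: 0.0 for gid in rpkm}
    return {gid: v * 1e6 / total for gid, v in rpkm.items()}


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class GeneMeta:
    gene_id: str
    genome_id: str = ""
    phylum: str = ""
    order: str = ""
    genus: str = ""
    context_type: str = ""
    is_pcodh: bool = True


@dataclass
class DatasetSummary:
    dataset_id: str
    pcodh_detected: bool
    pcodh_reads: int
    rpkm_by_taxon: dict[str, dict[str, float]] = field(default_factory=dict)
    read_fraction_by_taxon: dict[str, dict[str, float]] = field(default_factory=dict)
    rpkm_by_context: dict[str, float] = field(default_factory=dict)
    read_fraction_by_context: dict[str, float] = field(default_factory=dict)
    covered_positions: dict[str, int] = field(default_factory=dict)


def detect_and_aggregate(
    quant: TranscriptQuant,
    gene_metadata: Mapping[str, GeneMeta],
    taxon_ranks: Sequence[str] = ("phylum", "order", "genus"),
) -> DatasetSummary:
    """Per-dataset detection flag plus taxon- and context-level aggregates."""
    expressed = [gid for gid, c in quant.counts.items() if c > 0]
    missing = [gid for gid in expressed if gid not in gene_metadata]
    if missing:
        raise ValueError(f"metadata missing for expressed gene(s): {missing}")
    pcodh_reads = sum(
        c for gid, c in quant.counts.items() if gene_metadata[gid].is_pcodh
    )
    summary = DatasetSummary(
        dataset_id=quant.dataset_id,
        pcodh_detected=pcodh_reads >= 1,
        pcodh_reads=pcodh_reads,
        covered_positions=dict(quant.covered_positions),
    )
    total_counts = sum(quant.counts.values())
    for rank in taxon_ranks:
        rpkm_sums: dict[str, float] = {}
        count_sums: dict[str, int] = {}
        for gid, c in quant.counts.items():
            label = getattr(gene_metadata[gid], rank) or "unassigned"
            rpkm_sums[label] = rpkm_sums.get(label, 0.0) + quant.rpkm[gid]
            count_sums[label] = count_sums.get(label, 0) + c
        summary.rpkm_by_taxon[rank] = rpkm_sums
        summary.read_fraction_by_taxon[rank] = {
            lab: (c / total_counts if total_counts else 0.0)
            for lab, c in count_sums.items()
        }
    ctx_rpkm: dict[str, float] = {}
    ctx_counts: dict[str, int] = {}
    for gid, c in quant.counts.items():
        ctx = gene_metadata[gid].context_type or "unclassified"
        ctx_rpkm[ctx] = ctx_rpkm.get(ctx, 0.0) + quant.rpkm[gid]
        ctx_counts[ctx] = ctx_counts.get(ctx, 0) + c
    summary.rpkm_by_context = ctx_rpkm
    summary.read_fraction_by_context = {
        ctx: (c / total_counts if total_counts else 0.0)
        for ctx, c in ctx_counts.items()
    }
    return summary


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ (gzip allowed)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads: list[tuple[str, str]] = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            reads.append((header[1:].strip(), seq))
    return reads


def read_gene_metadata(path: str | Path) -> dict[str, GeneMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, GeneMeta] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        out[d["gene_id"]] = GeneMeta(
            gene_id=d["gene_id"],
            genome_id=d.get("genome_id", ""),
            phylum=d.get("phylum", ""),
            order=d.get("order", ""),
            genus=d.get("genus", ""),
            context_type=d.get("context_type", ""),
            is_pcodh=d.get("is_pcodh", "true").lower() != "false",
        )
    return out


def write_quant_table(path: str | Path, quant: TranscriptQuant) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_nt\tcount\tcovered_positions\trpkm\ttpm\n")
        for gid in quant.counts:
            fh.write(
                f"{gid}\t{quant.lengths[gid]}\t{quant.counts[gid]}"
                f"\t{quant.covered_positions.get(gid, 0)}"
                f"\t{quant.rpkm[gid]:.6g}\t{quant.tpm[gid]:.6g}\n"
            )
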