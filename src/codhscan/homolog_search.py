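"""Local-alignment mining of candidate Ni-CODH genes and clade assignment.

Candidates are detected by Smith-Waterman local alignment (affine gaps,
BLOSUM62 by default) of each annotated protein against a set of
clade-representative catalytic-subunit references, filtered on three
cutoffs: E-value <= 1e-10, alignment length >= 200 aa and identity >= 30 %.
"a sequence length of 200 aa" is read as alignment length in columns, the
usual reading of tabular-output filters.  E-values follow the
Karlin-Altschul formula E = m * n * 2^(-bits) with configurable (lambda, K)
and effective database size, defaulting to gapped BLOSUM62 statistics.

The clade of a surviving gene is that of the reference with the highest
alignment identity (ties: higher bit score, then lexicographically smaller
clade label).  The same machinery screens for Mo-CODH large-subunit (CoxL)
homologs, which must additionally carry the exact AYRCSFR active-site
motif.  Precomputed 12-column tabular hits may be ingested instead of
running the in-house search; both paths share the threshold logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import PROTEIN_ALPHABET, GenomeBundle, TabularHit

MO_CODH_MOTIF = "AYRCSFR"


@dataclass
class SearchParams:
    """Thresholds and scoring model of the homolog search."""

    evalue_max: float = 1e-10
    identity_min_pct: float = 30.0
    alnlen_min_aa: int = 200
    matrix: str = "BLOSUM62"
    gap_open: int = 11  # gap of length g costs gap_open + g * gap_extend
    gap_extend: int = 1
    db_size_aa: float = 1e7
    karlin_lambda: float = 0.267  # gapped BLOSUM62, open 11 / extend 1
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_max <= 0 or self.alnlen_min_aa <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.identity_min_pct <= 100:
            raise ValueError("identity_min_pct must be in (0, 100]")

    def bit_score(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: float, query_length: int) -> float:
        return query_length * self.db_size_aa * 2 ** (-self.bit_score(raw_score))


@dataclass
class CladeCall:
    gene_id: str
    clade: str
    best_identity_pct: float
    best_reference_id: str


@lru_cache(maxsize=8)
def _local_aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    # Biopython charges open_gap_score on the first gap residue, so a
    # length-g gap costs open+extra*(g-1); shift by one extend to match the
    # open + g*extend convention.
    return PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )


def _validate_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")


def align_local(
    query_protein: str,
    subject_protein: str,
    params: SearchParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> TabularHit:
    """Smith-Waterman local alignment reported as one tabular hit.

    Identity is matches / alignment columns (gap columns included) * 100.
    """
    params = params or SearchParams()
    _validate_protein(query_protein, query_id)
    _validate_protein(subject_protein, subject_id)
    aligner = _local_aligner(params.matrix, params.gap_open, params.gap_extend)
    alignment = aligner.align(query_protein, subject_protein)[0]
    counts = alignment.counts()
    gaps = counts.internal_gaps
    columns = counts.identities + counts.mismatches + gaps
    q_blocks, s_blocks = alignment.aligned
    gap_opens = (
        counts.open_internal_insertions + counts.open_internal_deletions
    )
    return TabularHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * counts.identities / columns if columns else 0.0,
        aln_length=max(columns, 1),
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
        evalue=params.evalue(alignment.score, len(query_protein)),
        bit_score=params.bit_score(alignment.score),
    )


def passes_thresholds(hit: TabularHit, params: SearchParams) -> bool:
    """Shared pass/fail rule for in-house and ingested tabular hits."""
    return (
        hit.evalue <= params.evalue_max
        and hit.pct_identity >= params.identity_min_pct
        and hit.aln_length >= params.alnlen_min_aa
    )


def find_candidates(
    bundle: GenomeBundle,
    reference_set: Sequence[tuple[str, str]],
    params: SearchParams | None = None,
) -> list[TabularHit]:
    """All (reference, gene) hits passing every threshold, one best per pair.

    A gene is a candidate when at least one reference passes; candidacy is
    deliberately inclusive because the stricter motif filter follows.
    """
    params = params or SearchParams()
    if not reference_set:
        raise ValueError("empty reference set")
    aligner = _local_aligner(params.matrix, params.gap_open, params.gap_extend)
    hits: list[TabularHit] = []
    for ref_id, ref_seq in reference_set:
        _validate_protein(ref_seq, ref_id)
        for gene in bundle.genes:
            if not gene.protein:
                continue
            # Score-only pass first: the E-value depends on the raw score
            # alone, so sub-threshold pairs skip the traceback entirely.
            score = aligner.score(ref_seq, gene.protein)
            if params.evalue(score, len(ref_seq)) > params.evalue_max:
                continue
            hit = align_local(
                ref_seq, gene.protein, params, query_id=ref_id,
                subject_id=gene.gene_id,
            )
            if passes_thresholds(hit, params):
                hits.append(hit)
    return hits


def candidate_gene_ids(hits: Iterable[TabularHit]) -> list[str]:
    seen: dict[str, None] = {}
    for h in hits:
        seen.setdefault(h.subject_id, None)
    return list(seen)


def assign_clade(
    gene_id: str,
    hits: Sequence[TabularHit],
    clade_map: Mapping[str, str],
) -> CladeCall:
    """Clade of the passing reference with maximum identity.

    Ties break by higher bit score, then lexicographically smaller clade
    label.
    """
    mine = [h for h in hits if h.subject_id == gene_id]
    if not mine:
        raise ValueError(f"no passing hit for gene {gene_id}")
    best = min(
        mine,
        key=lambda h: (-h.pct_identity, -h.bit_score, clade_map[h.query_id]),
    )
    return CladeCall(
        gene_id=gene_id,
        clade=clade_map[best.query_id],
        best_identity_pct=best.pct_identity,
        best_reference_id=best.query_id,
    )


def find_mo_codh(
    bundle: GenomeBundle,
    coxl_reference: tuple[str, str],
    params: SearchParams | None = None,
) -> list[str]:
    """Genes passing the thresholds against CoxL AND bearing AYRCSFR exactly."""
    params = params or SearchParams()
    hits = find_candidates(bundle, [coxl_reference], params)
    out: list[str] = []
    for gid in candidate_gene_ids(hits):
        if MO_CODH_MOTIF in bundle.gene(gid).protein:
            out.append(gid)
    return out
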