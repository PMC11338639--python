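"""End-to-end orchestration: search -> motif filter -> context -> profile.

Thin glue over the stage modules so the CLI, the tests and scripted runs
share one code path.  The stage order follows the discovery workflow:
homology candidates first, then the motif filter, and clades are reported
for the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .context_classifier import ContextWindow, classify_window
from .homolog_search import (
    CladeCall,
    SearchParams,
    assign_clade,
    candidate_gene_ids,
    find_candidates,
)
from .io_formats import GenomeBundle, TabularHit
from .motif_validator import MotifConfig, MotifReport, check_motifs


@dataclass
class ScreenResult:
    """Everything the discovery screen produced for one genome collection."""

    hits: list[TabularHit] = field(default_factory=list)
    candidates: dict[str, list[str]] = field(default_factory=dict)  # genome -> genes
    motif_reports: dict[str, MotifReport] = field(default_factory=dict)  # gene -> report
    clade_calls: dict[str, CladeCall] = field(default_factory=dict)  # validated gene
    validated: dict[str, list[str]] = field(default_factory=dict)  # genome -> genes

    @property
    def validated_gene_ids(self) -> list[str]:
        return [g for genes in self.validated.values() for g in genes]

    @property
    def validated_genome_ids(self) -> list[str]:
        return [gid for gid, genes in self.validated.items() if genes]


def screen_collection(
    bundles: Sequence[GenomeBundle],
    references: Sequence[tuple[str, str]],
    clade_map: Mapping[str, str],
    motif_config: MotifConfig,
    params: SearchParams | None = None,
) -> ScreenResult:
    """Detect candidate cooS genes, validate motifs, assign clades."""
    params = params or SearchParams()
    result = ScreenResult()
    for bundle in bundles:
        hits = find_candidates(bundle, references, params)
        result.hits.extend(hits)
        candidates = candidate_gene_ids(hits)
        result.candidates[bundle.genome_id] = candidates
        survivors: list[str] = []
        for gene_id in candidates:
            report = check_motifs(
                bundle.gene(gene_id).protein, motif_config, gene_id=gene_id
            )
            result.motif_reports[gene_id] = report
            if report.overall_pass:
                survivors.append(gene_id)
                result.clade_calls[gene_id] = assign_clade(gene_id, hits, clade_map)
        result.validated[bundle.genome_id] = survivors
    return result


def classify_contexts(
    bundles: Sequence[GenomeBundle],
    screen: ScreenResult,
    radius: int = 15,
) -> dict[str, ContextWindow]:
    """Context window per validated gene, keyed by gene id."""
    by_id = {b.genome_id: b for b in bundles}
    windows: dict[str, ContextWindow] = {}
    for genome_id, genes in screen.validated.items():
        for gene_id in genes:
            windows[gene_id] = classify_window(by_id[genome_id], gene_id, radius)
    return windows
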