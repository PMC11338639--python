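"""Genomic-context typing of validated pCODH (cooS) genes.

The context of a focal cooS gene is the set of genes within +/-15 rank
positions on its contig (strand-agnostic, truncated at contig edges).
KO/COG markers in the window assign one of eight context types; windows
with no marker evidence are ``unclassified``.  When several types have
evidence the highest-precedence type wins, in the order WLP > PEPCK >
FNOR > ABC_transporter > Fe_hydrogenase > MFS_transporter >
uncharacterized_dehydrogenase > cysteine_synthase; co-occurring secondary
evidence is preserved in ``marker_evidence``, never discarded.

Auxiliary genes with interpretive value (oxyR, narGHIJK, pflAB, hypAB,
cooC, cooF) are tallied per window but never drive the type call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .io_formats import GeneRecord, GenomeBundle

DEFAULT_RADIUS = 15

TYPE_PRECEDENCE = (
    "WLP",
    "PEPCK",
    "FNOR",
    "ABC_transporter",
    "Fe_hydrogenase",
    "MFS_transporter",
    "uncharacterized_dehydrogenase",
    "cysteine_synthase",
)

UNCLASSIFIED = "unclassified"


@dataclass
class MarkerRule:
    """Markers of one context type.

    ``groups`` is a list of marker-id sets; the rule fires when every group
    has at least one match in the window.  Single-group rules are the
    common any-of case; the ABC transporter uses three groups, one per
    subunit, because its markers are a unit.
    """

    type_name: str
    groups: list[set[str]]


#: KO/COG markers of the eight context types.
DEFAULT_MARKER_RULES: list[MarkerRule] = [
    MarkerRule("WLP", [{"K14138", "COG1614"}]),  # acsB
    MarkerRule("PEPCK", [{"K01610", "COG1866"}]),  # pckA
    MarkerRule("FNOR", [{"COG1251"}]),
    MarkerRule(
        "ABC_transporter",
        [{"K02049", "COG0715"}, {"K02050", "COG0600"}, {"K02051", "COG1116"}],
    ),
    MarkerRule("Fe_hydrogenase", [{"COG4624"}]),
    MarkerRule("MFS_transporter", [{"COG2223", "K08177"}]),  # NarK / OxlT
    MarkerRule("uncharacterized_dehydrogenase", [{"K00004", "COG1063"}]),
    MarkerRule("cysteine_synthase", [{"K01738", "COG0031"}]),
]

#: Auxiliary gene symbols tallied per window.
DEFAULT_AUX_RULES: dict[str, set[str]] = {
    "oxyR": {"K04761", "COG0583"},
    "narGHIJK": {"K00370", "K00371", "K00373", "K00374", "K02575"},
    "pflAB": {"K04069", "K00656"},
    "hypAB": {"K04651", "K04652"},
    "cooC": {"K07321"},
    "cooF": {"K00196", "COG0437", "COG1142"},
}


@dataclass
class ContextWindow:
    focal_gene_id: str
    genome_id: str
    contig_id: str
    member_genes: list[GeneRecord]
    offsets: list[int]
    marker_evidence: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    assigned_type: str = UNCLASSIFIED
    auxiliary: dict[str, list[str]] = field(default_factory=dict)


def extract_window(
    bundle: GenomeBundle, focal_gene_id: str, radius: int = DEFAULT_RADIUS
) -> ContextWindow:
    """Genes within ``radius`` ranks of the focal gene on its contig."""
    focal = bundle.gene(focal_gene_id)  # raises KeyError if unknown
    members: list[tuple[int, GeneRecord]] = []
    for g in bundle.genes:
        if g.contig_id != focal.contig_id:
            continue
        offset = g.rank - focal.rank
        if abs(offset) <= radius:
            members.append((offset, g))
    members.sort(key=lambda t: t[0])
    return ContextWindow(
        focal_gene_id=focal_gene_id,
        genome_id=bundle.genome_id,
        contig_id=focal.contig_id,
        member_genes=[g for _, g in members],
        offsets=[o for o, _ in members],
    )


def match_markers(
    window: ContextWindow, marker_rules: list[MarkerRule] | None = None
) -> dict[str, list[tuple[str, str]]]:
    """Evidence per type: member genes whose KO/COG sets hit the markers.

    The focal gene is excluded (it may carry misleading annotations).
    Multi-group rules report evidence only when every group is matched
    somewhere in the window.
    """
    rules = marker_rules if marker_rules is not None else DEFAULT_MARKER_RULES
    evidence: dict[str, list[tuple[str, str]]] = {}
    for rule in rules:
        per_group: list[list[tuple[str, str]]] = []
        for group in rule.groups:
            found = []
            for g in window.member_genes:
                if g.gene_id == window.focal_gene_id:
                    continue
                matched = g.annotations & group
                for m in sorted(matched):
                    found.append((g.gene_id, m))
            per_group.append(found)
        if all(per_group):
            evidence[rule.type_name] = [hit for group in per_group for hit in group]
    return evidence


def assign_type(marker_evidence: Mapping[str, list[tuple[str, str]]]) -> str:
    """Highest-precedence type with evidence; ``unclassified`` if none."""
    for type_name in TYPE_PRECEDENCE:
        if marker_evidence.get(type_name):
            return type_name
    return UNCLASSIFIED


def tally_auxiliary(
    window: ContextWindow, aux_rules: Mapping[str, set[str]] | None = None
) -> dict[str, list[str]]:
    rules = aux_rules if aux_rules is not None else DEFAULT_AUX_RULES
    out: dict[str, list[str]] = {}
    for symbol, markers in rules.items():
        genes = [
            g.gene_id
            for g in window.member_genes
            if g.gene_id != window.focal_gene_id and g.annotations & markers
        ]
        if genes:
            out[symbol] = genes
    return out


def classify_window(
    bundle: GenomeBundle,
    focal_gene_id: str,
    radius: int = DEFAULT_RADIUS,
    marker_rules: list[MarkerRule] | None = None,
    aux_rules: Mapping[str, set[str]] | None = None,
) -> ContextWindow:
    """Extract, match, type and tally one focal gene's context."""
    window = extract_window(bundle, focal_gene_id, radius)
    window.marker_evidence = match_markers(window, marker_rules)
    window.assigned_type = assign_type(window.marker_evidence)
    window.auxiliary = tally_auxiliary(window, aux_rules)
    return window


# ---------------------------------------------------------------------------
# Rules file IO
# ---------------------------------------------------------------------------

def write_marker_rules(path: str | Path, rules: list[MarkerRule]) -> None:
    doc = {r.type_name: [sorted(g) for g in r.groups] for r in rules}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_marker_rules(path: str | Path) -> list[MarkerRule]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [MarkerRule(name, [set(g) for g in groups]) for name, groups in doc.items()]
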