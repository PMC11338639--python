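"""Active-site / metal-cluster motif validation of candidate Ni-CODH genes.

A candidate that passed the homology thresholds is confirmed as a putative
Ni-CODH (pCODH) only if it conserves, with zero substitutions or deletions,
the residues of the five metal clusters (two Ni-Fe-S C-clusters, the
cubane-type 4Fe-4S B-cluster, the interface 4Fe-4S D-cluster) and the two
acid-base catalytic residues of the CooS catalytic subunit.

Residue coordinates are never hard-coded in the logic: they ship as an
editable :class:`MotifConfig` anchored to a named reference sequence.  Each
candidate is aligned pairwise (global, affine gaps) to the anchor and the
configured anchor positions are mapped through the alignment.  The same
machinery provides the Cys-Cys active-site check used to tell genuine
pyruvate formate-lyase (PFL) sequences apart from PFL-like proteins under
KO K00656.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio.Align import PairwiseAligner, substitution_matrices

INTACT = "intact"
SUBSTITUTED = "substituted"
DELETED = "deleted"
UNALIGNED = "unaligned"

#: Minimum candidate-to-anchor alignment identity (fraction) below which the
#: position mapping is considered unreliable and every site reports
#: ``unaligned`` (a failing state distinct from substitution).
MIN_MAPPING_IDENTITY = 0.20

#: Default site layout used by the synthetic reference set: 1-based anchor
#: positions and the residue set required at each.  For real data the
#: config must be rebuilt against an experimentally characterized anchor
#: (e.g. a CooSII-type catalytic subunit); this layout is a synthetic
#: stand-in with the same structure (two C-clusters, B- and D-cluster,
#: two acid-base catalysts).
DEFAULT_SITE_LAYOUT: dict[str, list[tuple[int, str]]] = {
    "D_cluster": [(39, "C"), (47, "C")],
    "B_cluster": [(56, "C"), (60, "C"), (65, "C"), (70, "C")],
    "acid_base_1": [(93, "K")],
    "C_cluster_1": [(261, "H"), (295, "C"), (333, "C")],
    "C_cluster_2": [(446, "C"), (476, "C"), (526, "C")],
    "acid_base_2": [(563, "H")],
}

#: Cys-Cys active-site layout of the synthetic PFL anchor (1-based).
DEFAULT_PFL_LAYOUT: dict[str, list[tuple[int, str]]] = {
    "cys_cys": [(418, "C"), (419, "C")],
}


@dataclass
class MotifSite:
    """One motif site: named group of anchor positions with required residues."""

    name: str
    positions: list[int]
    required: list[str]  # residue set (string of allowed residues) per position

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"site {self.name}: no positions configured")
        if len(self.positions) != len(self.required):
            raise ValueError(f"site {self.name}: positions/required length mismatch")


@dataclass
class MotifConfig:
    """Anchor sequence plus the motif sites defined on its coordinates."""

    anchor_reference_id: str
    anchor_sequence: str
    sites: list[MotifSite]

    def __post_init__(self) -> None:
        n = len(self.anchor_sequence)
        for site in self.sites:
            for pos in site.positions:
                if not 1 <= pos <= n:
                    raise ValueError(
                        f"site {site.name}: position {pos} outside anchor (len {n})"
                    )


@dataclass
class MotifReport:
    gene_id: str
    site_status: dict[str, str] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return bool(self.site_status) and all(
            s == INTACT for s in self.site_status.values()
        )


def config_from_layout(
    anchor_id: str, anchor_seq: str, layout: dict[str, list[tuple[int, str]]]
) -> MotifConfig:
    sites = [
        MotifSite(name, [p for p, _ in spec], [r for _, r in spec])
        for name, spec in layout.items()
    ]
    return MotifConfig(anchor_id, anchor_seq, sites)


# ---------------------------------------------------------------------------
# Alignment / mapping
# ---------------------------------------------------------------------------

def _global_aligner(matrix: str = "BLOSUM62") -> PairwiseAligner:
    # Affine gaps matching the local-search stage (open 11, extend 1 in the
    # open+k*extend convention); terminal gaps are free so that length
    # differences do not distort the identity estimate.
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load(matrix),
        open_gap_score=-12,
        extend_gap_score=-1,
    )
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def map_anchor_positions(
    candidate_protein: str, config: MotifConfig
) -> dict[int, int | None] | None:
    """Map each configured anchor position to a candidate position (0-based).

    Returns ``None`` when the candidate aligns to the anchor with identity
    below :data:`MIN_MAPPING_IDENTITY` (unreliable mapping); within the
    returned dict an anchor position maps to ``None`` when it falls in a
    deletion of the candidate.
    """
    if not candidate_protein:
        return None
    aligner = _global_aligner()
    alignment = aligner.align(config.anchor_sequence, candidate_protein)[0]
    counts = alignment.counts()
    # terminal gap columns count: a short or barely overlapping candidate
    # must register as unaligned, not as a high-identity fragment
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    if identity < MIN_MAPPING_IDENTITY:
        return None

    wanted = sorted({p for site in config.sites for p in site.positions})
    mapping: dict[int, int | None] = {p: None for p in wanted}
    for (t_start, t_end), (q_start, _q_end) in zip(*alignment.aligned):
        for pos in wanted:
            idx = pos - 1
            if t_start <= idx < t_end:
                mapping[pos] = q_start + (idx - t_start)
    return mapping


def check_motifs(
    candidate_protein: str, config: MotifConfig, gene_id: str = ""
) -> MotifReport:
    """Verdict per configured site; overall pass iff every site is intact.

    A site is ``deleted`` when any of its positions maps to a gap,
    ``substituted`` when any mapped residue is outside the required set,
    ``intact`` otherwise.  Deletion takes precedence over substitution.
    """
    report = MotifReport(gene_id=gene_id)
    mapping = map_anchor_positions(candidate_protein, config)
    if mapping is None:
        report.site_status = {site.name: UNALIGNED for site in config.sites}
        return report
    for site in config.sites:
        status = INTACT
        for pos, allowed in zip(site.positions, site.required):
            cand_idx = mapping[pos]
            if cand_idx is None:
                status = DELETED
                break
            if candidate_protein[cand_idx] not in allowed:
                status = SUBSTITUTED
        report.site_status[site.name] = status
    return report


def check_pfl_active_site(candidate_protein: str, pfl_config: MotifConfig) -> bool:
    """True iff the candidate conserves the PFL Cys-Cys active site."""
    return check_motifs(candidate_protein, pfl_config).overall_pass


# ---------------------------------------------------------------------------
# Config file IO (YAML)
# ---------------------------------------------------------------------------

def write_motif_config(path: str | Path, config: MotifConfig) -> None:
    doc = {
        "anchor_reference_id": config.anchor_reference_id,
        "anchor_sequence": config.anchor_sequence,
        "sites": {
            site.name: [
                {"position": p, "required": r}
                for p, r in zip(site.positions, site.required)
            ]
            for site in config.sites
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_motif_config(path: str | Path) -> MotifConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sites = [
        MotifSite(
            name,
            [entry["position"] for entry in entries],
            [entry["required"] for entry in entries],
        )
        for name, entries in doc["sites"].items()
    ]
    return MotifConfig(doc["anchor_reference_id"], doc["anchor_sequence"], sites)
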