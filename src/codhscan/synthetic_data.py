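"""Deterministic generator of genome bundles, reference sets and reads.

Every downstream stage of the pipeline is exercised against genomes built
here, with a planted ground truth recorded in a truth table:

* a clade-representative reference set of catalytic-subunit proteins that
  share the configured metal-cluster motif residues but are mutually
  divergent, emulating the CooS/CdhA clade representatives;
* genomes carrying cooS-derived genes at controlled identity levels and
  motif states, marker-defined genomic-context arrangements, and named
  Wood-Ljungdahl-pathway (WLP) gene-complement presets;
* error-free metatranscriptome-like reads drawn from chosen genes.

The sequence model is deliberately simple: proteins are random over the 20
standard residues except at positions conserved by construction (motif
residues and a scaffold of clade-invariant positions that keeps the
templates alignable to a single anchor), divergence is substitution-only,
and genes are separated by fixed 50-nt spacers.  Rank-based windows ignore
distances, so spacing carries no signal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    GeneRecord,
    GenomeBundle,
    reverse_complement,
    write_fasta,
)
from .motif_validator import (
    DEFAULT_PFL_LAYOUT,
    DEFAULT_SITE_LAYOUT,
    MotifConfig,
    config_from_layout,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Clade labels of the synthetic reference set (subset of A-H plus mini).
REFERENCE_CLADES = ("B", "C", "D", "E", "F", "mini")

#: Length of every catalytic-subunit template.
TEMPLATE_LENGTH = 650

#: Residues conserved on each side of every motif position, in templates
#: and in planted candidates alike.  Active-site neighborhoods are under
#: purifying selection in real catalytic subunits; here the conserved
#: flanks also pin the anchor alignment so motif positions map exactly.
MOTIF_FLANK = 3

#: Number of additional clade-invariant scaffold positions outside the
#: motif neighborhoods; keeps any candidate at >=50 % identity to its own
#: template alignable (>20 % identity) to the single motif anchor.
N_SCAFFOLD = 30

#: Fraction of non-conserved positions each clade template retains from the
#: common ancestral sequence; tuned so pairwise template identity is ~55 %.
TEMPLATE_RETENTION = 0.648

PFL_TEMPLATE_LENGTH = 740
COXL_TEMPLATE_LENGTH = 780
COXL_MOTIF = "AYRCSFR"
COXL_MOTIF_START = 380  # 1-based position of the motif in the CoxL template

INTERGENIC_NT = 50

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}


# ---------------------------------------------------------------------------
# Protein-level generators
# ---------------------------------------------------------------------------

def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _motif_positions(layout: Mapping[str, list[tuple[int, str]]]) -> dict[int, str]:
    """1-based position -> one required residue, from a site layout."""
    out: dict[int, str] = {}
    for entries in layout.values():
        for pos, required in entries:
            out[pos] = required[0]
    return out


def _stratified_sample(rng: random.Random, positions: Sequence[int], n: int) -> list[int]:
    """Pick ``n`` positions spread evenly along ``positions`` (one per bin).

    Stratified placement keeps the realized local identity homogeneous
    along the sequence, so an identity measured on any subregion — in
    particular on the locally aligned region — matches the global target.
    """
    if n == 0:
        return []
    if n >= len(positions):
        return list(positions)
    picked = []
    for b in range(n):
        lo = b * len(positions) // n
        hi = (b + 1) * len(positions) // n
        picked.append(positions[rng.randrange(lo, hi)])
    return picked


def mutate_to_identity(
    template_protein: str,
    target_identity: float,
    protected_positions: Iterable[int] = (),
    seed: int = 0,
) -> str:
    """Substitute residues to reach an exact global identity to the template.

    ``protected_positions`` are 1-based template positions left untouched.
    Exactly ``round((1 - target) * len)`` non-protected positions are
    substituted, stratified along the sequence, each to a uniformly drawn
    different residue; the realized identity equals the target up to
    rounding (well within the +/-2-percentage-point contract).
    """
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0, 1]")
    protected = {p - 1 for p in protected_positions}
    if any(p < 0 or p >= len(template_protein) for p in protected):
        raise ValueError("protected position outside template")
    n_mut = round((1.0 - target_identity) * len(template_protein))
    eligible = [i for i in range(len(template_protein)) if i not in protected]
    if n_mut > len(eligible):
        raise ValueError(
            f"cannot reach identity {target_identity} with "
            f"{len(protected)} protected positions"
        )
    rng = random.Random(seed)
    seq = list(template_protein)
    for i in _stratified_sample(rng, eligible, n_mut):
        choices = [aa for aa in AMINO_ACIDS if aa != seq[i]]
        seq[i] = rng.choice(choices)
    return "".join(seq)


def motif_window_positions(
    layout: Mapping[str, list[tuple[int, str]]] | None = None,
    flank: int = MOTIF_FLANK,
    length: int = TEMPLATE_LENGTH,
) -> list[int]:
    """1-based positions of every motif residue plus its conserved flanks."""
    layout = layout if layout is not None else DEFAULT_SITE_LAYOUT
    out: set[int] = set()
    for pos in _motif_positions(layout):
        for p in range(pos - flank, pos + flank + 1):
            if 1 <= p <= length:
                out.add(p)
    return sorted(out)


def make_reference_set(seed: int) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Clade-representative catalytic-subunit templates plus a clade map.

    Emits one template per clade label in :data:`REFERENCE_CLADES`, each
    carrying the configured motif residues, pairwise < 60 % identical.
    All templates descend from one ancestral sequence by substitution only,
    sharing a conserved scaffold, so any of them can serve as the motif
    anchor for candidates derived from any clade.
    """
    rng = random.Random(seed)
    motif = _motif_positions(DEFAULT_SITE_LAYOUT)
    ancestral = list(_random_protein(rng, TEMPLATE_LENGTH))
    for pos, residue in motif.items():
        ancestral[pos - 1] = residue
    conserved = {p - 1 for p in motif_window_positions()}
    free = [i for i in range(TEMPLATE_LENGTH) if i not in conserved]
    conserved |= set(rng.sample(free, N_SCAFFOLD))
    mutable = [i for i in range(TEMPLATE_LENGTH) if i not in conserved]
    n_mut = round((1.0 - TEMPLATE_RETENTION) * len(mutable))

    records: list[tuple[str, str]] = []
    clade_map: dict[str, str] = {}
    for clade in REFERENCE_CLADES:
        seq = list(ancestral)
        for i in _stratified_sample(rng, mutable, n_mut):
            choices = [aa for aa in AMINO_ACIDS if aa != seq[i]]
            seq[i] = rng.choice(choices)
        ref_id = f"synCooS_clade{clade}"
        records.append((ref_id, "".join(seq)))
        clade_map[ref_id] = clade
    return records, clade_map


def default_motif_config(seed: int = 0) -> MotifConfig:
    """Motif config anchored to the clade-F template of the reference set."""
    records, clade_map = make_reference_set(seed)
    anchor_id = next(rid for rid, clade in clade_map.items() if clade == "F")
    anchor_seq = dict(records)[anchor_id]
    return config_from_layout(anchor_id, anchor_seq, DEFAULT_SITE_LAYOUT)


def make_pfl_reference() -> tuple[str, str]:
    """Synthetic PFL anchor carrying the Cys-Cys active site.

    A fixed reference (internal seed): planted PFL-like genes always
    derive from this one anchor, whatever genome seed is in use.
    """
    rng = random.Random(0x5F1)
    seq = list(_random_protein(rng, PFL_TEMPLATE_LENGTH))
    for pos, residue in _motif_positions(DEFAULT_PFL_LAYOUT).items():
        seq[pos - 1] = residue
    return "synPFL_anchor", "".join(seq)


def default_pfl_config() -> MotifConfig:
    pfl_id, pfl_seq = make_pfl_reference()
    return config_from_layout(pfl_id, pfl_seq, DEFAULT_PFL_LAYOUT)


def make_coxl_reference() -> tuple[str, str]:
    """Synthetic Mo-CODH large-subunit (CoxL) anchor bearing AYRCSFR.

    Fixed reference, like :func:`make_pfl_reference`.
    """
    rng = random.Random(0xC0)
    seq = list(_random_protein(rng, COXL_TEMPLATE_LENGTH))
    for i, residue in enumerate(COXL_MOTIF):
        seq[COXL_MOTIF_START - 1 + i] = residue
    return "synCoxL_anchor", "".join(seq)


# ---------------------------------------------------------------------------
# Genome planting
# ---------------------------------------------------------------------------

CONTEXT_TYPES = (
    "WLP",
    "PEPCK",
    "FNOR",
    "ABC_transporter",
    "Fe_hydrogenase",
    "MFS_transporter",
    "uncharacterized_dehydrogenase",
    "cysteine_synthase",
)

WLP_PRESETS = (
    "full_wlp",
    "fdh_lacking_pfl",
    "fdh_lacking_transporter",
    "fdh_lacking_neither",
    "no_wlp",
)

#: Context-type marker placements: offset from the focal gene -> (KOs, COGs).
#: Mirrors the marker-defined arrangements around cooS: the WLP type keeps
#: the consecutive cooS-cooC-acsB arrangement; the ABC type plants all three
#: transporter subunits; auxiliary genes (oxyR, hypAB, pflAB) ride along
#: where the arrangement calls for them.
_CONTEXT_PLAN: dict[str, list[tuple[int, set[str], set[str], str]]] = {
    "WLP": [
        (1, {"K07321"}, set(), "cooC"),
        (2, {"K14138"}, {"COG1614"}, "acsB"),
        (3, {"K01938"}, set(), "fhs"),
    ],
    "PEPCK": [
        (-1, {"K04761"}, {"COG0583"}, "oxyR"),
        (1, {"K01610"}, {"COG1866"}, "pckA"),
    ],
    "FNOR": [
        (2, set(), {"COG1251"}, "fnor"),
    ],
    "ABC_transporter": [
        (1, {"K02049"}, {"COG0715"}, "abc1"),
        (2, {"K02050"}, {"COG0600"}, "abc2"),
        (3, {"K02051"}, {"COG1116"}, "abc3"),
    ],
    "Fe_hydrogenase": [
        (1, set(), {"COG4624"}, "feHyd"),
        (4, {"K04069"}, set(), "pflA"),
        (5, {"K00656"}, set(), "pflD"),
    ],
    "MFS_transporter": [
        (1, {"K08177"}, set(), "oxlT"),
        (2, set(), {"COG2223"}, "narK"),
    ],
    "uncharacterized_dehydrogenase": [
        (-2, {"K04652"}, set(), "hypB"),
        (-1, {"K04651"}, set(), "hypA"),
        (1, {"K00004"}, set(), "bdh"),
        (2, set(), {"COG1063"}, "zn_dh"),
    ],
    "cysteine_synthase": [
        (1, {"K01738"}, {"COG0031"}, "cysK"),
    ],
}

#: Genome-wide gene complements of the WLP presets: (KOs, COGs, role).
_WLP_CORE: list[tuple[set[str], set[str], str]] = [
    ({"K14138"}, {"COG1614"}, "acsB"),
    ({"K00197"}, set(), "acsC"),
    ({"K00194"}, set(), "acsD"),
    ({"K15023"}, set(), "acsE"),
    ({"K07321"}, set(), "cooC"),
    ({"K01938"}, set(), "fhs"),
    ({"K01491"}, set(), "folD"),
    ({"K00297"}, set(), "metF"),
    ({"K25007"}, set(), "metV"),
    ({"K03737"}, set(), "por"),
]

_WLP_PLAN: dict[str, list[tuple[set[str], set[str], str]]] = {
    "full_wlp": _WLP_CORE + [({"K05299"}, set(), "fdhA")],
    "fdh_lacking_pfl": _WLP_CORE
    + [({"K04069"}, set(), "pflA"), ({"K00656"}, set(), "pflD")],
    "fdh_lacking_transporter": _WLP_CORE
    + [({"K06212"}, set(), "focA"), ({"K00656"}, set(), "pflD_decoy")],
    "fdh_lacking_neither": _WLP_CORE + [({"K00656"}, set(), "pflD_decoy")],
    "no_wlp": [],
}

FDH_KOS = {"K05299", "K22015", "K00123"}
FORMATE_TRANSPORTER_KOS = {"K03459", "K06212", "K08177", "K21990", "K21993"}

#: Every KO/COG that can constitute context-marker evidence; preset genes
#: annotated with any of these stay out of the focal window.
_CONTEXT_MARKER_IDS = {
    "K14138", "COG1614", "K01610", "COG1866", "COG1251",
    "K02049", "K02050", "K02051", "COG0715", "COG0600", "COG1116",
    "COG4624", "K08177", "COG2223", "K00004", "COG1063",
    "K01738", "COG0031",
}


@dataclass
class PlantedGene:
    """One cooS-derived gene to plant: which template, how diverged, and
    whether the motif sites stay intact."""

    template_name: str
    target_identity: float
    motif_state: str = "intact"  # intact | substituted | deleted
    contig_id: str = "ctg0"
    rank_slot: int | None = None
    strand: str = "+"
    #: Conserve the active-site neighborhoods (the default, as homologs
    #: do); disable for boundary-identity controls whose divergence must be
    #: homogeneous along the whole sequence.
    protect_motif_windows: bool = True
    #: Optional 1-based inclusive slice emitted instead of the full-length
    #: protein — controls the alignable length for length-cutoff tests.
    fragment: tuple[int, int] | None = None


@dataclass
class PlantSpec:
    genome_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    planted_genes: list[PlantedGene] = field(default_factory=list)
    context_type: str | None = None
    wlp_profile: str = "no_wlp"
    seed: int = 0
    n_background_genes: int = 40

    def __post_init__(self) -> None:
        if self.context_type is not None and self.context_type not in _CONTEXT_PLAN:
            raise ValueError(f"unknown context_type {self.context_type!r}")
        if self.wlp_profile not in _WLP_PLAN:
            raise ValueError(f"unknown wlp_profile {self.wlp_profile!r}")
        for g in self.planted_genes:
            if g.motif_state not in {"intact", "substituted", "deleted"}:
                raise ValueError(f"unknown motif_state {g.motif_state!r}")


@dataclass
class TruthRow:
    fact_type: str
    genome_id: str
    gene_id: str
    key: str
    value: str


def _back_translate(rng: random.Random, protein: str) -> str:
    codons = [rng.choice(_CODONS[aa]) for aa in protein]
    codons.append(rng.choice(["TAA", "TAG", "TGA"]))
    return "".join(codons)


def _apply_motif_state(
    protein: str, motif_state: str, rng: random.Random
) -> tuple[str, str]:
    """Break (or keep) one motif site; returns (sequence, touched site name)."""
    if motif_state == "intact":
        return protein, ""
    if motif_state == "substituted":
        site_name = rng.choice(sorted(DEFAULT_SITE_LAYOUT))
        pos, required = DEFAULT_SITE_LAYOUT[site_name][0]
        replacement = rng.choice([aa for aa in AMINO_ACIDS if aa not in required])
        seq = list(protein)
        seq[pos - 1] = replacement
        return "".join(seq), site_name
    # deleted: excise one wide-span site in full, flanks included, as a
    # truncated pseudo-gene would.  A short in-window deletion can be
    # re-absorbed by the pairwise alignment (the gap slides onto a stray
    # residue of the same kind and reads as intact), so only sites whose
    # positions span >= 20 residues are used for this state.
    multi = sorted(
        n
        for n, spec in DEFAULT_SITE_LAYOUT.items()
        if len(spec) >= 2 and max(p for p, _ in spec) - min(p for p, _ in spec) >= 20
    )
    site_name = rng.choice(multi)
    positions = [p for p, _ in DEFAULT_SITE_LAYOUT[site_name]]
    lo = min(positions) - MOTIF_FLANK
    hi = max(positions) + MOTIF_FLANK
    seq = list(protein)
    del seq[lo - 1 : hi]
    return "".join(seq), site_name


def plant_genome(
    spec: PlantSpec,
    references: Sequence[tuple[str, str]] | None = None,
    clade_map: Mapping[str, str] | None = None,
    reference_seed: int = 0,
) -> tuple[GenomeBundle, list[TruthRow]]:
    """Build one genome bundle from a :class:`PlantSpec` plus its truth table.

    Background genes are random-codon ORFs of 200-700 aa with no
    annotations, so every marker match in the window is unambiguous.
    """
    if references is None or clade_map is None:
        references, clade_map = make_reference_set(reference_seed)
    templates = dict(references)
    rng = random.Random(spec.seed)
    protected_window = motif_window_positions()
    truth: list[TruthRow] = []

    n = spec.n_background_genes
    # slot -> (protein, kos, cogs, strand, role)
    plan: dict[int, tuple[str, set[str], set[str], str, str]] = {}

    focal_slot = None
    for k, pg in enumerate(spec.planted_genes):
        if pg.template_name not in templates:
            raise ValueError(f"unknown template {pg.template_name!r}")
        slot = pg.rank_slot if pg.rank_slot is not None else n // 2 + 3 * k
        if not 0 <= slot < n:
            raise ValueError("contig too small for requested window")
        protein = mutate_to_identity(
            templates[pg.template_name],
            pg.target_identity,
            protected_positions=protected_window if pg.protect_motif_windows else (),
            seed=rng.randrange(2**31),
        )
        protein, touched_site = _apply_motif_state(protein, pg.motif_state, rng)
        if pg.fragment is not None:
            lo, hi = pg.fragment
            protein = protein[lo - 1 : hi]
        plan[slot] = (protein, set(), set(), pg.strand, "planted_codh")
        if focal_slot is None:
            focal_slot = slot
        gid = _slot_gene_id(spec.genome_id, slot)
        truth += [
            TruthRow("planted_codh", spec.genome_id, gid, "template", pg.template_name),
            TruthRow(
                "planted_codh", spec.genome_id, gid, "clade",
                clade_map[pg.template_name],
            ),
            TruthRow(
                "planted_codh", spec.genome_id, gid, "identity",
                f"{pg.target_identity:.3f}",
            ),
            TruthRow("planted_codh", spec.genome_id, gid, "motif_state", pg.motif_state),
        ]
        if touched_site:
            truth.append(
                TruthRow("planted_codh", spec.genome_id, gid, "broken_site", touched_site)
            )

    # Context marker genes around the first planted gene.
    if spec.context_type is not None:
        if focal_slot is None:
            raise ValueError("context_type requires at least one planted gene")
        focal_id = _slot_gene_id(spec.genome_id, focal_slot)
        for offset, kos, cogs, role in _CONTEXT_PLAN[spec.context_type]:
            slot = focal_slot + offset
            if not 0 <= slot < n:
                raise ValueError("contig too small for requested window")
            if slot in plan:
                raise ValueError(f"slot collision at rank {slot}")
            protein = _marker_protein(rng, role)
            plan[slot] = (protein, set(kos), set(cogs), "+", role)
            truth.append(
                TruthRow(
                    "context_marker", spec.genome_id,
                    _slot_gene_id(spec.genome_id, slot),
                    spec.context_type, role,
                )
            )
        truth.append(
            TruthRow("context_type", spec.genome_id, focal_id, "type", spec.context_type)
        )
    elif focal_slot is not None:
        focal_id = _slot_gene_id(spec.genome_id, focal_slot)
        truth.append(TruthRow("context_type", spec.genome_id, focal_id, "type", "none"))

    # Genome-wide WLP-preset genes.  Genes carrying a context-marker
    # annotation (acsB in particular) are kept outside the focal window so
    # they never contaminate context typing; the rest may fall anywhere.
    preset_genes = _WLP_PLAN[spec.wlp_profile]
    outside = [
        s
        for s in range(n)
        if s not in plan and (focal_slot is None or abs(s - focal_slot) > 16)
    ]
    inside = [s for s in range(n) if s not in plan and s not in outside]
    placements: list[tuple[tuple[set[str], set[str], str], int]] = []
    for kos, cogs, role in preset_genes:
        if (kos | cogs) & _CONTEXT_MARKER_IDS:
            if not outside:
                raise ValueError("not enough background slots for the WLP preset")
            placements.append(((kos, cogs, role), outside.pop(0)))
    for kos, cogs, role in preset_genes:
        if not (kos | cogs) & _CONTEXT_MARKER_IDS:
            pool = outside if outside else inside
            if not pool:
                raise ValueError("not enough background slots for the WLP preset")
            placements.append(((kos, cogs, role), pool.pop(0)))
    for (kos, cogs, role), slot in placements:
        protein = _marker_protein(rng, role)
        plan[slot] = (protein, set(kos), set(cogs), "+", role)
        truth.append(
            TruthRow(
                "wlp_gene", spec.genome_id, _slot_gene_id(spec.genome_id, slot),
                role, ";".join(sorted(kos | cogs)),
            )
        )
    truth.append(TruthRow("wlp_profile", spec.genome_id, "", "preset", spec.wlp_profile))

    # Assemble the contig: background ORFs in untouched slots.
    genes: list[GeneRecord] = []
    contig_parts: list[str] = []
    pos = 0
    contig_id = spec.planted_genes[0].contig_id if spec.planted_genes else "ctg0"
    for slot in range(n):
        spacer = "".join(rng.choice("ACGT") for _ in range(INTERGENIC_NT))
        contig_parts.append(spacer)
        pos += len(spacer)
        if slot in plan:
            protein, kos, cogs, strand, _role = plan[slot]
        else:
            protein = _random_protein(rng, rng.randint(200, 700))
            kos, cogs, strand = set(), set(), rng.choice("++-")
        coding = _back_translate(rng, protein)
        segment = reverse_complement(coding) if strand == "-" else coding
        gene = GeneRecord(
            gene_id=_slot_gene_id(spec.genome_id, slot),
            genome_id=spec.genome_id,
            contig_id=contig_id,
            start=pos,
            end=pos + len(segment),
            strand=strand,
            rank=slot,
            protein=protein,
            ko_ids=kos,
            cog_ids=cogs,
        )
        genes.append(gene)
        contig_parts.append(segment)
        pos += len(segment)

    bundle = GenomeBundle(
        genome_id=spec.genome_id,
        taxonomy=dict(spec.taxonomy),
        contigs={contig_id: "".join(contig_parts)},
        genes=genes,
    )

    truth += _expected_profile_rows(spec, plan)
    return bundle, truth


def _slot_gene_id(genome_id: str, slot: int) -> str:
    return f"{genome_id}_g{slot:03d}"


_PFL_CYS = [p for p, _ in DEFAULT_PFL_LAYOUT["cys_cys"]]


def _marker_protein(rng: random.Random, role: str) -> str:
    """Protein sequence for a marker/preset gene.

    PFL genes (K00656) get a PFL-anchor-derived sequence: a valid Cys-Cys
    active site for ``pflD``, a substituted one for ``pflD_decoy`` —
    exercising the filter that separates genuine PFL from PFL-like genes.
    """
    if role.startswith("pflD"):
        _pid, pfl_seq = make_pfl_reference()
        seq = mutate_to_identity(
            pfl_seq, 0.8, protected_positions=_PFL_CYS, seed=rng.randrange(2**31)
        )
        if role == "pflD_decoy":
            chars = list(seq)
            chars[_PFL_CYS[0] - 1] = "S"
            seq = "".join(chars)
        return seq
    return _random_protein(rng, rng.randint(250, 550))


def _expected_profile_rows(
    spec: PlantSpec, plan: Mapping[int, tuple[str, set[str], set[str], str, str]]
) -> list[TruthRow]:
    """Expected genome-level WLP classification, derived from what was
    actually planted (context markers included) under the profiler's rules."""
    kos: set[str] = set()
    has_valid_pfl = False
    has_intact_codh = False
    for _protein, gene_kos, _cogs, _strand, role in plan.values():
        kos |= gene_kos
        if role == "pflD":
            has_valid_pfl = True
    for pg in spec.planted_genes:
        if pg.motif_state == "intact":
            has_intact_codh = True
    has_fdh = bool(kos & FDH_KOS)
    if has_fdh:
        route = "fdh"
    elif has_valid_pfl:
        route = "pfl"
    elif kos & FORMATE_TRANSPORTER_KOS:
        route = "transporter"
    else:
        route = "none"
    is_pcodh_acs = has_intact_codh and "K14138" in kos
    return [
        TruthRow(
            "expected", spec.genome_id, "", "fdh_status",
            "has_any_fdh" if has_fdh else "fdh_lacking",
        ),
        TruthRow("expected", spec.genome_id, "", "formate_route", route),
        TruthRow(
            "expected", spec.genome_id, "", "is_pcodh_acs",
            "true" if is_pcodh_acs else "false",
        ),
    ]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    bundles: Sequence[GenomeBundle],
    abundance_map: Mapping[str, float],
    read_length: int,
    n_reads: int,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Draw error-free reads from gene sequences; returns (reads, truth counts).

    Genes are sampled proportionally to ``weight * gene_length``; the read
    start is uniform over valid positions and the read is emitted as the
    reverse complement with probability 0.5.  Reads are ``(read_id,
    sequence)`` pairs; truth counts record the source gene of every read.
    """
    gene_seqs: dict[str, str] = {}
    for b in bundles:
        for g in b.genes:
            if g.gene_id in abundance_map:
                gene_seqs[g.gene_id] = b.gene_nucleotide(g.gene_id)
    missing = set(abundance_map) - set(gene_seqs)
    if missing:
        raise ValueError(f"abundance_map names unknown genes: {sorted(missing)}")
    weights = []
    gene_ids = sorted(gene_seqs)
    for gid in gene_ids:
        if abundance_map[gid] < 0:
            raise ValueError("negative abundance weight")
        if read_length > len(gene_seqs[gid]):
            raise ValueError(f"read_length exceeds length of gene {gid}")
        weights.append(abundance_map[gid] * len(gene_seqs[gid]))
    if sum(weights) == 0:
        raise ValueError("all abundance weights are zero")

    rng = random.Random(seed)
    reads: list[tuple[str, str]] = []
    truth_counts = {gid: 0 for gid in gene_ids}
    for i in range(n_reads):
        gid = rng.choices(gene_ids, weights=weights)[0]
        seq = gene_seqs[gid]
        start = rng.randrange(len(seq) - read_length + 1)
        read = seq[start : start + read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        reads.append((f"read_{i:06d} {gid}", read))
        truth_counts[gid] += 1
    return reads, truth_counts


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write reads as FASTQ with constant 'I' quality strings."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Truth table IO
# ---------------------------------------------------------------------------

def write_truth_table(path: str | Path, rows: Iterable[TruthRow]) -> None:
    with open(path, "w") as fh:
        fh.write("fact_type\tgenome_id\tgene_id\tkey\tvalue\n")
        for r in rows:
            fh.write(f"{r.fact_type}\t{r.genome_id}\t{r.gene_id}\t{r.key}\t{r.value}\n")


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(TruthRow(*line.split("\t")))
    return rows


def write_reference_fasta(
    path: str | Path, clade_map_path: str | Path, seed: int
) -> None:
    """Write the reference set and its template->clade map to disk."""
    records, clade_map = make_reference_set(seed)
    write_fasta(path, records)
    with open(clade_map_path, "w") as fh:
        fh.write("reference_id\tclade\n")
        for rid, clade in clade_map.items():
            fh.write(f"{rid}\t{clade}\n")
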