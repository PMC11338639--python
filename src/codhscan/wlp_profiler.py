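"""Genome-level Wood-Ljungdahl-pathway (WLP) gene-complement profiling.

Builds genome x gene-symbol presence matrices from KO annotations, defines
pCODH/ACS-encoding genomes (validated pCODH plus acsB/K14138), and
classifies each genome's formate situation: ``fdh_lacking`` genomes carry
none of the formate-dehydrogenase catalytic subunits (fdhA/fdhF/fdoG), and
the formate route falls through fdh > validated PFL > formate transporter
> none.

K00656 (PflD) covers PFL-like proteins without PFL activity, so by default
a K00656 gene counts toward the ``pfl`` symbol only when its protein
conserves the Cys-Cys active site; a flag restores raw-KO counting.
Presence is genome-wide, deliberately independent of whether cooS and acsB
sit in one genomic context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .io_formats import GenomeBundle
from .motif_validator import MotifConfig, check_pfl_active_site

#: Gene symbol -> KO ids.  OxlT (K08177) appears under both the formate
#: transporters here and the MFS context markers; the overlap is
#: intentional and documented.
DEFAULT_SYMBOL_MAP: dict[str, list[str]] = {
    "cooC": ["K07321"],
    "cooF": ["K00196"],
    "acsB": ["K14138"],
    "acsC": ["K00197"],
    "acsD": ["K00194"],
    "acsE": ["K15023"],
    "cdhC": ["K00193"],
    "fhs": ["K01938"],
    "folD": ["K01491"],
    "metF": ["K00297"],
    "metV": ["K25007"],
    "rnfA": ["K03612"],
    "rnfB": ["K03613"],
    "rnfC": ["K03614"],
    "rnfD": ["K03615"],
    "rnfE": ["K03616"],
    "rnfG": ["K03617"],
    "rnfC2": ["K25008"],
    "ech": ["K15830", "K15832"],
    "hdrA": ["K03388"],
    "hdrB": ["K03389"],
    "hdrC": ["K03390"],
    "mvhD": ["K14127"],
    "por": ["K03737"],
    "porA": ["K00169"],
    "porB": ["K00170"],
    "porC": ["K00171"],
    "porD": ["K00172"],
    "fdhA": ["K05299"],
    "fdhF": ["K22015"],
    "fdoG": ["K00123"],
    "fdh_other": ["K00122", "K00124", "K00125", "K00126", "K00127", "K22515", "K22516"],
    "focB": ["K03459"],
    "focA": ["K06212"],
    "oxlT": ["K08177"],
    "yfdC": ["K21990"],
    "fdhC": ["K21993"],
    "pfl": ["K04069", "K00656"],
}

FDH_CATALYTIC_SYMBOLS = ("fdhA", "fdhF", "fdoG")
FORMATE_TRANSPORTER_SYMBOLS = ("focA", "focB", "oxlT", "yfdC", "fdhC")

#: KO whose members require the Cys-Cys active-site check.
PFL_VALIDATED_KO = "K00656"
#: Glutamate-synthase KO co-annotated on some putative Fdh genes; such
#: genes still count toward fdh, but the co-annotation is reported.
GLUTAMATE_SYNTHASE_KO = "K00266"


@dataclass
class GenomeProfile:
    genome_id: str
    presence: dict[str, bool]
    is_pcodh_acs: bool
    fdh_status: str  # has_any_fdh | fdh_lacking
    formate_route: str  # fdh | pfl | transporter | none


def build_presence_matrix(
    bundles: Sequence[GenomeBundle],
    symbol_map: Mapping[str, list[str]] | None = None,
    pfl_config: MotifConfig | None = None,
    pfl_validation: bool = True,
) -> pd.DataFrame:
    """Boolean genome x symbol matrix.

    ``presence[genome, symbol]`` is true iff any gene of the genome carries
    any KO of the symbol; a multi-KO gene counts for every symbol it
    matches.  With ``pfl_validation`` on (the default), K00656 genes count
    toward ``pfl`` only when their protein passes the Cys-Cys check
    (``pfl_config`` required).
    """
    symbols = dict(symbol_map) if symbol_map is not None else DEFAULT_SYMBOL_MAP
    if not symbols:
        raise ValueError("empty symbol map")
    if pfl_validation and any(PFL_VALIDATED_KO in kos for kos in symbols.values()):
        if pfl_config is None:
            raise ValueError("pfl_validation requires a pfl_config")
    rows = {}
    for bundle in bundles:
        row = {}
        for symbol, kos in symbols.items():
            present = False
            for gene in bundle.genes:
                matched = gene.ko_ids & set(kos)
                if not matched:
                    continue
                if (
                    pfl_validation
                    and matched == {PFL_VALIDATED_KO}
                    and not check_pfl_active_site(gene.protein, pfl_config)
                ):
                    continue
                present = True
                break
            row[symbol] = present
        rows[bundle.genome_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(symbols)).fillna(
        False
    )


def count_fdh_glutamate_coannotation(bundles: Sequence[GenomeBundle]) -> int:
    """Number of putative Fdh genes also annotated as glutamate synthase."""
    fdh_kos = {
        ko
        for sym in (*FDH_CATALYTIC_SYMBOLS, "fdh_other")
        for ko in DEFAULT_SYMBOL_MAP[sym]
    }
    n = 0
    for bundle in bundles:
        for gene in bundle.genes:
            if gene.ko_ids & fdh_kos and GLUTAMATE_SYNTHASE_KO in gene.ko_ids:
                n += 1
    return n


def classify_genome(
    genome_id: str,
    presence_row: Mapping[str, bool],
    has_validated_pcodh: bool,
) -> GenomeProfile:
    """Fdh status and formate route of one genome from its presence row."""
    has_fdh = any(presence_row.get(s, False) for s in FDH_CATALYTIC_SYMBOLS)
    if has_fdh:
        route = "fdh"
    elif presence_row.get("pfl", False):
        route = "pfl"
    elif any(presence_row.get(s, False) for s in FORMATE_TRANSPORTER_SYMBOLS):
        route = "transporter"
    else:
        route = "none"
    return GenomeProfile(
        genome_id=genome_id,
        presence=dict(presence_row),
        is_pcodh_acs=has_validated_pcodh and bool(presence_row.get("acsB", False)),
        fdh_status="has_any_fdh" if has_fdh else "fdh_lacking",
        formate_route=route,
    )


def profile_genomes(
    bundles: Sequence[GenomeBundle],
    validated_pcodh_genomes: Iterable[str],
    symbol_map: Mapping[str, list[str]] | None = None,
    pfl_config: MotifConfig | None = None,
    pfl_validation: bool = True,
) -> tuple[pd.DataFrame, list[GenomeProfile]]:
    """Presence matrix plus per-genome profiles for a genome collection."""
    matrix = build_presence_matrix(bundles, symbol_map, pfl_config, pfl_validation)
    validated = set(validated_pcodh_genomes)
    profiles = [
        classify_genome(gid, matrix.loc[gid].to_dict(), gid in validated)
        for gid in matrix.index
    ]
    return matrix, profiles


def genus_proportions(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, Mapping[str, str]],
    symbols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-genus fraction of genomes carrying each symbol, in [0, 1].

    Genomes with an empty genus label group under ``unassigned``.  Genus
    rows weighted by their genome counts reaggregate exactly to the global
    fraction.
    """
    symbols = list(symbols) if symbols is not None else list(matrix.columns)
    genus = pd.Series(
        {
            gid: (taxonomy.get(gid, {}).get("genus") or "unassigned")
            for gid in matrix.index
        }
    )
    grouped = matrix[symbols].groupby(genus).mean()
    grouped["n_genomes"] = matrix.groupby(genus).size()
    return grouped


# ---------------------------------------------------------------------------
# Symbol map IO
# ---------------------------------------------------------------------------

def write_symbol_map(path: str | Path, symbol_map: Mapping[str, list[str]]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in symbol_map.items()}, fh, sort_keys=False)


def read_symbol_map(path: str | Path) -> dict[str, list[str]]:
    with open(path) as fh:
        return {k: list(v) for k, v in yaml.safe_load(fh).items()}
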