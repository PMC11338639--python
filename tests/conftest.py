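"""Shared fixtures: synthetic reference set and small planted genomes."""

from __future__ import annotations

import pytest

from codhscan.synthetic_data import (
    PlantSpec,
    PlantedGene,
    default_motif_config,
    default_pfl_config,
    make_reference_set,
    plant_genome,
)

REF_SEED = 11


@pytest.fixture(scope="session")
def reference_set():
    records, clade_map = make_reference_set(REF_SEED)
    return records, clade_map


@pytest.fixture(scope="session")
def motif_config():
    return default_motif_config(REF_SEED)


@pytest.fixture(scope="session")
def pfl_config():
    return default_pfl_config()


@pytest.fixture(scope="session")
def planted_bundle(reference_set):
    """One genome with an intact clade-E cooS in a WLP-type context."""
    records, clade_map = reference_set
    spec = PlantSpec(
        genome_id="gfix",
        taxonomy={"phylum": "Bacillota", "genus": "Blautia"},
        planted_genes=[PlantedGene("synCooS_cladeE", 0.7)],
        context_type="WLP",
        wlp_profile="full_wlp",
        seed=101,
    )
    bundle, truth = plant_genome(spec, records, clade_map)
    return bundle, truth
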