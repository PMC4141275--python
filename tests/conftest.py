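"""Shared synthetic worlds, built once per session (they are the expensive part)."""

import numpy as np
import pandas as pd
import pytest

from sigscan.repeats import assign_regions, classify_variant_context
from sigscan.simulate import (
    SimulationConfig,
    generate_reference,
    generate_tumor_mutations,
)

CASCADE_REGIONS = {
    "exonic": 0.075,
    "intronic": 0.25,
    "3'UTR": 0.03,
    "5'UTR": 0.015,
    "ncRNA": 0.02,
    "upstream": 0.01,
    "downstream": 0.01,
    "intergenic": 0.59,
}


@pytest.fixture(scope="session")
def default_world():
    """A ~1e5-variant cohort under the default study conditions.

    indel_fraction is set to 0.5 so both the substitution and the indel
    estimators see ~5e4 events.
    """
    cfg = SimulationConfig(indel_fraction=0.5, seed=2)
    ref = generate_reference(cfg)
    variants, truth = generate_tumor_mutations(ref)
    classified = classify_variant_context(variants, ref.repeat_index, ref.genome)
    classified = assign_regions(classified, ref.regions)
    return {"config": cfg, "ref": ref, "variants": classified, "truth": truth}


@pytest.fixture(scope="session")
def cascade_world():
    """Homopolymer-dense world for the selection-normalization cascade.

    One reference (with a shorter exonic homopolymer length mixture, the
    confounder the cascade must resist) and two mutation runs sharing
    it: a homogeneous null (exonic retention 1.0) and a selected run with
    exonic hit rates multiplied by 0.84.
    """
    base = SimulationConfig(
        genome_length=24_000_000,
        region_proportions=dict(CASCADE_REGIONS),
        homopolymers_per_mb=5000.0,
        microsatellites_per_mb=0.0,
        exonic_homopolymer_length_geom_p=0.8,
        indel_context_enrichments={
            "homopolymer": 15.0, "microsatellite": 1.0, "short_homopolymer": 1.0,
        },
        n_tumors_deficient=16,
        n_tumors_proficient=0,
        burden_ratio=1.0,
        indel_fraction=1.0,
        proficient_mutations_per_mb=1050.0,
        exonic_indel_retention=1.0,
        seed=5,
    )
    ref = generate_reference(base)

    def _run(cfg):
        variants, _ = generate_tumor_mutations(ref, cfg)
        return classify_variant_context(variants, ref.repeat_index, ref.genome)

    null_variants = _run(base)
    selected_variants = _run(base.with_(exonic_indel_retention=0.84))
    return {
        "config": base,
        "ref": ref,
        "null": null_variants,
        "selected": selected_variants,
    }
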