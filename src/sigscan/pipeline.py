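"""End-to-end orchestration: simulate -> annotate -> statistics -> classifier.

Stages run in dependency order, every output is declared in a JSON run
manifest (with SHA-256 checksums), and a fixed seed reproduces the run
byte-for-byte for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .classifier import optimize_threshold, score_samples
from .covariates import build_window_table, fit_mutation_rate_model
from .recurrence import expected_recurrence_null, select_candidate_markers, tabulate_recurrence
from .repeats import assign_regions, classify_variant_context, context_enrichment, region_mutation_frequency
from .selection import corrected_region_indel_frequency
from .simulate import (
    SimulationConfig,
    default_marker_rates,
    generate_marker_cohort,
    generate_reference,
    generate_tumor_mutations,
)
from .spectrum import dinucleotide_spectrum, flanking_slippage, indel_profile

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: SimulationConfig, outdir, n_marker_deficient: int = 40,
                 n_marker_proficient: int = 160, n_markers: int = 59) -> dict:
    """Run every stage on a synthetic cohort and write all reports.

    Returns the run manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: simulate -------------------------------------------------
    ref = generate_reference(config)
    variants, truth = generate_tumor_mutations(ref, config)
    ref.genome.to_fasta(outdir / "reference.fasta")
    io.write_bed(ref.regions, outdir / "regions.bed", name_col="region")
    io.write_repeats_bed(ref.runs, outdir / "repeats.bed")
    io.write_bed(ref.cpg_islands, outdir / "cpg_islands.bed")
    for name, track in ref.tracks.items():
        io.write_tsv(track, outdir / f"track_{name}.tsv")
    for sample in truth.sample_status["sample"]:
        io.write_vcf(variants, outdir / f"{sample}.vcf", ref.genome, sample=sample)
    io.write_tsv(truth.sample_status, outdir / "samples.tsv")

    # -- stage 2: annotate + context statistics ---------------------------
    classified = classify_variant_context(variants, ref.repeat_index, ref.genome)
    classified = assign_regions(classified, ref.regions)
    enr = context_enrichment(classified, ref.repeat_index, ref.genome.callable_length())
    io.write_tsv(enr, outdir / "context_enrichment.tsv")
    freq = region_mutation_frequency(classified, ref.regions)
    io.write_tsv(freq, outdir / "region_frequency.tsv")

    # -- stage 3: spectra --------------------------------------------------
    subs = classified[classified["variant_class"] == "substitution"]
    indels = classified[classified["variant_class"] != "substitution"]
    if len(subs):
        spec = dinucleotide_spectrum(subs, ref.genome)
        io.write_tsv(spec.to_frame(), outdir / "spectrum.tsv")
        fl = flanking_slippage(subs, ref.repeat_index, ref.genome.callable_length())
        io.write_tsv(fl.conversion.reset_index(names="composition"),
                     outdir / "flanking_conversion.tsv")
    prof = indel_profile(indels, ref.repeat_index)
    io.write_tsv(prof.per_base, outdir / "indel_profile_per_base.tsv")
    io.write_tsv(prof.by_length, outdir / "indel_profile_by_length.tsv")

    # -- stage 4: covariate regression ------------------------------------
    table = build_window_table(
        ref.genome, ref.repeat_index, classified, ref.regions,
        ref.tracks["replication_time"], cpg_islands=ref.cpg_islands,
        dnase_track=ref.tracks["dnase"], lamina_track=ref.tracks["lamina"],
        window_size=config.window_size,
    )
    io.write_tsv(table, outdir / "window_table.tsv")
    for response in ("substitutions", "indels"):
        fit = fit_mutation_rate_model(table, response=response)
        io.write_tsv(fit.table, outdir / f"model_{response}.tsv")

    # -- stage 5: selection-normalization cascade -------------------------
    cascade = corrected_region_indel_frequency(indels, ref.runs, mode="union")
    io.write_tsv(cascade.strata, outdir / "cascade_strata.tsv")
    io.write_tsv(cascade.summary, outdir / "cascade_summary.tsv")

    # -- stage 6: recurrence + marker candidates --------------------------
    samples = list(truth.sample_status["sample"])
    tissues = {s: ("EM" if i % 2 == 0 else "CRC") for i, s in enumerate(samples)}
    rec = tabulate_recurrence(indels, ref.runs, samples)
    io.write_tsv(rec.loci, outdir / "recurrence.tsv")
    io.write_tsv(expected_recurrence_null(rec), outdir / "recurrence_null.tsv")
    k_cut = min(6, max(2, rec.loci["k"].max())) if len(rec.loci) else 6
    markers = select_candidate_markers(
        rec, tissues, min_recurrence=int(k_cut),
        require_tissue_rule=len(set(tissues.values())) > 1,
    )
    io.write_tsv(markers, outdir / "marker_candidates.tsv")

    # -- stage 7: marker-panel classifier ---------------------------------
    d_rates, p_rates = default_marker_rates(n_markers, seed=config.seed)
    matrix, m_truth = generate_marker_cohort(
        n_marker_deficient, n_marker_proficient, d_rates, p_rates,
        missing_rate=0.02, seed=config.seed,
    )
    io.write_marker_matrix(matrix, m_truth, outdir / "marker_matrix.tsv")
    evaluation = optimize_threshold(matrix, m_truth)
    io.write_tsv(evaluation.table, outdir / "classifier_evaluation.tsv")
    calls = score_samples(matrix, threshold=evaluation.best_threshold)
    io.write_tsv(calls.reset_index(names="sample"), outdir / "msi_calls.tsv")

    # -- manifest ----------------------------------------------------------
    outputs = sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [
            "simulate", "annotate", "spectrum", "covariates",
            "selection_norm", "recurrence", "classifier",
        ],
        "outputs": {name: _sha256(outdir / name) for name in outputs},
        "best_threshold": int(evaluation.best_threshold),
        "best_mcc": float(evaluation.best_mcc),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
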