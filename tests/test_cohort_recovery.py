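"""Parameter-recovery suite: every stated generator parameter is recovered by
the corresponding downstream estimator from a ~1e5-variant synthetic cohort."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigscan.covariates import build_window_table
from sigscan.repeats import context_enrichment, region_mutation_frequency
from sigscan.simulate import SimulationConfig, generate_reference, generate_tumor_mutations
from sigscan.spectrum import (
    cpg_island_rates,
    dinucleotide_spectrum,
    flanking_slippage,
    indel_profile,
    nearest_distance_null,
    replication_profile,
    spectrum_similarity,
    windowed_counts,
)


def _subs(world):
    v = world["variants"]
    return v[v["variant_class"] == "substitution"]


def _indels(world):
    v = world["variants"]
    return v[v["variant_class"] != "substitution"]


def test_transition_fraction_recovered(default_world):
    spec = dinucleotide_spectrum(_subs(default_world), default_world["ref"].genome)
    assert spec.transition_fraction() == pytest.approx(0.74, abs=0.01)


def test_per_million_normalization_sums_to_million(default_world):
    spec = dinucleotide_spectrum(_subs(default_world), default_world["ref"].genome)
    assert spec.per_million_substitutions.sum() == pytest.approx(1e6, abs=1)


def test_deletion_fraction_within_binomial_ci(default_world):
    indels = _indels(default_world)
    n = len(indels)
    k = int((indels["alt"].str.len() < indels["ref"].str.len()).sum())
    lo, hi = stats.binom.interval(0.99, n, 0.81)
    assert lo <= k <= hi


def test_context_enrichment_folds_recovered(default_world):
    enr = context_enrichment(
        default_world["variants"],
        default_world["ref"].repeat_index,
        default_world["ref"].genome.callable_length(),
    ).set_index(["variant_type", "context_class"])["fold"]
    assert enr[("indel", "homopolymer")] == pytest.approx(40.0, abs=3.0)
    assert enr[("indel", "microsatellite")] == pytest.approx(2.3, abs=0.2)
    assert enr[("indel", "short_homopolymer")] == pytest.approx(1.0, abs=0.1)
    assert enr[("substitution", "homopolymer")] == pytest.approx(3.0, abs=0.4)
    assert enr[("substitution", "microsatellite")] == pytest.approx(1.5, abs=0.12)


def test_flanking_slippage_fold_and_conversion(default_world):
    ref = default_world["ref"]
    res = flanking_slippage(_subs(default_world), ref.repeat_index,
                            ref.genome.callable_length())
    assert res.fold_homopolymer == pytest.approx(3.0, abs=0.45)
    assert res.fold_microsatellite == pytest.approx(1.3, abs=0.3)
    conv = res.conversion
    # the base flanking an A-run is mostly converted to an A (likewise per base)
    for base in "ACGT":
        assert conv.loc[base].idxmax() == base


def test_cpg_island_rate_ratio_recovered(default_world):
    ref = default_world["ref"]
    out = cpg_island_rates(_subs(default_world), ref.cpg_islands, ref.genome)
    ratio = out.set_index("series").loc["all", "ratio"]
    assert ratio == pytest.approx(0.5, abs=0.06)


@pytest.fixture(scope="module")
def exon_rich_world():
    """Cohort with a boosted exonic share so the exonic homopolymer length
    mixture is well sampled (the 1.12% default leaves too few exonic loci
    for a stable per-base rate ratio)."""
    props = {"exonic": 0.15, "intronic": 0.25, "3'UTR": 0.03, "5'UTR": 0.01,
             "ncRNA": 0.02, "upstream": 0.01, "downstream": 0.012,
             "intergenic": 0.518}
    cfg = SimulationConfig(
        genome_length=4_000_000, window_size=400_000, region_proportions=props,
        indel_fraction=0.5, proficient_mutations_per_mb=160, seed=41,
    )
    ref = generate_reference(cfg)
    variants, _ = generate_tumor_mutations(ref, cfg)
    from sigscan.repeats import assign_regions, classify_variant_context

    classified = assign_regions(
        classify_variant_context(variants, ref.repeat_index, ref.genome), ref.regions
    )
    return {"ref": ref, "variants": classified}


def test_exonic_indel_retention_recovered(exon_rich_world):
    freq = region_mutation_frequency(
        exon_rich_world["variants"], exon_rich_world["ref"].regions
    )
    cohort = freq.query("sample == 'cohort_mean' and variant_type == 'indel'")
    f = cohort.set_index("region")["frequency"]
    assert f["exonic"] / f["intergenic"] == pytest.approx(0.09, abs=0.02)
    # the depletion is driven by indels: substitutions show no such deficit
    subs = freq.query("sample == 'cohort_mean' and variant_type == 'substitution'")
    fs = subs.set_index("region")["frequency"]
    assert fs["exonic"] / fs["intergenic"] == pytest.approx(1.0, abs=0.25)


def test_region_fractions_match_configuration(default_world):
    regions = default_world["ref"].regions
    cfg = default_world["config"]
    frac = (
        (regions["end"] - regions["start"]).groupby(regions["region"]).sum()
        / cfg.genome_length
    )
    for label, p in cfg.region_proportions.items():
        assert frac[label] == pytest.approx(p, abs=0.003), label


def test_cg_homopolymers_underrepresented_among_affected(default_world):
    prof = indel_profile(_indels(default_world), default_world["ref"].repeat_index)
    assert prof.deletion_fraction == pytest.approx(0.81, abs=0.02)
    assert prof.cg_affected_share < prof.cg_run_share
    # hit probability rises with run length
    by_len = prof.by_length[prof.by_length["n_runs"] >= 50]
    frac = by_len.sort_values("length")["fraction_affected"].to_numpy()
    assert frac[-1] > frac[0]


def test_replication_trend_transitions_only(default_world):
    ref = default_world["ref"]
    table = build_window_table(
        ref.genome, ref.repeat_index, default_world["variants"], ref.regions,
        ref.tracks["replication_time"], cpg_islands=ref.cpg_islands,
        dnase_track=ref.tracks["dnase"], lamina_track=ref.tracks["lamina"],
        window_size=500_000,
    )
    prof = replication_profile(
        _subs(default_world), ref.tracks["replication_time"], ref.genome,
        n_bins=7, window_table=table,
    )
    bins = prof.bins
    # configured positive gradient on transitions: late bins mutate more
    late = bins["ts_rel"].iloc[-2:].mean()
    assert late > 1.1
    assert prof.trend_pvalues["transitions"]["bonferroni_significant"]
    # transversions were generated flat
    assert not prof.trend_pvalues["transversions"]["bonferroni_significant"]


def test_substitutions_enriched_adjacent_to_repeats_only(default_world):
    ref = default_world["ref"]
    runs = ref.runs
    feats = runs[runs["kind"].isin(["homopolymer", "microsatellite"])][
        ["contig", "start", "end"]
    ]
    callable_iv = pd.DataFrame(
        {"contig": ["chr1"], "start": [0], "end": [ref.genome.length("chr1")]}
    )
    subs = _subs(default_world)
    res = nearest_distance_null(subs, feats, callable_iv, n_random=40, seed=3)
    # bin 0 covers the repeat itself and the immediately flanking base:
    # slippage raises it well above the null
    assert res.enrichment[0] > 1.2
    # far from any repeat the placement matches the null
    far = (res.bin_lower >= 8) & (res.expected > 200)
    assert np.allclose(res.enrichment[far], 1.0, atol=0.15)


def test_spectra_of_independent_deficient_tumors_agree(default_world):
    genome = default_world["ref"].genome
    subs = _subs(default_world)
    samples = sorted(set(subs["sample"]))
    deficient = [s for s in samples if s.startswith("MMRd")]
    a = dinucleotide_spectrum(subs[subs["sample"] == deficient[0]], genome)
    b = dinucleotide_spectrum(subs[subs["sample"] == deficient[1]], genome)
    assert spectrum_similarity(a, b) > 0.95


def test_unbiased_profile_is_dissimilar(default_world):
    """A mutational process without the transition bias shares none of the
    spectrum's structure: its R^2 against the MMR-deficient-style spectrum is
    markedly lower than a resimulation's (directional, as squared correlation
    cannot distinguish an identical from an inverted contrast)."""
    genome = default_world["ref"].genome
    base = dinucleotide_spectrum(_subs(default_world), genome)
    cfg = SimulationConfig(
        genome_length=2_000_000, window_size=200_000, indel_fraction=0.0,
        proficient_mutations_per_mb=200, transition_fraction=1 / 3, seed=23,
    )
    ref2 = generate_reference(cfg)
    v2, _ = generate_tumor_mutations(ref2, cfg)
    flat = dinucleotide_spectrum(v2[v2["variant_class"] == "substitution"], ref2.genome)
    resim = dinucleotide_spectrum(
        _subs(default_world).sample(frac=0.5, random_state=0), genome
    )
    # the abundance-normalized rates isolate the mutational process from the
    # shared genome composition
    norm = "per_million_dinucleotides"
    r2_self = spectrum_similarity(base, resim, normalization=norm)
    r2_flat = spectrum_similarity(base, flat, normalization=norm)
    assert r2_self > 0.95
    assert r2_flat < r2_self - 0.5


def test_windowed_counts_correlate_iff_landscape_shared():
    """Resimulation oracle: cohorts drawn from one per-window rate landscape
    correlate; cohorts from independent landscapes do not."""
    rng = np.random.default_rng(31)
    n_win = 40
    landscape = rng.gamma(2.0, 1.0, n_win)
    other = rng.gamma(2.0, 1.0, n_win)

    def draw(rates):
        counts = rng.poisson(rates * 200)
        return counts

    a, b = draw(landscape), draw(landscape)
    c = draw(other)
    from sigscan.spectrum import spectrum_similarity as r2

    assert r2(a, b) > 0.5
    assert r2(a, c) < 0.3
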