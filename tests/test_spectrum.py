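"""Substitution/indel spectra, context dependencies and the distance null."""

import numpy as np
import pandas as pd
import pytest

from sigscan.genome import Genome
from sigscan.repeats import RepeatIndex, classify_variant_context, scan_repeats
from sigscan.spectrum import (
    SpectrumMatrix,
    cpg_island_rates,
    dinucleotide_spectrum,
    flanking_slippage,
    indel_profile,
    nearest_distance_null,
    replication_profile,
    spectrum_similarity,
    windowed_counts,
)

BASES = "ACGT"


def random_subs(rng, seq, n, contig="chr1"):
    pos = rng.integers(0, len(seq) - 1, size=n)
    refs = [seq[p] for p in pos]
    alts = [rng.choice([b for b in BASES if b != r]) for r in refs]
    return pd.DataFrame(
        {"contig": contig, "pos": pos, "ref": refs, "alt": alts, "sample": "s"}
    )


def test_single_substitution_single_cell():
    genome = Genome({"chr1": "TTAC"})
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [2], "ref": ["A"], "alt": ["G"], "sample": ["s"]}
    )
    spec = dinucleotide_spectrum(subs, genome)
    assert spec.total == 1
    assert spec.counts[0, 1, 2] == 1  # A followed by C, to G
    assert np.count_nonzero(spec.counts) == 1
    assert spec.per_million_substitutions[0, 1, 2] == 1e6


def test_contig_end_goes_to_boundary_bucket():
    genome = Genome({"chr1": "TTA"})
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [2], "ref": ["A"], "alt": ["G"], "sample": ["s"]}
    )
    spec = dinucleotide_spectrum(subs, genome)
    assert spec.boundary_count == 1
    assert spec.total == 0


def test_spectrum_matches_brute_force_tally():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list(BASES), size=5000))
    genome = Genome({"chr1": seq})
    subs = random_subs(rng, seq, 1000)
    spec = dinucleotide_spectrum(subs, genome)
    brute = np.zeros((4, 4, 4), dtype=int)
    for _, row in subs.iterrows():
        p = row["pos"]
        brute[BASES.index(row["ref"]), BASES.index(seq[p + 1]), BASES.index(row["alt"])] += 1
    np.testing.assert_array_equal(spec.counts, brute)
    assert spec.per_million_substitutions.sum() == pytest.approx(1e6)


def test_ref_mismatch_errors():
    genome = Genome({"chr1": "AAAA"})
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [1], "ref": ["C"], "alt": ["T"], "sample": ["s"]}
    )
    with pytest.raises(ValueError, match="mismatch"):
        dinucleotide_spectrum(subs, genome)


def test_similarity_identity_symmetry_and_errors():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list(BASES), size=5000))
    genome = Genome({"chr1": seq})
    a = dinucleotide_spectrum(random_subs(rng, seq, 500), genome)
    b = dinucleotide_spectrum(random_subs(rng, seq, 500), genome)
    assert spectrum_similarity(a, a) == pytest.approx(1.0)
    assert spectrum_similarity(a, b) == pytest.approx(spectrum_similarity(b, a))
    with pytest.raises(ValueError, match="zero-variance"):
        spectrum_similarity(np.ones(48), np.arange(48.0))


def test_affine_transform_keeps_similarity_one():
    v = np.random.default_rng(3).random(48)
    assert spectrum_similarity(v, 3.0 * v + 7.0) == pytest.approx(1.0)


def test_windowed_counts_hand_tally_and_partial_window():
    genome = Genome({"chr1": "A" * 5500})
    variants = pd.DataFrame(
        {"contig": "chr1", "pos": [0, 999, 1000, 2500, 5300],
         "ref": "A", "alt": "G", "sample": "s", "region": "intergenic"}
    )
    out = windowed_counts(variants, genome, window_size=1000)
    assert list(out["count"]) == [2, 1, 1, 0, 0, 1]
    assert list(out["complete"]) == [True] * 5 + [False]


def test_windowed_counts_requires_region_column_for_scope():
    genome = Genome({"chr1": "A" * 3000})
    variants = pd.DataFrame(
        {"contig": "chr1", "pos": [1], "ref": "A", "alt": "G", "sample": "s"}
    )
    with pytest.raises(ValueError, match="region"):
        windowed_counts(variants, genome, window_size=1000)


def test_cpg_island_rates_hand_computed():
    # 1000 bp genome, one 100 bp island; 2 subs inside, 8 outside
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list(BASES), size=1000))
    genome = Genome({"chr1": seq})
    islands = pd.DataFrame({"contig": ["chr1"], "start": [100], "end": [200]})
    pos = [110, 150] + [300, 350, 400, 500, 600, 700, 800, 900]
    subs = pd.DataFrame(
        {"contig": "chr1", "pos": pos,
         "ref": [seq[p] for p in pos],
         "alt": [BASES[(BASES.index(seq[p]) + 1) % 4] for p in pos],
         "sample": "s"}
    )
    out = cpg_island_rates(subs, islands, genome).set_index("series")
    overall = 10 / 1000
    assert out.loc["all", "relative_in"] == pytest.approx((2 / 100) / overall)
    assert out.loc["all", "relative_out"] == pytest.approx((8 / 900) / overall)


def test_cpg_island_degenerate_tracks_error():
    genome = Genome({"chr1": "ACGT" * 100})
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [0], "ref": ["A"], "alt": ["G"], "sample": ["s"]}
    )
    with pytest.raises(ValueError, match="no CpG islands"):
        cpg_island_rates(subs, pd.DataFrame(columns=["contig", "start", "end"]), genome)
    full = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [400]})
    with pytest.raises(ValueError, match="whole genome"):
        cpg_island_rates(subs, full, genome)


def test_indel_profile_all_single_deletions():
    seq = "GGGGCAAAAAAACGGGG"
    genome = Genome({"chr1": seq})
    runs = scan_repeats(seq)
    index = RepeatIndex(runs)
    indels = pd.DataFrame(
        {"contig": "chr1", "pos": [4, 4, 4], "ref": "CA", "alt": "C",
         "sample": ["s1", "s2", "s3"]}
    )
    classified = classify_variant_context(indels, index, genome)
    prof = indel_profile(classified, index)
    assert prof.deletion_fraction == 1.0
    assert prof.length_histogram.to_dict() == {-1: 1.0}
    per = prof.per_base.set_index("base")
    assert per.loc["A", "n_affected"] == 1 and per.loc["A", "fraction_affected"] == 1.0


def test_replication_profile_binning_errors():
    genome = Genome({"chr1": "ACGT" * 2500})
    track = pd.DataFrame(
        {"contig": "chr1", "start": [0, 5000], "end": [5000, 10000], "value": [0.1, 0.1]}
    )
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [0], "ref": ["A"], "alt": ["G"], "sample": ["s"]}
    )
    with pytest.raises(ValueError, match="distinct"):
        replication_profile(subs, track, genome, n_bins=7)


def test_distance_null_uniform_placement_is_flat():
    rng = np.random.default_rng(5)
    L = 200_000
    seq = "".join(rng.choice(list(BASES), size=L))
    genome = Genome({"chr1": seq})
    features = pd.DataFrame(
        {"contig": "chr1", "start": np.arange(50) * 4000, "end": np.arange(50) * 4000 + 50}
    )
    callable_iv = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [L]})
    subs = random_subs(rng, seq, 3000)
    res = nearest_distance_null(subs, features, callable_iv, n_random=100, seed=0)
    ok = res.expected >= 30
    assert ok.any()
    se = np.sqrt(res.expected[ok])
    assert (np.abs(res.observed[ok] - res.expected[ok]) <= 4 * se).all()


def test_distance_null_reproducible_and_converges():
    rng = np.random.default_rng(6)
    L = 20_000
    seq = "".join(rng.choice(list(BASES), size=L))
    features = pd.DataFrame({"contig": ["chr1"], "start": [5000], "end": [5100]})
    callable_iv = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [L]})
    subs = random_subs(rng, seq, 300)
    r1 = nearest_distance_null(subs, features, callable_iv, n_random=200, seed=7)
    r2 = nearest_distance_null(subs, features, callable_iv, n_random=200, seed=7)
    np.testing.assert_array_equal(r1.expected, r2.expected)
    big = nearest_distance_null(subs, features, callable_iv, n_random=2000, seed=8)
    ok = big.expected >= 20
    # Monte-Carlo error of the 200-replicate estimate vs a 2000-replicate oracle
    assert np.allclose(r1.expected[ok], big.expected[ok], rtol=0.2)


def test_distance_null_configuration_errors():
    features = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [10]})
    callable_iv = pd.DataFrame({"contig": ["chr1"], "start": [0], "end": [100]})
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [50], "ref": ["A"], "alt": ["G"], "sample": ["s"]}
    )
    with pytest.raises(ValueError, match="n_random"):
        nearest_distance_null(subs, features, callable_iv, n_random=1)
    with pytest.raises(ValueError, match="empty"):
        nearest_distance_null(subs, features.iloc[:0], callable_iv)


def test_flanking_slippage_empty_when_no_flanking_hits():
    seq = "GGTTGGCCGGTTGG"  # no runs at all
    index = RepeatIndex(scan_repeats(seq))
    subs = pd.DataFrame(
        {"contig": ["chr1"], "pos": [1], "ref": ["G"], "alt": ["T"], "sample": ["s"]}
    )
    res = flanking_slippage(subs, index, len(seq))
    assert res.empty
    assert res.n_flanking == 0
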