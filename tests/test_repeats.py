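"""Repeat scanning, context classification and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from sigscan import (
    Genome,
    RepeatIndex,
    classify_variant_context,
    context_enrichment,
    region_mutation_frequency,
    scan_repeats,
)
from sigscan.repeats import assign_regions, infer_variant_class

COMP = str.maketrans("ACGT", "TGCA")


def brute_force_runs(seq, min_hp=6, min_shp=3, min_ms=6, max_unit=6):
    """O(L*k) reference scanner used as an independent oracle."""
    L = len(seq)
    out = set()
    i = 0
    while i < L:
        j = i
        while j < L and seq[j] == seq[i]:
            j += 1
        ln = j - i
        if seq[i] in "ACGT" and ln >= min_shp:
            kind = "homopolymer" if ln >= min_hp else "short_homopolymer"
            out.add((i, j, seq[i], kind))
        i = j
    for k in range(2, max_unit + 1):
        for i in range(L - k):
            ok = lambda p: seq[p] in "ACGT"
            if i > 0 and i - 1 + k < L and ok(i - 1) and ok(i - 1 + k) and seq[i - 1] == seq[i - 1 + k]:
                continue  # not a maximal start
            j = i + k
            while j < L and ok(j) and ok(j - k) and seq[j] == seq[j - k]:
                j += 1
            total = j - i
            unit = seq[i : i + k]
            if total < max(min_ms, 2 * k) or not all(c in "ACGT" for c in unit):
                continue
            if any(unit == unit[:d] * (k // d) for d in range(1, k) if k % d == 0):
                continue  # non-primitive unit
            out.add((i, i + total, unit, "microsatellite"))
    return out


def runs_as_set(df):
    return set(zip(df["start"], df["end"], df["unit"], df["kind"]))


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("GGAAAAAAGG", {(2, 8, "A", "homopolymer")}),
        ("GGAAAAAGG", {(2, 7, "A", "short_homopolymer")}),
        ("AAAAAA", {(0, 6, "A", "homopolymer")}),  # never an AAx3 microsatellite
        ("TTACACACACGG", {(2, 10, "AC", "microsatellite")}),
        ("ACACA", set()),  # 5 bases, below the 6-base floor
        ("GGAANAAAGG", {(5, 8, "A", "short_homopolymer")}),  # N breaks runs
    ],
)
def test_scan_repeats_definitional_cases(seq, expected):
    found = runs_as_set(scan_repeats(seq))
    assert found == brute_force_runs(seq)
    assert found == expected


def test_scan_rejects_bad_alphabet():
    with pytest.raises(ValueError, match="offset 3"):
        scan_repeats("ACGXAAAA")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_scan_matches_brute_force_on_random_sequence(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=10_000))
    assert runs_as_set(scan_repeats(seq)) == brute_force_runs(seq)


@pytest.mark.parametrize("seed", [7, 8])
def test_homopolymer_scan_is_strand_symmetric(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=4000))
    fwd = scan_repeats(seq)
    rev = scan_repeats(seq[::-1].translate(COMP))
    L = len(seq)
    fwd_hp = {
        (L - e, L - s, u.translate(COMP))
        for s, e, u, k in runs_as_set(fwd)
        if k in ("homopolymer", "short_homopolymer")
    }
    rev_hp = {
        (s, e, u)
        for s, e, u, k in runs_as_set(rev)
        if k in ("homopolymer", "short_homopolymer")
    }
    assert fwd_hp == rev_hp


# ----------------------------------------------------------------------
# context classification
# ----------------------------------------------------------------------

def toy_world():
    #            0123456789012345678901234567890123
    seq = "GGCTAAAAAAAAGGGTCACACACACGTTTTCGGATCGGATCGATCGTACGTAGCTAGC"
    genome = Genome({"chr1": seq})
    runs = scan_repeats(seq)
    return genome, runs, RepeatIndex(runs)


def test_anchor_deletion_in_homopolymer_is_affected():
    genome, runs, index = toy_world()
    # A8 run at [4,12); left-normalized 1bp deletion anchored at pos 3
    v = pd.DataFrame(
        {"contig": ["chr1"], "pos": [3], "ref": ["TA"], "alt": ["T"], "sample": ["s1"]}
    )
    out = classify_variant_context(v, index, genome)
    assert out.loc[0, "context_class"] == "homopolymer"
    rid = out.loc[0, "run_id"]
    assert rid >= 0 and index.runs.loc[rid, "unit"] == "A" and index.runs.loc[rid, "length"] == 8


def test_substitution_in_repeat_free_stretch_is_non_repeat():
    genome, runs, index = toy_world()
    v = pd.DataFrame(
        {"contig": ["chr1"], "pos": [1], "ref": ["G"], "alt": ["T"], "sample": ["s1"]}
    )
    out = classify_variant_context(v, index, genome)
    assert out.loc[0, "context_class"] == "non_repeat"
    assert out.loc[0, "run_id"] == -1


def test_non_unit_indel_does_not_affect_microsatellite():
    genome, runs, index = toy_world()
    # AC microsatellite at [16,26); deleting a single base is not a whole unit
    v = pd.DataFrame(
        {"contig": ["chr1"], "pos": [15], "ref": ["CA"], "alt": ["C"], "sample": ["s1"]}
    )
    out = classify_variant_context(v, index, genome)
    assert out.loc[0, "context_class"] == "microsatellite"
    assert out.loc[0, "run_id"] == -1  # positional context only, no affected run


def test_variant_outside_reference_errors():
    genome, runs, index = toy_world()
    v = pd.DataFrame(
        {"contig": ["chr1"], "pos": [10_000], "ref": ["A"], "alt": ["G"], "sample": ["s1"]}
    )
    with pytest.raises(ValueError, match="outside"):
        classify_variant_context(v, index, genome)


def test_classification_matches_interval_scan_oracle():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    # salt with planted repeats so every class occurs
    seq = seq[:100] + "A" * 9 + seq[109:800] + "TG" * 6 + seq[812:2000] + "CCCC" + seq[2004:]
    genome = Genome({"chr1": seq})
    runs = scan_repeats(seq)
    index = RepeatIndex(runs)
    pos = rng.integers(0, len(seq) - 1, size=500)
    refs = [seq[p] for p in pos]
    alts = ["ACGT".replace(r, "")[0] for r in refs]
    v = pd.DataFrame({"contig": "chr1", "pos": pos, "ref": refs, "alt": alts, "sample": "s"})
    out = classify_variant_context(v, index, genome)

    order = ["homopolymer", "microsatellite", "short_homopolymer"]
    for p, got in zip(pos, out["context_class"]):
        expected = "non_repeat"
        for kind in order:
            sub = runs[(runs["kind"] == kind) & (runs["start"] <= p) & (p < runs["end"])]
            if len(sub):
                expected = kind
                break
        assert got == expected

    # classes are exhaustive and mutually exclusive
    assert out["context_class"].isin(order + ["non_repeat"]).all()
    assert out["context_class"].value_counts().sum() == len(out)


def test_infer_variant_class():
    assert infer_variant_class("A", "G") == "substitution"
    assert infer_variant_class("AT", "A") == "deletion"
    assert infer_variant_class("A", "AT") == "insertion"


# ----------------------------------------------------------------------
# enrichment and region frequencies
# ----------------------------------------------------------------------

def test_context_enrichment_hand_computed():
    genome, runs, index = toy_world()
    L = genome.callable_length()
    counts = index.class_base_counts()
    # 20 substitutions: 10 in the homopolymer, 10 outside any repeat
    hp_pos = [4] * 10
    nr_pos = [1] * 10
    v = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": hp_pos + nr_pos,
            "ref": "A",
            "alt": "G",
            "sample": "s",
        }
    )
    out = classify_variant_context(v, index, genome)
    enr = context_enrichment(out, index, L).set_index(["variant_type", "context_class"])
    row = enr.loc[("substitution", "homopolymer")]
    assert row["observed_fraction"] == 0.5
    assert row["expected_fraction"] == counts["homopolymer"] / L
    assert row["fold"] == pytest.approx(0.5 / (counts["homopolymer"] / L))


def test_uniform_placement_gives_unit_folds():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=200_000))
    genome = Genome({"chr1": seq})
    index = RepeatIndex(scan_repeats(seq))
    n = 100_000
    pos = rng.integers(0, len(seq), size=n)
    refs = [seq[p] for p in pos]
    alts = ["ACGT".replace(r, "")[0] for r in refs]
    v = pd.DataFrame({"contig": "chr1", "pos": pos, "ref": refs, "alt": alts, "sample": "s"})
    out = classify_variant_context(v, index, genome)
    enr = context_enrichment(out, index, len(seq))
    for _, row in enr.iterrows():
        if row["expected_fraction"] == 0:
            continue
        se = np.sqrt(row["expected_fraction"] * (1 - row["expected_fraction"]) / n)
        tol = 3 * se / row["expected_fraction"]
        assert abs(row["fold"] - 1.0) <= max(tol, 1e-6), row


def test_region_frequency_hand_computed():
    genome, runs, index = toy_world()
    L = genome.length("chr1")
    regions = pd.DataFrame(
        {
            "contig": "chr1",
            "start": [0, 20],
            "end": [20, L],
            "region": ["exonic", "intergenic"],
        }
    )
    v = pd.DataFrame(
        {
            "contig": "chr1",
            "pos": [1, 5, 25, 30, 40, 41],
            "ref": ["G", "A", "A", "T", "G", "G"],
            "alt": ["T", "G", "C", "A", "A", "A"],
            "sample": ["s1", "s1", "s1", "s1", "s1", "s2"],
        }
    )
    out = assign_regions(v, regions)
    out["variant_class"] = "substitution"
    freq = region_mutation_frequency(out, regions)
    s1_ex = freq.query("sample=='s1' and region=='exonic'")["frequency"].iloc[0]
    assert s1_ex == pytest.approx(2 / 20)
    s1_ig = freq.query("sample=='s1' and region=='intergenic'")["frequency"].iloc[0]
    assert s1_ig == pytest.approx(3 / (L - 20))
    cohort_ig = freq.query("sample=='cohort_mean' and region=='intergenic'")["frequency"].iloc[0]
    assert cohort_ig == pytest.approx((3 / (L - 20) + 1 / (L - 20)) / 2)


def test_single_region_covering_everything():
    genome, runs, index = toy_world()
    L = genome.length("chr1")
    regions = pd.DataFrame(
        {"contig": ["chr1"], "start": [0], "end": [L], "region": ["intergenic"]}
    )
    v = pd.DataFrame(
        {"contig": "chr1", "pos": [3, 7], "ref": "A", "alt": "G", "sample": "s"}
    )
    v["variant_class"] = "substitution"
    freq = region_mutation_frequency(assign_regions(v, regions), regions)
    total = freq.query("sample=='cohort_mean'")["frequency"].iloc[0]
    assert total == pytest.approx(2 / L)
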