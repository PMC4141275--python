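"""Substitution and indel spectra and their sequence-context dependencies.

The central object is the dinucleotide substitution matrix: counts indexed
by (mutated base, following base on the reference strand, new base), 48
valid triplets with no strand collapsing.  Two normalizations are carried:
per million dinucleotides (count divided by the genome-wide abundance of
the dinucleotide, times 1e6) and per million substitutions (count divided
by the total substitution count, times 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _intervals
from .genome import Genome
from .repeats import RepeatIndex

BASES = "ACGT"
#: transitions: purine<->purine, pyrimidine<->pyrimidine (A<->G, C<->T)
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_a, _b] = True


def is_transition(ref_codes, alt_codes) -> np.ndarray:
    return _TRANSITION[np.asarray(ref_codes), np.asarray(alt_codes)]


@dataclass
class SpectrumMatrix:
    """Dinucleotide-context substitution counts plus both normalizations."""

    counts: np.ndarray                      # (ref, following, alt)
    dinucleotide_abundance: np.ndarray      # (ref, following)
    boundary_count: int = 0                 # no valid following base

    def __post_init__(self):
        valid = ~np.eye(4, dtype=bool)[:, None, :]
        if np.any(self.counts * ~np.broadcast_to(valid, self.counts.shape)):
            raise ValueError("diagonal (ref == alt) cells must be empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def per_million_substitutions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty spectrum")
        return self.counts / self.total * 1e6

    @property
    def per_million_dinucleotides(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.dinucleotide_abundance[:, :, None] > 0,
                self.counts / self.dinucleotide_abundance[:, :, None] * 1e6,
                np.nan,
            )

    def values_48(self, normalization: str = "per_million_substitutions") -> np.ndarray:
        """The 48 valid entries (ref != alt), in a fixed order."""
        mat = getattr(self, normalization)
        mask = ~np.eye(4, dtype=bool)
        out = []
        for r in range(4):
            for f in range(4):
                for a in range(4):
                    if mask[r, a]:
                        out.append(mat[r, f, a])
        return np.array(out)

    def transition_fraction(self) -> float:
        ts = self.counts[_TRANSITION[:, None, :] * np.ones((1, 4, 1), bool)].sum()
        return float(ts / self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        pms = self.per_million_substitutions
        pmd = self.per_million_dinucleotides
        for r in range(4):
            for f in range(4):
                for a in range(4):
                    if r == a:
                        continue
                    rows.append(
                        (BASES[f], BASES[r], BASES[a], int(self.counts[r, f, a]),
                         pmd[r, f, a], pms[r, f, a], bool(_TRANSITION[r, a]))
                    )
        return pd.DataFrame(
            rows,
            columns=["following", "ref", "alt", "count",
                     "rate_per_M_dinuc", "rate_per_M_subs", "transition"],
        )


def dinucleotide_spectrum(substitutions: pd.DataFrame, genome: Genome) -> SpectrumMatrix:
    """Tally substitutions by (mutated base, following base, new base).

    A substitution at a contig end (or followed by N) has no valid
    dinucleotide context and is counted in an explicit boundary bucket.
    """
    code = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((4, 4, 4), dtype=np.int64)
    boundary = 0
    for ctg, grp in substitutions.groupby("contig"):
        arr = genome.codes(ctg)
        pos = grp["pos"].to_numpy(np.int64)
        refs = np.array([code[r] for r in grp["ref"]], np.int64)
        alts = np.array([code[a] for a in grp["alt"]], np.int64)
        if np.any(arr[pos] != refs):
            bad = pos[arr[pos] != refs][0]
            raise ValueError(f"ref allele mismatch at {ctg}:{bad}")
        has_next = pos + 1 < arr.size
        nxt = np.where(has_next, arr[np.clip(pos + 1, 0, arr.size - 1)], 4)
        ok = has_next & (nxt < 4)
        boundary += int(np.count_nonzero(~ok))
        np.add.at(counts, (refs[ok], nxt[ok], alts[ok]), 1)
    return SpectrumMatrix(counts, genome.dinucleotide_counts(), boundary)


def spectrum_similarity(a, b, normalization: str = "per_million_substitutions") -> float:
    """Squared Pearson correlation between two spectra (or count vectors).

    The ``per_million_substitutions`` composition is the default; the
    ``per_million_dinucleotides`` rate normalization divides out genome
    dinucleotide abundance and sharpens the contrast between mutational
    processes that share a genome.
    """
    va = a.values_48(normalization) if isinstance(a, SpectrumMatrix) else np.asarray(a, float)
    vb = b.values_48(normalization) if isinstance(b, SpectrumMatrix) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError("spectra have different shapes")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero-variance spectrum; R^2 undefined")
    r = np.corrcoef(va, vb)[0, 1]
    return float(r ** 2)


def windowed_counts(
    variants: pd.DataFrame,
    genome: Genome,
    window_size: int = 1_000_000,
    scope: str | None = "intergenic",
) -> pd.DataFrame:
    """Per-window variant counts; trailing partial windows are flagged.

    If ``scope`` is given, the variant table must carry a ``region``
    column and only variants of that region class are counted.
    """
    df = variants
    if scope is not None:
        if "region" not in df.columns:
            raise ValueError("scope filtering requires a 'region' column")
        df = df[df["region"] == scope]
    frames = []
    for ctg in genome:
        L = genome.length(ctg)
        n_windows = int(np.ceil(L / window_size))
        if n_windows < 2:
            raise ValueError(f"contig {ctg} shorter than two windows")
        counts = np.zeros(n_windows, dtype=np.int64)
        sub = df[df["contig"] == ctg]
        if len(sub):
            np.add.at(counts, sub["pos"].to_numpy(np.int64) // window_size, 1)
        starts = np.arange(n_windows, dtype=np.int64) * window_size
        complete = (starts + window_size) <= L
        frames.append(
            pd.DataFrame(
                {"contig": ctg, "window_start": starts, "count": counts,
                 "complete": complete}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# replication-time profile
# ----------------------------------------------------------------------

def classify_substitution_types(substitutions: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Label transitions/transversions and the CpG-context G:C>A:T subset.

    A G:C>A:T change is "in CG" when the mutated C is followed by G, or
    the mutated G preceded by C, on the reference strand.
    """
    code = {b: i for i, b in enumerate(BASES)}
    df = substitutions.copy()
    refs = np.array([code[r] for r in df["ref"]])
    alts = np.array([code[a] for a in df["alt"]])
    df["transition"] = is_transition(refs, alts)
    in_cg = np.zeros(len(df), dtype=bool)
    for ctg, grp in df.groupby("contig"):
        arr = genome.codes(ctg)
        pos = grp["pos"].to_numpy(np.int64)
        r = refs[df["contig"].to_numpy() == ctg]
        a = alts[df["contig"].to_numpy() == ctg]
        nxt = np.where(pos + 1 < arr.size, arr[np.clip(pos + 1, 0, arr.size - 1)], 4)
        prv = np.where(pos - 1 >= 0, arr[np.clip(pos - 1, 0, arr.size - 1)], 4)
        c_to_t = (r == 1) & (a == 3) & (nxt == 2)
        g_to_a = (r == 2) & (a == 0) & (prv == 1)
        in_cg[df["contig"].to_numpy() == ctg] = c_to_t | g_to_a
    df["cpg_transition"] = df["transition"] & in_cg
    return df


@dataclass
class ReplicationProfile:
    bins: pd.DataFrame          # bin, n_windows, bases, ts_count, tv_count, ts_rel, tv_rel
    trend_pvalues: dict = field(default_factory=dict)


def replication_profile(
    substitutions: pd.DataFrame,
    replication_track: pd.DataFrame,
    genome: Genome,
    n_bins: int = 7,
    window_table: pd.DataFrame | None = None,
) -> ReplicationProfile:
    """Transition/transversion frequencies binned by replication time.

    CpG-context G:C>A:T transitions are excluded from the transition
    series.  Frequencies are reported relative to the earliest
    (lowest-track-value) bin.  If a window feature table is supplied, a
    covariate-adjusted linear-model trend p-value for replication time is
    attached (Bonferroni-corrected per model).
    """
    track = replication_track
    if track["value"].nunique() < n_bins:
        raise ValueError("fewer distinct replication-track values than bins")
    labeled = classify_substitution_types(substitutions, genome)

    # assign substitutions to track windows
    win = np.full(len(labeled), -1, dtype=np.int64)
    track = track.reset_index(drop=True)
    for ctg, grp in track.groupby("contig"):
        sel = np.flatnonzero((labeled["contig"] == ctg).to_numpy())
        idx = _intervals.point_lookup(
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            labeled["pos"].to_numpy(np.int64)[sel],
        )
        win[sel] = np.where(idx >= 0, grp.index.to_numpy()[idx], -1)
    labeled = labeled[win >= 0]
    win = win[win >= 0]

    ranks = track["value"].rank(method="first")
    bin_of_window = pd.qcut(ranks, n_bins, labels=False).to_numpy()
    bases = (track["end"] - track["start"]).to_numpy()

    rows = []
    sub_bin = bin_of_window[win]
    ts_mask = (labeled["transition"] & ~labeled["cpg_transition"]).to_numpy()
    tv_mask = (~labeled["transition"]).to_numpy()
    for b in range(n_bins):
        wsel = bin_of_window == b
        vsel = sub_bin == b
        rows.append(
            (b, int(wsel.sum()), int(bases[wsel].sum()),
             int(np.count_nonzero(vsel & ts_mask)),
             int(np.count_nonzero(vsel & tv_mask)))
        )
    bins = pd.DataFrame(rows, columns=["bin", "n_windows", "bases", "ts_count", "tv_count"])
    ts_rate = bins["ts_count"] / bins["bases"]
    tv_rate = bins["tv_count"] / bins["bases"]
    bins["ts_rel"] = ts_rate / ts_rate.iloc[0]
    bins["tv_rel"] = tv_rate / tv_rate.iloc[0]

    pvals = {}
    if window_table is not None:
        from .covariates import fit_mutation_rate_model

        for resp in ("transitions", "transversions"):
            fit = fit_mutation_rate_model(window_table, response=resp)
            row = fit.table.set_index("feature").loc["replication_time"]
            pvals[resp] = {
                "p": float(row["p"]),
                "bonferroni_significant": bool(row["significant"]),
            }
    return ReplicationProfile(bins, pvals)


# ----------------------------------------------------------------------
# flanking slippage
# ----------------------------------------------------------------------

@dataclass
class FlankingSlippage:
    conversion: pd.DataFrame        # homopolymer composition x new base counts
    fold_overall: float
    fold_homopolymer: float
    fold_microsatellite: float
    n_flanking: int
    empty: bool = False


def flanking_slippage(
    substitutions: pd.DataFrame,
    repeat_index: RepeatIndex,
    callable_length: int,
) -> FlankingSlippage:
    """Substitution excess and base-conversion pattern at repeat-flanking bases.

    The fold is the substitution rate at the two bases immediately
    flanking a run divided by the genome-wide substitution rate, overall
    and split by homopolymer vs microsatellite.  For homopolymers the
    distribution of the new base is tabulated per run composition (An,
    Cn, Gn, Tn); polymerase slippage converts the flanking base to the
    repeat base.
    """
    flanks = repeat_index.flanking_positions(kinds=("homopolymer", "microsatellite"))
    genome_rate = len(substitutions) / callable_length
    key = ["contig", "pos"]
    merged = substitutions.merge(flanks, on=key, how="inner")
    n_flank = len(merged)

    conv = pd.DataFrame(0, index=list(BASES), columns=list(BASES))
    hp = merged[merged["kind"] == "homopolymer"]
    for comp, grp in hp.groupby(hp["unit"].str[0]):
        for alt, c in grp["alt"].value_counts().items():
            conv.loc[comp, alt] += int(c)

    def _fold(kind: str | None) -> float:
        sel_f = flanks if kind is None else flanks[flanks["kind"] == kind]
        sel_m = merged if kind is None else merged[merged["kind"] == kind]
        if len(sel_f) == 0 or genome_rate == 0:
            return float("nan")
        return (len(sel_m) / len(sel_f)) / genome_rate

    return FlankingSlippage(
        conversion=conv,
        fold_overall=_fold(None),
        fold_homopolymer=_fold("homopolymer"),
        fold_microsatellite=_fold("microsatellite"),
        n_flanking=n_flank,
        empty=(n_flank == 0),
    )


# ----------------------------------------------------------------------
# CpG islands
# ----------------------------------------------------------------------

def cpg_island_rates(
    substitutions: pd.DataFrame,
    islands: pd.DataFrame,
    genome: Genome,
) -> pd.DataFrame:
    """Substitution frequency in/outside CpG islands relative to genome-wide.

    Rows: all / transitions / transversions; columns: relative_in,
    relative_out and their ratio.  Mutation counts are divided by the
    total size of each feature and expressed relative to the genome-wide
    frequency.
    """
    if len(islands) == 0:
        raise ValueError("no CpG islands in track; in-island frequency undefined")
    island_bases = int((islands["end"] - islands["start"]).sum())
    callable_length = genome.callable_length()
    out_bases = callable_length - island_bases
    if out_bases <= 0:
        raise ValueError("islands cover the whole genome; out-island rate undefined")

    labeled = classify_substitution_types(substitutions, genome)
    inside = np.zeros(len(labeled), dtype=bool)
    for ctg, grp in islands.groupby("contig"):
        s, e = _intervals.merge(grp["start"].to_numpy(), grp["end"].to_numpy())
        sel = np.flatnonzero((labeled["contig"] == ctg).to_numpy())
        idx = _intervals.point_lookup(s, e, labeled["pos"].to_numpy(np.int64)[sel])
        inside[sel] = idx >= 0

    rows = []
    for name, mask in (
        ("all", np.ones(len(labeled), bool)),
        ("transitions", labeled["transition"].to_numpy()),
        ("transversions", (~labeled["transition"]).to_numpy()),
    ):
        n = int(mask.sum())
        if n == 0:
            rows.append((name, np.nan, np.nan, np.nan))
            continue
        overall = n / callable_length
        rate_in = int((mask & inside).sum()) / island_bases / overall
        rate_out = int((mask & ~inside).sum()) / out_bases / overall
        rows.append((name, rate_in, rate_out, rate_in / rate_out if rate_out else np.nan))
    return pd.DataFrame(rows, columns=["series", "relative_in", "relative_out", "ratio"])


# ----------------------------------------------------------------------
# indel profile
# ----------------------------------------------------------------------

@dataclass
class IndelProfile:
    length_histogram: pd.Series      # signed length (deletions negative) -> fraction
    deletion_fraction: float
    per_base: pd.DataFrame           # homopolymer composition: runs, affected, fractions
    by_length: pd.DataFrame          # homopolymer length -> affected fraction
    cg_affected_share: float
    cg_run_share: float


def indel_profile(indels: pd.DataFrame, repeat_index: RepeatIndex) -> IndelProfile:
    """Indel length spectrum and per-composition homopolymer hit fractions.

    ``indels`` must have been classified (``run_id`` column).  Affected
    fractions are over the cohort union: a homopolymer counts as affected
    if at least one indel of any sample maps to it.
    """
    signed = indels["alt"].str.len() - indels["ref"].str.len()
    hist = (signed.value_counts() / len(indels)).sort_index()
    deletion_fraction = float((signed < 0).mean())

    runs = repeat_index.runs
    hp = runs[runs["kind"] == "homopolymer"]
    affected_ids = set(indels.loc[indels["run_id"] >= 0, "run_id"])
    hp_aff = hp.index.isin(affected_ids)

    rows = []
    for base in BASES:
        sel = hp["unit"] == base
        n = int(sel.sum())
        a = int((sel & hp_aff).sum())
        rows.append((base, n, a, a / n if n else np.nan))
    per_base = pd.DataFrame(rows, columns=["base", "n_runs", "n_affected", "fraction_affected"])

    by_len = (
        pd.DataFrame({"length": hp["length"].to_numpy(), "affected": hp_aff})
        .groupby("length")
        .agg(n_runs=("affected", "size"), n_affected=("affected", "sum"))
        .reset_index()
    )
    by_len["fraction_affected"] = by_len["n_affected"] / by_len["n_runs"]

    cg_runs = hp["composition"] == "CG"
    n_aff_total = int(hp_aff.sum())
    cg_affected_share = (
        int((cg_runs.to_numpy() & hp_aff).sum()) / n_aff_total if n_aff_total else np.nan
    )
    cg_run_share = float(cg_runs.mean()) if len(hp) else np.nan
    return IndelProfile(hist, deletion_fraction, per_base, by_len,
                        cg_affected_share, cg_run_share)


# ----------------------------------------------------------------------
# nearest-distance null
# ----------------------------------------------------------------------

@dataclass
class DistanceNullResult:
    bin_lower: np.ndarray
    bin_upper: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray
    n_random: int


def _nearest_distance(positions, starts, ends):
    """Distance from each position to the nearest interval (0 inside)."""
    d = np.full(positions.size, np.iinfo(np.int64).max, dtype=np.int64)
    if starts.size == 0:
        return d
    idx = np.searchsorted(starts, positions, side="right") - 1
    prev_ok = idx >= 0
    inside = prev_ok & (positions < ends[np.clip(idx, 0, None)])
    d[inside] = 0
    gap_prev = np.where(prev_ok, positions - ends[np.clip(idx, 0, None)] + 1, np.iinfo(np.int64).max)
    nxt = idx + 1
    nxt_ok = nxt < starts.size
    gap_next = np.where(nxt_ok, starts[np.clip(nxt, 0, starts.size - 1)] - positions, np.iinfo(np.int64).max)
    d[~inside] = np.minimum(gap_prev, gap_next)[~inside]
    return d


def nearest_distance_null(
    substitutions: pd.DataFrame,
    features: pd.DataFrame,
    callable_intervals: pd.DataFrame,
    n_random: int = 200,
    seed: int = 0,
    n_log_bins: int = 16,
) -> DistanceNullResult:
    """Observed vs randomized nearest-feature distances, in log-spaced bins.

    Random placements preserve the total variant count per sample and are
    drawn uniformly over the callable intervals; the expected histogram is
    the mean over ``n_random`` replicates.  Bins are {0-1, 2-3, 4-7, ...}.
    """
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    if len(features) == 0:
        raise ValueError("feature set is empty")

    feat = {}
    for ctg, grp in features.groupby("contig"):
        feat[ctg] = _intervals.merge(grp["start"].to_numpy(), grp["end"].to_numpy())

    def _distances(contigs, positions):
        d = np.empty(positions.size, dtype=np.int64)
        for ctg in pd.unique(contigs):
            sel = contigs == ctg
            s, e = feat.get(ctg, (np.empty(0, np.int64), np.empty(0, np.int64)))
            d[sel] = _nearest_distance(positions[sel], s, e)
        return d

    def _bin(d):
        # bins {0-1, 2-3, 4-7, 8-15, ...}
        b = np.where(d < 2, 0, np.floor(np.log2(np.maximum(d, 1))).astype(int))
        return np.minimum(b, n_log_bins - 1)

    obs_d = _distances(substitutions["contig"].to_numpy(), substitutions["pos"].to_numpy(np.int64))
    observed = np.bincount(_bin(obs_d), minlength=n_log_bins).astype(float)

    # flatten callable space for uniform draws
    c_ctg, c_start, c_end = [], [], []
    for _, row in callable_intervals.iterrows():
        c_ctg.append(row["contig"])
        c_start.append(int(row["start"]))
        c_end.append(int(row["end"]))
    lens = np.array(c_end) - np.array(c_start)
    cum = np.concatenate(([0], np.cumsum(lens)))
    total = int(cum[-1])

    rng = np.random.default_rng(seed)
    n = len(substitutions)
    expected = np.zeros(n_log_bins)
    for _ in range(n_random):
        flat = rng.integers(0, total, size=n)
        iv = np.searchsorted(cum, flat, side="right") - 1
        pos = np.array(c_start)[iv] + (flat - cum[iv])
        ctgs = np.array(c_ctg, dtype=object)[iv]
        expected += np.bincount(_bin(_distances(ctgs, pos)), minlength=n_log_bins)
    expected /= n_random
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(expected > 0, observed / expected, np.nan)
    lower = np.array([0] + [2 ** b for b in range(1, n_log_bins)])
    upper = np.array([1] + [2 ** (b + 1) - 1 for b in range(1, n_log_bins)])
    return DistanceNullResult(lower, upper, observed, expected, enrichment, n_random)
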