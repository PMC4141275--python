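"""Per-window genomic feature tables and multivariate mutation-rate models.

Nine features are tabulated per fixed-size window (1 Mb by convention):
distance to the nearer chromosome end (from the window midpoint),
replication time, simple-repeat bases (homopolymer + microsatellite),
GC fraction computed as (G+C)/(A+C+G+T), CpG dinucleotide bases, CpG
island bases, gene-content bases, and proxies for DNase accessibility
and nuclear-lamina association.  Mutation counts per window are modelled
jointly by ordinary least squares on standardized features; t-values are
reported with Bonferroni correction per model (0.05 / number of features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .genome import C, G, Genome
from .repeats import RepeatIndex
from .spectrum import classify_substitution_types

FEATURES = (
    "distance_to_telomere",
    "replication_time",
    "simple_repeat_bases",
    "gc_fraction",
    "cpg_dinucleotide_bases",
    "cpg_island_bases",
    "gene_content_bases",
    "dnase_site_bases",
    "lamina_bases",
)

RESPONSES = ("substitutions", "indels", "transitions", "transversions")


def _interval_window_overlap(starts, ends, window_size, n_windows):
    """Base overlap of intervals with each window of a tiling grid."""
    out = np.zeros(n_windows, dtype=np.int64)
    if len(starts) == 0:
        return out
    starts = np.asarray(starts, np.int64)
    ends = np.asarray(ends, np.int64)
    w0 = starts // window_size
    w1 = (ends - 1) // window_size
    same = w0 == w1
    np.add.at(out, w0[same], (ends - starts)[same])
    for s, e in zip(starts[~same], ends[~same]):
        for w in range(s // window_size, e // window_size + 1):
            lo = max(s, w * window_size)
            hi = min(e, (w + 1) * window_size)
            if hi > lo and w < n_windows:
                out[w] += hi - lo
    return out


def build_window_table(
    genome: Genome,
    repeat_index: RepeatIndex,
    variants: pd.DataFrame,
    regions: pd.DataFrame,
    replication_track: pd.DataFrame,
    cpg_islands: pd.DataFrame | None = None,
    dnase_track: pd.DataFrame | None = None,
    lamina_track: pd.DataFrame | None = None,
    window_size: int = 1_000_000,
    max_uncallable_fraction: float = 0.5,
) -> pd.DataFrame:
    """Assemble the per-window feature/response table.

    ``replication_track`` (and the optional DNase/lamina tracks) are
    interval tables with a ``value`` column (for the proxies, ``value``
    is interpreted as covered-base density in [0, 1]).  Windows with more
    than half uncallable bases are dropped.
    """
    rows = []
    labeled = classify_substitution_types(
        variants[variants["variant_class"] == "substitution"], genome
    )
    indels = variants[variants["variant_class"] != "substitution"]
    runs = repeat_index.runs

    total_windows = sum(
        genome.length(ctg) // window_size for ctg in genome
    )
    if total_windows < 10:
        raise ValueError(
            "window size yields fewer than 10 complete windows; model unidentifiable"
        )

    for ctg in genome:
        L = genome.length(ctg)
        n_windows = L // window_size  # complete windows only
        if n_windows == 0:
            continue
        arr = genome.codes(ctg)
        edges = np.arange(n_windows + 1) * window_size

        ctg_runs = runs[runs["contig"] == ctg]
        repeat_bases = _interval_window_overlap(
            ctg_runs["start"], ctg_runs["end"], window_size, n_windows
        )
        ctg_regions = regions[regions["contig"] == ctg]
        genic = ctg_regions[ctg_regions["region"] != "intergenic"]
        gene_bases = _interval_window_overlap(
            genic["start"], genic["end"], window_size, n_windows
        )

        def _track_mean(track):
            vals = np.zeros(n_windows)
            cov = np.zeros(n_windows)
            if track is None:
                return vals
            sub = track[track["contig"] == ctg]
            for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
                ov = _interval_window_overlap([s], [e], window_size, n_windows)
                vals += ov * v
                cov += ov
            with np.errstate(invalid="ignore"):
                return np.where(cov > 0, vals / np.maximum(cov, 1), np.nan)

        rep = _track_mean(replication_track)
        dnase = _track_mean(dnase_track) if dnase_track is not None else np.zeros(n_windows)
        lamina = _track_mean(lamina_track) if lamina_track is not None else np.zeros(n_windows)

        if cpg_islands is not None:
            ctg_isl = cpg_islands[cpg_islands["contig"] == ctg]
            island_bases = _interval_window_overlap(
                ctg_isl["start"], ctg_isl["end"], window_size, n_windows
            )
        else:
            island_bases = np.zeros(n_windows, dtype=np.int64)

        lab_ctg = labeled[labeled["contig"] == ctg]
        ind_ctg = indels[indels["contig"] == ctg]

        def _win_counts(pos):
            w = np.asarray(pos, np.int64) // window_size
            w = w[w < n_windows]
            return np.bincount(w, minlength=n_windows)

        sub_counts = _win_counts(lab_ctg["pos"])
        ts_counts = _win_counts(lab_ctg.loc[lab_ctg["transition"] & ~lab_ctg["cpg_transition"], "pos"])
        tv_counts = _win_counts(lab_ctg.loc[~lab_ctg["transition"], "pos"])
        ind_counts = _win_counts(ind_ctg["pos"])

        for w in range(n_windows):
            s, e = int(edges[w]), int(edges[w + 1])
            window = arr[s:e]
            callable_b = int(np.count_nonzero(window < 4))
            if callable_b < (e - s) * (1 - max_uncallable_fraction):
                continue
            mid = (s + e) / 2
            dist_telomere = min(mid, L - mid)
            acgt = window[window < 4]
            gc = float(np.count_nonzero((acgt == C) | (acgt == G)) / acgt.size)
            pair_cg = int(np.count_nonzero((window[:-1] == C) & (window[1:] == G)))
            rows.append(
                (ctg, s, e, dist_telomere, rep[w], int(repeat_bases[w]), gc,
                 pair_cg, int(island_bases[w]), int(gene_bases[w]),
                 dnase[w], lamina[w],
                 int(sub_counts[w]), int(ind_counts[w]),
                 int(ts_counts[w]), int(tv_counts[w]))
            )
    table = pd.DataFrame(
        rows,
        columns=["contig", "start", "end", *FEATURES,
                 "substitutions", "indels", "transitions", "transversions"],
    )
    if table[list(FEATURES)].isna().any().any():
        n0 = len(table)
        table = table.dropna(subset=list(FEATURES)).reset_index(drop=True)
        warnings.warn(f"dropped {n0 - len(table)} windows lacking track coverage")
    return table


@dataclass
class ModelFit:
    table: pd.DataFrame   # feature, coef, t, p, significant
    r_squared: float
    n_windows: int
    response: str
    alpha: float


def fit_mutation_rate_model(
    window_table: pd.DataFrame,
    response: str = "substitutions",
    features: tuple = FEATURES,
    alpha: float = 0.05,
    condition_threshold: float = 1e8,
) -> ModelFit:
    """OLS of per-window mutation counts on all features jointly.

    Features are standardized (zero mean, unit variance) before fitting so
    t-values are scale-free and comparable across features.  Two-sided
    p-values carry a per-model Bonferroni flag at ``alpha / n_features``.
    Collinear feature sets trigger a warning with a variance-inflation
    report but the fit is still returned.
    """
    if response not in window_table.columns:
        raise ValueError(f"unknown response {response!r}")
    if len(window_table) < 10:
        raise ValueError("need at least 10 windows to fit the model")
    X = window_table[list(features)].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        flat = [f for f, s in zip(features, sd) if s == 0]
        raise ValueError(f"features with zero variance: {flat}")
    Xs = (X - X.mean(axis=0)) / sd
    y = window_table[response].to_numpy(dtype=float)

    design = sm.add_constant(Xs)
    if np.linalg.cond(design) > condition_threshold:
        vifs = {
            f: float(variance_inflation_factor(Xs, i))
            for i, f in enumerate(features)
        }
        warnings.warn(f"collinear features; VIF report: {vifs}")
    fit = sm.OLS(y, design).fit()

    bonf = alpha / len(features)
    rows = []
    for i, f in enumerate(features):
        rows.append(
            (f, float(fit.params[i + 1]), float(fit.tvalues[i + 1]),
             float(fit.pvalues[i + 1]), bool(fit.pvalues[i + 1] < bonf))
        )
    table = pd.DataFrame(rows, columns=["feature", "coef", "t", "p", "significant"])
    return ModelFit(table, float(fit.rsquared), len(window_table), response, alpha)
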