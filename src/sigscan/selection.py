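"""Homopolymer-corrected regional indel frequencies (negative-selection statistic).

Raw per-region indel frequencies confound selection with homopolymer
content: regions differ in how many homopolymers they carry, how long
they are and their base composition, and slippage rates rise steeply
with run length.  The correction cascade removes these three confounders
by working per stratum (location t, composition c in {AT, CG}, length l):

    Freq[t,c,l]   = affected homopolymers / homopolymers
    rFreq[t,c,l]  = Freq[t,c,l] / Freq[genomic,c,l]
    wrFreq[t,c,l] = rFreq * n[t,c,l] / sum_l n[t,c,l]          (within c)
    nwrFreq       = wrFreq * n[t,c,l] / (n[t,AT,l] + n[t,CG,l])
    cFreq[t]      = sum over c and l of nwrFreq
    rFreq[t]      = cFreq[t] / cFreq[genomic]

so that equal per-stratum hit rates in every location yield rFreq[t] = 1
regardless of each location's homopolymer mixture, and a uniform
depletion of exonic hit rates surfaces directly as exonic rFreq < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _intervals

log = logging.getLogger(__name__)

GENOMIC = "genomic"


def assign_run_locations(runs: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``location`` column to a repeat-run table.

    A run belongs to the region containing its leftmost base; runs that
    straddle a region boundary are assigned by majority overlap (ties go
    to the leftmost base's region).
    """
    out = runs.copy()
    loc = np.full(len(out), None, dtype=object)
    for ctg, grp in regions.groupby("contig"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        labels = grp["region"].to_numpy()
        sel = np.flatnonzero((out["contig"] == ctg).to_numpy())
        r_start = out["start"].to_numpy(np.int64)[sel]
        r_end = out["end"].to_numpy(np.int64)[sel]
        i0 = _intervals.point_lookup(starts, ends, r_start)
        i1 = _intervals.point_lookup(starts, ends, r_end - 1)
        if (i0 < 0).any():
            bad = sel[i0 < 0][0]
            raise ValueError(f"run {out.index[bad]} not covered by region annotation")
        res = labels[i0].copy()
        straddle = np.flatnonzero((i0 != i1) & (i1 >= 0))
        for j in straddle:
            s, e = r_start[j], r_end[j]
            best_label, best_ov = labels[i0[j]], -1
            for k in range(i0[j], i1[j] + 1):
                ov = min(e, ends[k]) - max(s, starts[k])
                if ov > best_ov:
                    best_ov, best_label = ov, labels[k]
            res[j] = best_label
        loc[sel] = res
    missing = [i for i, v in enumerate(loc) if v is None]
    if missing:
        raise ValueError(f"run {out.index[missing[0]]} has no location annotation")
    out["location"] = loc
    return out


@dataclass
class CorrectionCascade:
    strata: pd.DataFrame     # location, composition, length, n, n_affected, freq, rfreq, wrfreq, nwrfreq
    summary: pd.DataFrame    # location, cfreq, rfreq_final
    mode: str
    n_excluded_strata: int


def corrected_region_indel_frequency(
    indels: pd.DataFrame,
    runs: pd.DataFrame,
    mode: str = "union",
    length_cap: int = 30,
    samples=None,
) -> CorrectionCascade:
    """Run the full correction cascade over homopolymer strata.

    ``indels`` must carry ``run_id`` (from context classification) and
    ``sample``; ``runs`` must carry a ``location`` column (see
    :func:`assign_run_locations`).  In ``union`` mode a homopolymer is
    affected when any cohort indel maps to it (the binary per-cohort
    statistic); ``per_sample`` flags each (homopolymer, sample) pair;
    ``rate`` counts indel events per pair, which is exactly linear in
    per-sample hit rates and therefore the mode of choice for parameter
    recovery.  Lengths are capped at ``length_cap`` with a pooled top
    stratum.
    """
    if mode not in ("union", "per_sample", "rate"):
        raise ValueError("mode must be 'union', 'per_sample' or 'rate'")
    hp = runs[runs["kind"] == "homopolymer"]
    if "location" not in hp.columns or hp["location"].isna().any():
        bad = hp.index[hp["location"].isna()][0] if "location" in hp.columns else "?"
        raise ValueError(f"run {bad} lacks a location annotation")
    if samples is None:
        samples = sorted(indels["sample"].unique())
    m = len(samples)

    lengths = np.minimum(hp["length"].to_numpy(), length_cap)
    base = pd.DataFrame(
        {
            "run_id": hp.index.to_numpy(),
            "location": hp["location"].to_numpy(),
            "composition": hp["composition"].to_numpy(),
            "length": lengths,
        }
    )

    hits = indels[indels["run_id"].isin(set(hp.index))]
    if mode == "union":
        affected = set(hits["run_id"].unique())
        base["n_affected"] = base["run_id"].isin(affected).astype(int)
        base["n"] = 1
    elif mode == "per_sample":
        per_pair = hits.groupby("run_id")["sample"].nunique()
        base["n_affected"] = base["run_id"].map(per_pair).fillna(0).astype(int)
        base["n"] = m
    else:  # rate: indel events per (homopolymer, sample); linear in hit rates
        per_run = hits.groupby("run_id").size()
        base["n_affected"] = base["run_id"].map(per_run).fillna(0).astype(int)
        base["n"] = m

    def _table(df, label=None):
        d = df if label is None else df.assign(location=label)
        return (
            d.groupby(["location", "composition", "length"])[["n", "n_affected"]]
            .sum()
            .reset_index()
        )

    strata = pd.concat(
        [_table(base), _table(base, GENOMIC)], ignore_index=True
    )
    strata["freq"] = strata["n_affected"] / strata["n"]

    genome = strata[strata["location"] == GENOMIC].set_index(["composition", "length"])["freq"]
    gdict = genome.to_dict()
    strata["genome_freq"] = [
        gdict.get((c, l), np.nan)
        for c, l in zip(strata["composition"], strata["length"])
    ]

    usable = strata["genome_freq"] > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("excluding %d strata with zero genome-wide frequency", n_excluded)
    strata["rfreq"] = np.where(usable, strata["freq"] / strata["genome_freq"], np.nan)

    # length weight within (location, composition)
    n_tc = strata.groupby(["location", "composition"])["n"].transform("sum")
    strata["wrfreq"] = strata["rfreq"] * strata["n"] / n_tc
    # composition weight within (location, length)
    n_tl = strata.groupby(["location", "length"])["n"].transform("sum")
    strata["nwrfreq"] = strata["wrfreq"] * strata["n"] / n_tl

    summary = (
        strata[usable]
        .groupby("location")["nwrfreq"]
        .sum()
        .rename("cfreq")
        .reset_index()
    )
    c_genomic = float(summary.loc[summary["location"] == GENOMIC, "cfreq"].iloc[0])
    summary["rfreq_final"] = summary["cfreq"] / c_genomic
    return CorrectionCascade(strata, summary, mode, n_excluded)
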