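"""Cohort indel recurrence at homopolymer loci and MSI marker candidate selection.

A locus is a reference homopolymer run, keyed by its coordinates — not by
the indel allele, so a 1 bp and a 2 bp deletion at the same run count as
one recurrent locus (marker assays interrogate the locus).  The null
expectation for recurrence stratifies by homopolymer length: with m
samples and a per-sample hit rate p(l) estimated from the cohort's
marginal affected fractions, the number of loci of length l affected in
at least k samples is binomial-tailed under independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RecurrenceTable:
    loci: pd.DataFrame          # locus_id, run_id, contig, start, unit, length, region?, k
    flags: pd.DataFrame         # loci x samples boolean
    samples: list

    @property
    def m(self) -> int:
        return len(self.samples)


def tabulate_recurrence(
    indels: pd.DataFrame,
    runs: pd.DataFrame,
    samples,
    kinds=("homopolymer",),
) -> RecurrenceTable:
    """Per-locus affected flags and recurrence count k across the cohort."""
    samples = list(samples)
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample labels: {dupes}")
    loci = runs[runs["kind"].isin(kinds)].copy()
    loci["locus_id"] = (
        loci["contig"].astype(str) + ":" + loci["start"].astype(str)
        + ":" + loci["unit"] + ":" + loci["length"].astype(str)
    )
    hits = indels[indels["run_id"].isin(set(loci.index))]
    unknown = set(hits["sample"].unique()) - set(samples)
    if unknown:
        raise ValueError(f"indel samples not in cohort sample list: {sorted(unknown)}")
    flags = (
        pd.crosstab(hits["run_id"], hits["sample"]).astype(bool)
        .reindex(index=loci.index, columns=samples, fill_value=False)
    )
    loci["k"] = flags.sum(axis=1).astype(int)
    cols = ["locus_id", "contig", "start", "end", "unit", "length", "k"]
    if "location" in loci.columns:
        cols.append("location")
    return RecurrenceTable(loci[cols], flags, samples)


def expected_recurrence_null(
    table: RecurrenceTable,
    thresholds=(2, 3, 4, 5),
) -> pd.DataFrame:
    """Observed vs binomial-null expected counts of loci affected in >= k samples.

    The per-sample hit rate p(l) is estimated per homopolymer length by
    pooling compositions: total affected flags among loci of length l
    divided by (number of such loci x m).  The top threshold is open
    (">= k").  Returns a frame with observed, expected and enrichment per
    (length, k).
    """
    m = table.m
    loci = table.loci
    flags = table.flags
    rows = []
    for length, grp in loci.groupby("length"):
        n_l = len(grp)
        total_flags = int(flags.loc[grp.index].to_numpy().sum())
        p_hat = total_flags / (n_l * m)
        for k in thresholds:
            observed = int((grp["k"] >= k).sum())
            if p_hat >= 1.0:
                expected = float(n_l) if k <= m else 0.0
            else:
                expected = float(n_l * stats.binom.sf(k - 1, m, p_hat))
            enrichment = observed / expected if expected > 0 else np.nan
            rows.append((int(length), k, n_l, p_hat, observed, expected, enrichment))
    return pd.DataFrame(
        rows,
        columns=["length", "k", "n_loci", "p_hat", "observed", "expected", "enrichment"],
    )


def select_candidate_markers(
    table: RecurrenceTable,
    sample_tissues: dict,
    min_recurrence: int = 6,
    max_length: int = 12,
    required_tissues=None,
    require_tissue_rule: bool = True,
) -> pd.DataFrame:
    """Apply the marker-candidate rules to a recurrence table.

    Rules: (i) affected in at least ``min_recurrence`` samples, (ii)
    detected in every required tissue (by default all tissues present in
    the cohort), (iii) homopolymer length at most ``max_length``.  Output
    is sorted by recurrence (descending) then locus id.
    """
    missing = [s for s in table.samples if s not in sample_tissues]
    if missing:
        raise ValueError(f"samples without tissue label: {missing}")
    tissues = {sample_tissues[s] for s in table.samples}
    if required_tissues is None:
        required_tissues = tissues
    required_tissues = set(required_tissues)
    if require_tissue_rule and len(tissues) < 2:
        raise ValueError(
            "cohort has a single tissue; cross-tissue rule cannot be evaluated "
            "(pass require_tissue_rule=False to disable)"
        )

    loci = table.loci
    pre = loci[(loci["k"] >= min_recurrence) & (loci["length"] <= max_length)]
    flags = table.flags.loc[pre.index]
    keep = []
    observed_tissues = []
    for rid in pre.index:
        row = flags.loc[rid]
        seen = {sample_tissues[s] for s in row.index[row]}
        ok = (not require_tissue_rule) or required_tissues <= seen
        keep.append(ok)
        observed_tissues.append(",".join(sorted(seen)))
    out = pre.copy()
    out["tissues"] = observed_tissues
    out = out[np.array(keep, dtype=bool)]
    return out.sort_values(["k", "locus_id"], ascending=[False, True]).reset_index(drop=True)
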