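"""Loss-of-function indel burden per gene set.

Counts, per sample, the indels expected to disrupt a gene's product:
frameshift indels inside coding exons (length not a multiple of three)
plus any indel within a configurable flank (default 25 bp) of an exon
boundary — splice-region events are counted regardless of frame.  Core
mismatch-repair genes can be excluded so the hypermutator driver does
not inflate pathway burdens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MMR_GENES = ("MLH1", "MSH2", "MSH6", "MSH3", "PMS1", "PMS2")


@dataclass
class GeneSetBurden:
    gene_set: str
    per_sample: pd.Series      # indel count per sample (all cohort samples)
    n_affected: int            # samples with >= 1 counted indel
    mean: float
    se: float


def annotate_indels_to_exons(
    indels: pd.DataFrame, exons: pd.DataFrame, flank_bp: int = 25
) -> pd.DataFrame:
    """Attach gene, in_exon and distance-to-exon columns to an indel table.

    ``exons`` needs columns contig, start, end, gene (0-based half-open).
    Each indel is assigned to the nearest exon within ``flank_bp`` (or
    containing it); others get gene = NaN.
    """
    out = indels.copy()
    genes = np.full(len(out), None, dtype=object)
    in_exon = np.zeros(len(out), dtype=bool)
    dist = np.full(len(out), np.inf)
    for ctg, grp in exons.groupby("contig"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        names = grp["gene"].to_numpy()
        sel = np.flatnonzero((out["contig"] == ctg).to_numpy())
        pos = out["pos"].to_numpy(np.int64)[sel] + 1  # first changed base
        for j, p in zip(sel, pos):
            inside = (starts <= p) & (p < ends)
            if inside.any():
                idx = int(np.flatnonzero(inside)[0])
                genes[j], in_exon[j], dist[j] = names[idx], True, 0
                continue
            d = np.minimum(np.abs(starts - p), np.abs(p - (ends - 1)))
            idx = int(np.argmin(d))
            if d[idx] <= flank_bp:
                genes[j], dist[j] = names[idx], int(d[idx])
    out["gene"] = genes
    out["in_exon"] = in_exon
    out["exon_distance"] = dist
    return out


def gene_set_burden(
    indels: pd.DataFrame,
    gene_set,
    samples,
    set_name: str = "gene_set",
    flank_bp: int = 25,
    exclude_mmr: bool = False,
    exclude_genes=(),
) -> GeneSetBurden:
    """Per-sample loss-of-function indel counts within a gene set.

    ``indels`` must carry sample, gene, in_exon, exon_distance and an
    ``indel_length`` column (signed or absolute; only divisibility by 3
    matters).  Exonic indels count when frameshift; flank indels (0 <
    distance <= flank_bp) count regardless of frame.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    samples = list(samples)
    excluded = set(exclude_genes) | (set(MMR_GENES) if exclude_mmr else set())
    wanted = [g for g in gene_set if g not in excluded]

    known = set(indels["gene"].dropna().unique())
    unmapped = sorted(set(wanted) - known)
    if unmapped:
        warnings.warn(f"gene symbols with no mapped indels: {unmapped}")

    df = indels[indels["gene"].isin(wanted)].copy()
    frameshift = df["in_exon"] & (df["indel_length"].abs() % 3 != 0)
    boundary = ~df["in_exon"] & (df["exon_distance"] > 0) & (df["exon_distance"] <= flank_bp)
    df = df[frameshift | boundary]

    counts = df.groupby("sample").size().reindex(samples, fill_value=0)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(len(samples))) if len(samples) > 1 else float("nan")
    return GeneSetBurden(
        gene_set=set_name,
        per_sample=counts,
        n_affected=int((counts > 0).sum()),
        mean=mean,
        se=se,
    )
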