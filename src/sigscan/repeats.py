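"""Repeat detection, variant context classification and enrichment statistics.

Repeat classes follow the standard MSI conventions: a *homopolymer* is a
mononucleotide run of at least six bases, a *short homopolymer* one of
3-5 bases, and a *microsatellite* a tandem repeat of a 2-6 bp unit with
total length of at least six bases and at least two units.  Runs are
maximal and N breaks them.  A mononucleotide run is never additionally
reported as a microsatellite with a doubled unit: microsatellite units
must be primitive (not themselves a repetition of a shorter word).

Somatic variants are classified into these contexts with precedence
homopolymer > microsatellite > short_homopolymer > non_repeat when runs
overlap; an indel is considered to *affect* a run when its inserted or
deleted sequence is a whole number of that run's units and its span
intersects the run (left-normalized indels sit at the run's 5' anchor,
which abuts the run start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from . import _intervals
from .genome import Genome, decode, encode

log = logging.getLogger(__name__)

KIND_PRECEDENCE = ("homopolymer", "microsatellite", "short_homopolymer")
CONTEXT_CLASSES = KIND_PRECEDENCE + ("non_repeat",)

REGION_LABELS = (
    "exonic",
    "intronic",
    "5'UTR",
    "3'UTR",
    "ncRNA",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass(frozen=True)
class RepeatRun:
    """One maximal repeat locus (0-based half-open coordinates)."""

    contig: str
    start: int
    end: int
    unit: str
    unit_count: int
    kind: str
    composition: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _primitive(unit_codes: np.ndarray) -> bool:
    k = unit_codes.size
    for d in range(1, k):
        if k % d == 0 and np.all(unit_codes == np.tile(unit_codes[:d], k // d)):
            return False
    return True


def _runs_of(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) of maximal True runs in a boolean array."""
    if mask.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return edges[0::2].astype(np.int64), edges[1::2].astype(np.int64)


def homopolymer_runs(codes: np.ndarray, min_length: int = 6):
    """Fast mononucleotide-run enumeration: (starts, ends, bases) arrays."""
    if codes.size == 0:
        empty = np.empty(0, np.int64)
        return empty, empty, np.empty(0, np.uint8)
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    bases = codes[starts]
    keep = (bases < 4) & ((ends - starts) >= min_length)
    return starts[keep], ends[keep], bases[keep]


def scan_repeats(
    sequence,
    *,
    min_homopolymer: int = 6,
    min_short_homopolymer: int = 3,
    min_microsatellite_total: int = 6,
    max_unit: int = 6,
    contig: str = "chr1",
) -> pd.DataFrame:
    """Scan sequence(s) for homopolymers, short homopolymers and microsatellites.

    ``sequence`` may be a string/bytes, a uint8 code array, or a
    :class:`~sigscan.genome.Genome` (all contigs are scanned).  Returns a
    DataFrame with columns contig, start, end, unit, unit_count, length,
    kind, composition, sorted by (contig, start, end).
    """
    if isinstance(sequence, Genome):
        frames = [
            scan_repeats(
                sequence.codes(name),
                min_homopolymer=min_homopolymer,
                min_short_homopolymer=min_short_homopolymer,
                min_microsatellite_total=min_microsatellite_total,
                max_unit=max_unit,
                contig=name,
            )
            for name in sequence
        ]
        return pd.concat(frames, ignore_index=True)

    codes = encode(sequence)
    frames: list = []
    cols = ["contig", "start", "end", "unit", "unit_count", "length", "kind", "composition"]
    chars = np.array(list("ACGTN"))

    # homopolymers / short homopolymers via run-length encoding
    if codes.size:
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [codes.size]))
        bases = codes[starts]
        lengths = ends - starts
        keep = (bases < 4) & (lengths >= min_short_homopolymer)
        s, e, b, ln = starts[keep], ends[keep], bases[keep], lengths[keep]
        units = chars[b]
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig, "start": s, "end": e, "unit": units,
                    "unit_count": ln, "length": ln,
                    "kind": np.where(ln >= min_homopolymer, "homopolymer", "short_homopolymer"),
                    "composition": np.where((b == 0) | (b == 3), "AT", "CG"),
                }
            )
        )

    # microsatellites: tandem repeats of primitive units of length 2..max_unit
    for k in range(2, max_unit + 1):
        if codes.size <= k:
            break
        eq = (codes[:-k] == codes[k:]) & (codes[:-k] < 4) & (codes[k:] < 4)
        m_starts, m_ends = _runs_of(eq)
        totals = (m_ends - m_starts) + k
        keep = totals >= max(min_microsatellite_total, 2 * k)
        m_starts, totals = m_starts[keep], totals[keep]
        if m_starts.size == 0:
            continue
        unit_mat = codes[m_starts[:, None] + np.arange(k)[None, :]]
        # primitive units only: no divisor-period tiling
        prim = np.ones(m_starts.size, dtype=bool)
        for d in range(1, k):
            if k % d == 0:
                prim &= ~np.all(
                    unit_mat == np.tile(unit_mat[:, :d], k // d), axis=1
                )
        m_starts, totals, unit_mat = m_starts[prim], totals[prim], unit_mat[prim]
        bchars = np.frombuffer(b"ACGTN", dtype=np.uint8)
        units = (
            np.ascontiguousarray(bchars[unit_mat]).view(f"S{k}").ravel().astype(str)
        )
        frames.append(
            pd.DataFrame(
                {
                    "contig": contig, "start": m_starts, "end": m_starts + totals,
                    "unit": units, "unit_count": totals // k, "length": totals,
                    "kind": "microsatellite", "composition": None,
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=cols)
    df = pd.concat(frames, ignore_index=True)[cols]
    df = df.astype({"start": np.int64, "end": np.int64,
                    "unit_count": np.int64, "length": np.int64})
    return df.sort_values(["contig", "start", "end"]).reset_index(drop=True)


class RepeatIndex:
    """Positional index over a repeat-run table for fast context lookup.

    Overlapping runs of the same kind (possible for microsatellites with
    different periods) are flattened so that every base maps to exactly
    one run per kind; across kinds, lookups apply the documented
    precedence order.
    """

    def __init__(self, runs: pd.DataFrame):
        self.runs = runs.reset_index(drop=True)
        self._by_kind: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (ctg, kind), grp in self.runs.groupby(["contig", "kind"], sort=False):
            grp = grp.sort_values(["start", "end"])
            s = grp["start"].to_numpy(np.int64)
            e = grp["end"].to_numpy(np.int64)
            ids = grp.index.to_numpy(np.int64)
            prev_end = np.concatenate(([np.int64(-1)], np.maximum.accumulate(e)[:-1]))
            eff = np.maximum(s, prev_end)
            keep = eff < e
            self._by_kind[(ctg, kind)] = (eff[keep], e[keep], ids[keep])

    # -- lookup --------------------------------------------------------
    def lookup(self, contigs, positions) -> np.ndarray:
        """Run id containing each position (precedence applied), -1 if none."""
        contigs = np.asarray(contigs)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.size, -1, dtype=np.int64)
        for ctg in pd.unique(contigs):
            sel = np.flatnonzero(contigs == ctg)
            pos = positions[sel]
            res = np.full(pos.size, -1, dtype=np.int64)
            for kind in KIND_PRECEDENCE:
                key = (ctg, kind)
                if key not in self._by_kind:
                    continue
                starts, ends, ids = self._by_kind[key]
                unresolved = res < 0
                if not unresolved.any():
                    break
                idx = _intervals.point_lookup(starts, ends, pos[unresolved])
                hit = idx >= 0
                tmp = res[unresolved]
                tmp[hit] = ids[idx[hit]]
                res[unresolved] = tmp
            out[sel] = res
        return out

    # -- derived tables ------------------------------------------------
    def class_base_counts(self) -> Dict[str, int]:
        """Bases per context class, with precedence-disjoint accounting."""
        per_kind = {}
        for kind in KIND_PRECEDENCE:
            sub = self.runs[self.runs["kind"] == kind]
            per_kind[kind] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        hp = _intervals.merge(*per_kind["homopolymer"])
        ms = _intervals.merge(*per_kind["microsatellite"])
        shp = _intervals.merge(*per_kind["short_homopolymer"])
        hp_len = _intervals.total_length(*hp)
        ms_len = _intervals.total_length(*ms) - _intervals.intersection_length(*ms, *hp)
        hp_ms = _intervals.merge(
            np.concatenate([hp[0], ms[0]]), np.concatenate([hp[1], ms[1]])
        )
        shp_len = _intervals.total_length(*shp) - _intervals.intersection_length(*shp, *hp_ms)
        return {
            "homopolymer": hp_len,
            "microsatellite": ms_len,
            "short_homopolymer": shp_len,
        }

    def flanking_positions(self, kinds: Iterable[str] = ("homopolymer",)) -> pd.DataFrame:
        """The two bases immediately flanking each run of the given kinds."""
        sub = self.runs[self.runs["kind"].isin(list(kinds))]
        df = pd.DataFrame(
            {
                "contig": np.tile(sub["contig"].to_numpy(), 2),
                "pos": np.concatenate(
                    [sub["start"].to_numpy(np.int64) - 1, sub["end"].to_numpy(np.int64)]
                ),
                "run_id": np.tile(sub.index.to_numpy(np.int64), 2),
                "unit": np.tile(sub["unit"].to_numpy(), 2),
                "kind": np.tile(sub["kind"].to_numpy(), 2),
            }
        )
        df = df[df["pos"] >= 0]
        # a base flanked by two runs is one position; keep the first
        return df.drop_duplicates(subset=["contig", "pos"]).reset_index(drop=True)


# ----------------------------------------------------------------------
# variant classification
# ----------------------------------------------------------------------

def infer_variant_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "substitution"
    if len(ref) > len(alt):
        return "deletion"
    if len(alt) > len(ref):
        return "insertion"
    raise ValueError(f"unsupported allele pair {ref}>{alt}")


def _indel_matches_run(ref: str, alt: str, unit: str) -> bool:
    seq = ref[1:] if len(ref) > len(alt) else alt[1:]
    k = len(unit)
    if len(seq) == 0 or len(seq) % k != 0:
        return False
    # rotation-tolerant tiling check (left-normalization can rotate the unit)
    return seq in unit * (len(seq) // k + 2)


def classify_variant_context(
    variants: pd.DataFrame,
    repeat_index: RepeatIndex,
    genome: Genome | None = None,
) -> pd.DataFrame:
    """Attach ``context_class`` and ``run_id`` columns to a variant table.

    ``variants`` needs columns contig, pos (0-based; indels anchored on the
    base before the event), ref, alt.  For indels, ``run_id`` is the
    affected run (or -1 when the event is not a whole-unit change of any
    run); substitutions carry the run containing their position.
    """
    df = variants.copy()
    if "variant_class" not in df.columns:
        df["variant_class"] = [
            infer_variant_class(r, a) for r, a in zip(df["ref"], df["alt"])
        ]
    if genome is not None:
        for ctg, grp in df.groupby("contig"):
            if ctg not in genome:
                raise ValueError(f"unknown contig {ctg!r}")
            if (grp["pos"] < 0).any() or (grp["pos"] >= genome.length(ctg)).any():
                raise ValueError(f"variant position outside contig {ctg!r}")

    is_sub = (df["variant_class"] == "substitution").to_numpy()
    query = df["pos"].to_numpy(dtype=np.int64).copy()
    query[~is_sub] += 1  # first base touched by a left-normalized indel

    run_id = repeat_index.lookup(df["contig"].to_numpy(), query)
    kinds = repeat_index.runs["kind"]
    units = repeat_index.runs["unit"]

    context = np.full(len(df), "non_repeat", dtype=object)
    hit = run_id >= 0
    context[hit] = kinds.to_numpy()[run_id[hit]]

    # indels must be a whole number of units to *affect* the run
    affected = run_id.copy()
    idx_indel = np.flatnonzero(hit & ~is_sub)
    refs = df["ref"].to_numpy()
    alts = df["alt"].to_numpy()
    for i in idx_indel:
        if not _indel_matches_run(refs[i], alts[i], units.iat[run_id[i]]):
            affected[i] = -1
    affected[is_sub] = -1

    df["context_class"] = context
    df["run_id"] = affected
    df["position_run_id"] = run_id
    return df


def assign_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``region`` column from a partitioning region annotation."""
    df = variants.copy()
    out = np.full(len(df), None, dtype=object)
    for ctg, grp in regions.groupby("contig"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        labels = grp["region"].to_numpy()
        sel = np.flatnonzero((df["contig"] == ctg).to_numpy())
        idx = _intervals.point_lookup(starts, ends, df["pos"].to_numpy()[sel])
        if (idx < 0).any():
            missing = df["pos"].to_numpy()[sel][idx < 0][:3]
            raise ValueError(
                f"positions not covered by region annotation on {ctg}: {missing.tolist()}"
            )
        out[sel] = labels[idx]
    if any(v is None for v in out):
        bad = df.loc[[v is None for v in out], "contig"].unique()
        raise ValueError(f"contigs missing from region annotation: {bad.tolist()}")
    df["region"] = out
    return df


# ----------------------------------------------------------------------
# enrichment / frequency statistics
# ----------------------------------------------------------------------

def context_enrichment(
    variants: pd.DataFrame,
    repeat_index: RepeatIndex,
    callable_length: int,
) -> pd.DataFrame:
    """Observed vs expected context fractions, separately for substitutions and indels.

    Expected fraction of a class is its share of callable bases; the fold
    is observed/expected.  Returns a tidy frame indexed by
    (variant_type, context_class).
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    if len(variants) == 0:
        raise ValueError("no variants supplied")
    base_counts = repeat_index.class_base_counts()
    repeat_total = sum(base_counts.values())
    if repeat_total > callable_length:
        raise ValueError("callable_length smaller than total repeat bases")
    base_counts["non_repeat"] = callable_length - repeat_total

    df = variants.copy()
    df["variant_type"] = np.where(
        df["variant_class"] == "substitution", "substitution", "indel"
    )
    rows = []
    for vtype, grp in df.groupby("variant_type"):
        n = len(grp)
        obs = grp["context_class"].value_counts()
        for cls in CONTEXT_CLASSES:
            o = int(obs.get(cls, 0))
            exp_frac = base_counts[cls] / callable_length
            obs_frac = o / n
            fold = obs_frac / exp_frac if exp_frac > 0 else np.nan
            rows.append((vtype, cls, o, obs_frac, exp_frac, fold))
    return pd.DataFrame(
        rows,
        columns=[
            "variant_type", "context_class", "observed_n",
            "observed_fraction", "expected_fraction", "fold",
        ],
    )


def region_lengths(regions: pd.DataFrame) -> pd.Series:
    return (regions["end"] - regions["start"]).groupby(regions["region"]).sum()


def region_mutation_frequency(
    variants: pd.DataFrame,
    regions: pd.DataFrame,
    callable_per_region: pd.Series | None = None,
) -> pd.DataFrame:
    """Mutations per base (mpb) per region, per sample plus the cohort mean.

    Substitutions and indels are reported separately.  ``callable_per_region``
    defaults to the annotated region lengths.
    """
    lengths = (
        callable_per_region
        if callable_per_region is not None
        else region_lengths(regions)
    )
    if (lengths <= 0).any():
        zero = lengths[lengths <= 0].index.tolist()
        raise ValueError(f"regions with nonpositive callable length: {zero}")
    df = variants if "region" in variants.columns else assign_regions(variants, regions)
    df = df.copy()
    df["variant_type"] = np.where(
        df["variant_class"] == "substitution", "substitution", "indel"
    )
    counts = (
        df.groupby(["variant_type", "region", "sample"]).size().rename("count").reset_index()
    )
    counts["bases"] = counts["region"].map(lengths).astype(float)
    if counts["bases"].isna().any():
        raise ValueError("variant region missing from region length table")
    counts["frequency"] = counts["count"] / counts["bases"]

    cohort = (
        counts.groupby(["variant_type", "region"])
        .agg(count=("count", "sum"), frequency=("frequency", "mean"))
        .reset_index()
        .assign(sample="cohort_mean")
    )
    cohort["bases"] = cohort["region"].map(lengths).astype(float)
    return pd.concat([counts, cohort[counts.columns]], ignore_index=True)
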