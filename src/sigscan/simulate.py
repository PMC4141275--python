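"""Synthetic tumor-cohort generator with MMR-deficiency mutation structure.

Generates a reference sequence with planted homopolymers, microsatellites
and CpG islands, a partitioning region annotation, per-window covariate
tracks, per-sample somatic mutation sets and marker-genotype cohorts with
known MMR status — everything the downstream analyses consume, so the
whole pipeline is testable without any external data.

The generator's defaults encode the hypermutator phenotype the analyses
characterize: MMR-deficient samples carry a 50-fold mutation burden,
74% of substitutions are transitions, 81% of indels are deletions,
indels are enriched 40-fold in homopolymers and 2.3-fold in
microsatellites (substitutions 3- and 1.5-fold), substitution rates are
tripled at bases immediately flanking homopolymers (1.3x next to
microsatellites) with slippage converting the flanking base to the
repeat base, CpG islands mutate at half the outside rate, and exonic
indels are retained at 9% (91% depletion).  Placement weights are
normalized so each configured fold is the *expectation* of the
corresponding downstream estimator.

Every stage draws from child streams of a single seed via a fixed
spawn-key rule (reference = (seed, 0), mutations sample i = (seed, 1, i),
marker cohort = (seed, 2)), so cohorts of any size are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np
import pandas as pd

from .genome import Genome, decode
from .repeats import RepeatIndex, scan_repeats
from .selection import assign_run_locations

PAPER_REGION_PROPORTIONS = {
    "exonic": 0.0112,
    "intronic": 0.3401,
    "3'UTR": 0.0078,
    "5'UTR": 0.0014,
    "ncRNA": 0.0281,
    "upstream": 0.0058,
    "downstream": 0.0058,
    "intergenic": 0.5998,
}

BASES = "ACGT"
_TS_ALT = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
_TV_ALTS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}
_TRANSITION_CODE = np.zeros((5, 5), dtype=bool)
for _a, _b in _TS_ALT.items():
    _TRANSITION_CODE[_a, _b] = True


def _default_sub_enrichments():
    return {"homopolymer": 3.0, "microsatellite": 1.5, "short_homopolymer": 1.0}


def _default_indel_enrichments():
    return {"homopolymer": 40.0, "microsatellite": 2.3, "short_homopolymer": 1.0}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort (defaults as documented above)."""

    genome_length: int = 10_000_000
    contig: str = "chr1"
    region_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(PAPER_REGION_PROPORTIONS)
    )
    region_block_size: int = 5_000
    homopolymers_per_mb: float = 1200.0
    homopolymer_length_geom_p: float = 0.5
    exonic_homopolymer_length_geom_p: float | None = None
    cg_homopolymer_fraction: float = 0.07
    microsatellites_per_mb: float = 100.0
    cpg_island_fraction: float = 0.02
    cpg_island_mean_length: int = 1_000
    n_tumors_deficient: int = 3
    n_tumors_proficient: int = 2
    proficient_mutations_per_mb: float = 66.0
    burden_ratio: float = 50.0
    indel_fraction: float = 0.8
    transition_fraction: float = 0.74
    deletion_fraction: float = 0.81
    substitution_context_enrichments: Dict[str, float] = field(
        default_factory=_default_sub_enrichments
    )
    indel_context_enrichments: Dict[str, float] = field(
        default_factory=_default_indel_enrichments
    )
    flanking_slippage_fold: float = 3.0
    flanking_slippage_fold_microsatellite: float = 1.3
    cpg_island_rate_ratio: float = 0.5
    exonic_indel_retention: float = 0.09
    cg_homopolymer_indel_relative_rate: float = 0.25
    replication_time_gradient: float = 0.5
    indel_length_exponent: float = 1.5
    window_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        total = sum(self.region_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region proportions sum to {total}, not 1")
        for name in (
            "transition_fraction", "deletion_fraction", "cpg_island_rate_ratio",
            "exonic_indel_retention", "indel_fraction", "cg_homopolymer_fraction",
            "cpg_island_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("burden_ratio", "flanking_slippage_fold",
                     "flanking_slippage_fold_microsatellite"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for d in (self.substitution_context_enrichments, self.indel_context_enrichments):
            if any(v <= 0 for v in d.values()):
                raise ValueError("context enrichments must be positive")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticReference:
    genome: Genome
    regions: pd.DataFrame
    cpg_islands: pd.DataFrame
    tracks: Dict[str, pd.DataFrame]
    runs: pd.DataFrame              # scanned runs with a location column
    repeat_index: RepeatIndex
    config: SimulationConfig


@dataclass
class SyntheticTruth:
    sample_status: pd.DataFrame     # sample, status, expected_mutations
    config: SimulationConfig
    process_counts: pd.DataFrame    # process x count over emitted variants


def _rng(seed, *key):
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def _break_natural_runs(seq: np.ndarray, rng, max_rounds: int = 6) -> None:
    """Destroy chance homopolymers (>= 6 bases) in a background, in place.

    Planted homopolymers are the generator's ground truth for run-length
    dependent processes, so mononucleotide runs arising by chance are
    broken by replacing a middle base with one differing from both
    neighbours.  Chance tandem repeats of longer units are left alone:
    they are intrinsic to random sequence (any 2x4 bp period qualifies as
    a microsatellite) and are treated as genuine loci.
    """
    from .repeats import homopolymer_runs

    for _ in range(max_rounds):
        starts, ends, _bases = homopolymer_runs(seq, min_length=6)
        if starts.size == 0:
            return
        for s, e in zip(starts, ends):
            mid = (s + e) // 2
            forbidden = {int(seq[mid])}
            if mid > 0:
                forbidden.add(int(seq[mid - 1]))
            if mid + 1 < seq.size:
                forbidden.add(int(seq[mid + 1]))
            choices = [b for b in range(4) if b not in forbidden]
            seq[mid] = choices[int(rng.integers(len(choices)))] if choices else seq[mid]
    raise RuntimeError("failed to sterilize background sequence of chance repeats")


# ----------------------------------------------------------------------
# reference
# ----------------------------------------------------------------------

def generate_reference(config: SimulationConfig) -> SyntheticReference:
    """Reference sequence + region annotation + covariate tracks.

    Regions are equal-size blocks with label counts proportional to the
    configured fractions (largest-remainder rounding), shuffled along the
    genome.  Homopolymers and microsatellites are planted at the
    configured densities on a random background; CpG islands are CG-rich
    rewritten intervals.  Deterministic under a fixed seed.
    """
    L = config.genome_length
    rng = _rng(config.seed, 0)

    # -- region blocks ----------------------------------------------------
    n_blocks = L // config.region_block_size
    if n_blocks < len(config.region_proportions):
        raise ValueError("genome too short for the configured region block size")
    labels = list(config.region_proportions)
    quotas = np.array([config.region_proportions[x] * n_blocks for x in labels])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    for i in np.argsort(rem)[::-1][: n_blocks - counts.sum()]:
        counts[i] += 1
    block_labels = np.repeat(np.arange(len(labels)), counts)
    rng.shuffle(block_labels)
    block_starts = np.arange(n_blocks, dtype=np.int64) * config.region_block_size
    block_ends = block_starts + config.region_block_size
    block_ends[-1] = L  # absorb the remainder into the last block

    regions = pd.DataFrame(
        {
            "contig": config.contig,
            "start": block_starts,
            "end": block_ends,
            "region": [labels[i] for i in block_labels],
        }
    )
    # merge adjacent blocks with the same label
    same = regions["region"].ne(regions["region"].shift()).cumsum()
    regions = (
        regions.groupby(same)
        .agg(contig=("contig", "first"), start=("start", "min"),
             end=("end", "max"), region=("region", "first"))
        .reset_index(drop=True)
    )

    # -- background sequence ---------------------------------------------
    seq = rng.integers(0, 4, size=L, dtype=np.uint8)

    # -- CpG islands (CG-rich rewrites) -----------------------------------
    n_isl = int(round(L * config.cpg_island_fraction / config.cpg_island_mean_length))
    isl_rows = []
    if n_isl > 0:
        isl_starts = np.sort(rng.integers(0, L - 2 * config.cpg_island_mean_length, n_isl))
        prev_end = 0
        for s in isl_starts:
            ln = max(200, int(rng.exponential(config.cpg_island_mean_length)))
            s = max(int(s), prev_end + 1)
            e = min(s + ln, L)
            if e <= s:
                continue
            block = rng.choice(
                np.array([0, 1, 2, 3], np.uint8), size=e - s,
                p=[0.15, 0.35, 0.35, 0.15],
            )
            seq[s:e] = block
            isl_rows.append((config.contig, s, e))
            prev_end = e
    cpg_islands = pd.DataFrame(isl_rows, columns=["contig", "start", "end"])

    # chance runs in the background/islands would dilute the configured
    # repeat densities; remove them so planted repeats are the truth
    _break_natural_runs(seq, rng)

    # -- plant repeats -----------------------------------------------------
    n_hp = int(round(config.homopolymers_per_mb * L / 1e6))
    n_ms = int(round(config.microsatellites_per_mb * L / 1e6))
    block_label_of = np.repeat(block_labels, np.diff(np.append(block_starts, L)))
    exonic_idx = labels.index("exonic") if "exonic" in labels else -1

    n_el = n_hp + n_ms
    placed_hp = placed_ms = 0
    if n_el > 0:
        cand = np.sort(rng.integers(1, L - 64, size=int(n_el * 2.5)))
        is_hp = np.zeros(cand.size, dtype=bool)
        is_hp[: int(round(cand.size * n_hp / n_el))] = True
        rng.shuffle(is_hp)
        prev_end = 0
        for start, hp in zip(cand, is_hp):
            if start < prev_end + 2:
                continue
            if hp:
                if placed_hp >= n_hp:
                    continue
                p = config.homopolymer_length_geom_p
                if (
                    config.exonic_homopolymer_length_geom_p is not None
                    and exonic_idx >= 0
                    and block_label_of[start] == exonic_idx
                ):
                    p = config.exonic_homopolymer_length_geom_p
                ln = 5 + int(rng.geometric(p))
                if rng.random() < config.cg_homopolymer_fraction:
                    base = rng.choice([1, 2])
                else:
                    base = rng.choice([0, 3])
                seq[start : start + ln] = base
                # keep the run maximal as planted
                if seq[start - 1] == base:
                    seq[start - 1] = (base + 1) % 4
                if start + ln < L and seq[start + ln] == base:
                    seq[start + ln] = (base + 1) % 4
                prev_end = start + ln
                placed_hp += 1
            else:
                if placed_ms >= n_ms:
                    continue
                k = rng.choice([2, 3, 4, 5, 6], p=[0.4, 0.25, 0.15, 0.12, 0.08])
                while True:
                    unit = rng.integers(0, 4, size=k, dtype=np.uint8)
                    if len(set(unit.tolist())) > 1:
                        break
                reps = max(2, int(np.ceil(6 / k))) + int(rng.geometric(0.5)) - 1
                total = k * reps
                tile = np.tile(unit, reps)
                seq[start : start + total] = tile
                prev_end = start + total
                placed_ms += 1
            if placed_hp >= n_hp and placed_ms >= n_ms:
                break
        if placed_hp < 0.9 * n_hp or placed_ms < 0.9 * n_ms:
            raise ValueError(
                "genome too short to host the requested repeat density "
                f"(placed {placed_hp}/{n_hp} homopolymers, {placed_ms}/{n_ms} microsatellites)"
            )

    genome = Genome({config.contig: seq})

    # -- covariate tracks ---------------------------------------------------
    W = config.window_size
    n_win = int(np.ceil(L / W))
    w_start = np.arange(n_win, dtype=np.int64) * W
    w_end = np.minimum(w_start + W, L)
    mid = (w_start + w_end) / 2
    replication = 0.5 + 0.5 * np.sin(2 * np.pi * 3 * mid / L)
    walk = np.cumsum(rng.normal(size=n_win))
    dnase = (walk - walk.min()) / max(float(np.ptp(walk)), 1e-12)
    walk2 = np.cumsum(rng.normal(size=n_win))
    lamina = (walk2 - walk2.min()) / max(float(np.ptp(walk2)), 1e-12)
    tracks = {
        name: pd.DataFrame(
            {"contig": config.contig, "start": w_start, "end": w_end, "value": vals}
        )
        for name, vals in (
            ("replication_time", replication),
            ("dnase", dnase),
            ("lamina", lamina),
        )
    }

    runs = scan_repeats(genome)
    runs = assign_run_locations(runs, regions)
    return SyntheticReference(
        genome=genome,
        regions=regions,
        cpg_islands=cpg_islands,
        tracks=tracks,
        runs=runs,
        repeat_index=RepeatIndex(runs),
        config=config,
    )


# ----------------------------------------------------------------------
# somatic mutations
# ----------------------------------------------------------------------

def _class_weights(enrichments, base_counts, callable_length):
    """Per-class placement mass W_c with the non-repeat class absorbing the
    normalization, so observed/expected folds equal the configured values."""
    W = {c: enrichments[c] * base_counts[c] for c in enrichments}
    b_non = callable_length - sum(base_counts.values())
    w_non = callable_length - sum(W.values())
    if w_non <= 0 or b_non <= 0:
        raise ValueError(
            "repeat enrichments leave no mass for non-repeat placement; "
            "genome too repeat-dense for the configured folds"
        )
    W["non_repeat"] = w_non
    return W


def _sample_names(config):
    deficient = [f"MMRd_{i+1:02d}" for i in range(config.n_tumors_deficient)]
    proficient = [f"MMRp_{i+1:02d}" for i in range(config.n_tumors_proficient)]
    return deficient, proficient


def generate_tumor_mutations(
    reference: SyntheticReference,
    config: SimulationConfig | None = None,
):
    """Per-sample somatic variant sets with known generating processes.

    Returns ``(variants, truth)``: a variant table (contig, pos, ref,
    alt, sample, variant_class, process) with left-normalized indels
    anchored one base before the run, and a :class:`SyntheticTruth`.
    Indel hits are Poisson per (locus, sample) so per-sample hit rates
    are exactly the configured placement weights; repeated hits are kept
    as separate events.
    """
    cfg = config or reference.config
    genome = reference.genome
    seq = genome.codes(cfg.contig)
    L = genome.length(cfg.contig)
    callable_length = genome.callable_length()
    runs = reference.runs
    index = reference.repeat_index

    deficient, proficient = _sample_names(cfg)
    all_samples = deficient + proficient
    if not all_samples:
        raise ValueError("cohort must contain at least one tumor")

    base_counts = index.class_base_counts()
    for cls, n in base_counts.items():
        if n == 0 and (
            cfg.indel_context_enrichments.get(cls, 1.0) != 1.0
            or cfg.substitution_context_enrichments.get(cls, 1.0) != 1.0
        ):
            raise ValueError(f"no callable bases in required context class {cls!r}")

    # --- run-level indel weights ---------------------------------------
    kind = runs["kind"].to_numpy()
    length = runs["length"].to_numpy()
    location = runs["location"].to_numpy()
    comp = runs["composition"].to_numpy()
    start_arr = runs["start"].to_numpy()
    end_arr = runs["end"].to_numpy()
    unit_arr = runs["unit"].to_numpy()

    g_len = np.maximum(np.minimum(length, 20) - 5, 1) ** cfg.indel_length_exponent
    region_mult = np.where(location == "exonic", cfg.exonic_indel_retention, 1.0)
    comp_mult = np.where(
        (kind == "homopolymer") & (comp == "CG"),
        cfg.cg_homopolymer_indel_relative_rate,
        1.0,
    )
    run_w = np.where(kind == "short_homopolymer", 1.0, g_len) * region_mult * comp_mult
    run_w[start_arr < 1] = 0.0  # need a left anchor base
    # placement must round-trip through context classification: a run whose
    # start falls inside a higher-precedence overlapping run would have its
    # indels classified as that other class, so it gets no placement mass
    eff = index.lookup(np.full(len(runs), cfg.contig, dtype=object), start_arr)
    eff_kind = np.where(eff >= 0, kind[np.clip(eff, 0, None)], "none")
    run_w[eff_kind != kind] = 0.0

    W_indel = _class_weights(cfg.indel_context_enrichments, base_counts, callable_length)
    class_run_w = {}
    for cls in cfg.indel_context_enrichments:
        sel = kind == cls
        tot = run_w[sel].sum()
        if tot > 0:
            class_run_w[cls] = (np.flatnonzero(sel), run_w[sel] / tot)

    # region blocks for non-repeat indel placement (exonic thinning)
    reg = reference.regions
    blk_starts = reg["start"].to_numpy(np.int64)
    blk_ends = reg["end"].to_numpy(np.int64)
    blk_mult = np.where(reg["region"].to_numpy() == "exonic", cfg.exonic_indel_retention, 1.0)
    blk_w = (blk_ends - blk_starts) * blk_mult
    blk_p = blk_w / blk_w.sum()

    # --- per-base substitution weights (built lazily) -------------------
    sub_weights = None

    def _build_sub_weights():
        W_sub = _class_weights(
            cfg.substitution_context_enrichments, base_counts, callable_length
        )
        b_non = callable_length - sum(base_counts.values())
        w = np.full(L, W_sub["non_repeat"] / b_non, dtype=np.float64)
        for cls in ("short_homopolymer", "microsatellite", "homopolymer"):
            sel = kind == cls
            f = W_sub[cls] / base_counts[cls] if base_counts[cls] else 0.0
            for s, e in zip(start_arr[sel], end_arr[sel]):
                w[s:e] = f
        mean_w = w.sum() / callable_length
        flanks = index.flanking_positions(kinds=("homopolymer", "microsatellite"))
        f_pos = flanks["pos"].to_numpy(np.int64)
        f_kind = flanks["kind"].to_numpy()
        ok = f_pos < L
        f_pos, f_kind = f_pos[ok], f_kind[ok]
        fold = np.where(
            f_kind == "homopolymer",
            cfg.flanking_slippage_fold,
            cfg.flanking_slippage_fold_microsatellite,
        )
        w[f_pos] = fold * mean_w
        # island dampening applies to every base, flanks included, so the
        # measured flanking fold (relative to the genome-wide mean) is exact
        for _, row in reference.cpg_islands.iterrows():
            w[row["start"] : row["end"]] *= cfg.cpg_island_rate_ratio
        w[seq >= 4] = 0.0
        # slippage conversion target: the repeat base adjacent to the flank
        right = (
            index.lookup(
                np.full(f_pos.size, cfg.contig, dtype=object),
                np.clip(f_pos + 1, 0, L - 1),
            )
            >= 0
        ) & (f_pos + 1 < L)
        conv_base = np.where(
            right, seq[np.clip(f_pos + 1, 0, L - 1)], seq[np.clip(f_pos - 1, 0, None)]
        )
        conv = {
            int(p): (int(b), float(f))
            for p, b, f in zip(f_pos, conv_base, fold)
            if b < 4
        }
        # repeat-templated conversions replace the drawn alt, so the
        # background transition probability is compensated analytically to
        # keep the cohort-wide transition fraction at its configured value
        convertible = (conv_base != seq[f_pos]) & (conv_base < 4) & (seq[f_pos] < 4)
        w_total = w.sum()
        excess = w[f_pos] * (fold - 1.0) / fold * convertible
        f_slip = float(excess.sum() / w_total) if w_total > 0 else 0.0
        conv_ts = _TRANSITION_CODE[seq[f_pos], conv_base] & convertible
        p_conv_ts = (
            float(excess[conv_ts].sum() / excess.sum()) if excess.sum() > 0 else 0.0
        )
        q_background = cfg.transition_fraction
        if f_slip < 1.0:
            q_background = np.clip(
                (cfg.transition_fraction - f_slip * p_conv_ts) / (1.0 - f_slip), 0.0, 1.0
            )
        # replication gradient multiplier for transitions
        track = reference.tracks["replication_time"]
        per_win = track["value"].to_numpy()
        rep_base = np.repeat(per_win, np.diff(np.append(track["start"].to_numpy(), L)))
        w_ts = w * (1.0 + cfg.replication_time_gradient * rep_base)
        return {
            "tv": np.cumsum(w),
            "ts": np.cumsum(w_ts),
            "conv": conv,
            "q_background": float(q_background),
        }

    frames = []
    base_rate = cfg.proficient_mutations_per_mb * L / 1e6
    for i, sample in enumerate(all_samples):
        rng = _rng(cfg.seed, 1, i)
        status = "deficient" if sample in deficient else "proficient"
        lam = base_rate * (cfg.burden_ratio if status == "deficient" else 1.0)
        n_mut = rng.poisson(lam)
        n_indel = rng.binomial(n_mut, cfg.indel_fraction)
        n_sub = n_mut - n_indel

        rows = []

        # ---- indels -----------------------------------------------------
        cls_names = list(W_indel)
        cls_p = np.array([W_indel[c] for c in cls_names])
        cls_p = cls_p / cls_p.sum()
        n_per_cls = rng.multinomial(n_indel, cls_p)
        for cls, n_cls in zip(cls_names, n_per_cls):
            if n_cls == 0:
                continue
            if cls == "non_repeat":
                placed = 0
                attempts = 0
                while placed < n_cls and attempts < 20:
                    attempts += 1
                    todo = n_cls - placed
                    blocks = rng.choice(len(blk_p), size=todo, p=blk_p)
                    offs = rng.random(todo)
                    pos = (
                        blk_starts[blocks]
                        + (offs * (blk_ends[blocks] - blk_starts[blocks])).astype(np.int64)
                    )
                    pos = pos[(pos >= 1) & (pos < L - 4)]
                    in_run = index.lookup(
                        np.full(pos.size, cfg.contig, dtype=object), pos + 1
                    ) >= 0
                    pos = pos[~in_run]
                    for p in pos[: n_cls - placed]:
                        dl = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
                        if rng.random() < cfg.deletion_fraction:
                            span = seq[p : p + 1 + dl]
                            if (span >= 4).any():
                                continue
                            ref = decode(span)
                            alt = ref[0]
                        else:
                            if seq[p] >= 4:
                                continue
                            ins = decode(rng.integers(0, 4, size=dl, dtype=np.uint8))
                            ref = decode(seq[p : p + 1])
                            alt = ref + ins
                        rows.append((int(p), ref, alt, "background_indel"))
                        placed += 1
            else:
                ids, p_run = class_run_w.get(cls, (None, None))
                if ids is None:
                    raise ValueError(f"no callable bases in required region class {cls!r}")
                hit_counts = rng.poisson(p_run * n_cls)
                for ridx, h in zip(ids[hit_counts > 0], hit_counts[hit_counts > 0]):
                    s = int(start_arr[ridx])
                    unit = unit_arr[ridx]
                    k = len(unit)
                    run_len = int(length[ridx])
                    anchor = s - 1
                    ref_anchor = decode(seq[anchor : anchor + 1])
                    for _ in range(int(h)):
                        units = 1 if rng.random() < 0.85 else 2
                        if rng.random() < cfg.deletion_fraction:
                            units = min(units, max(run_len // k, 1))
                            removed = decode(seq[s : s + units * k])
                            rows.append(
                                (anchor, ref_anchor + removed, ref_anchor, "slippage_indel")
                            )
                        else:
                            ins = decode(seq[s : s + k]) * units
                            rows.append(
                                (anchor, ref_anchor, ref_anchor + ins, "slippage_indel")
                            )

        # ---- substitutions ---------------------------------------------
        if n_sub > 0:
            if sub_weights is None:
                sub_weights = _build_sub_weights()
            n_ts = rng.binomial(n_sub, sub_weights["q_background"])
            for kind_lbl, n_k, cum in (
                ("ts", n_ts, sub_weights["ts"]),
                ("tv", n_sub - n_ts, sub_weights["tv"]),
            ):
                if n_k == 0:
                    continue
                u = rng.random(n_k) * cum[-1]
                pos = np.searchsorted(cum, u)
                refs = seq[pos]
                conv_map = sub_weights["conv"]
                for p, r in zip(pos, refs):
                    p, r = int(p), int(r)
                    hit = conv_map.get(p)
                    if hit is not None:
                        conv, fold = hit
                        if conv != r and fold > 1 and rng.random() < (fold - 1.0) / fold:
                            rows.append(
                                (p, BASES[r], BASES[conv], "slippage_substitution")
                            )
                            continue
                    if kind_lbl == "ts":
                        alt = _TS_ALT[r]
                    else:
                        alt = int(rng.choice(_TV_ALTS[r]))
                    rows.append((p, BASES[r], BASES[alt], "background_substitution"))

        df = pd.DataFrame(rows, columns=["pos", "ref", "alt", "process"])
        df["sample"] = sample
        frames.append(df)

    variants = pd.concat(frames, ignore_index=True)
    variants["contig"] = cfg.contig
    vc = []
    for r, a in zip(variants["ref"], variants["alt"]):
        if len(r) == len(a):
            vc.append("substitution")
        elif len(r) > len(a):
            vc.append("deletion")
        else:
            vc.append("insertion")
    variants["variant_class"] = vc
    variants = variants[
        ["contig", "pos", "ref", "alt", "sample", "variant_class", "process"]
    ].sort_values(["sample", "pos"], kind="stable").reset_index(drop=True)

    status_df = pd.DataFrame(
        {
            "sample": all_samples,
            "status": ["deficient"] * len(deficient) + ["proficient"] * len(proficient),
            "expected_mutations": [base_rate * cfg.burden_ratio] * len(deficient)
            + [base_rate] * len(proficient),
        }
    )
    proc_counts = variants["process"].value_counts().rename_axis("process").reset_index(name="count")
    truth = SyntheticTruth(status_df, cfg, proc_counts)
    return variants, truth


def generate_cohort(config: SimulationConfig):
    """Convenience wrapper: reference plus mutations in one call."""
    ref = generate_reference(config)
    variants, truth = generate_tumor_mutations(ref, config)
    return ref, variants, truth


# ----------------------------------------------------------------------
# stratum-level homopolymer cohorts
# ----------------------------------------------------------------------

DEFAULT_LOCATION_SHARES = {
    "exonic": 0.10,
    "5'UTR": 0.10,
    "3'UTR": 0.10,
    "intronic": 0.30,
    "intergenic": 0.40,
}


def generate_stratum_cohort(
    n_runs: int = 200_000,
    n_indels: int = 100_000,
    m_samples: int = 16,
    location_shares: Dict[str, float] | None = None,
    cg_fraction: float = 0.07,
    length_geom_p: float = 0.5,
    location_length_geom_p: Dict[str, float] | None = None,
    location_rate_multipliers: Dict[str, float] | None = None,
    length_exponent: float = 1.5,
    seed: int = 0,
):
    """Direct homopolymer-strata cohort: runs plus per-sample indel hits.

    Bypasses sequence simulation: homopolymer loci are drawn with a
    location, a composition and a length (optionally location-specific
    length mixtures), and indel hits are Poisson per (locus, sample)
    with rate proportional to a length effect (length - 5)^a times an
    optional per-location multiplier.  Useful for calibrating the
    correction cascade: with all multipliers equal the cascade's final
    per-location frequencies are 1 regardless of the location mixtures.

    Returns ``(runs, indels)`` directly consumable by
    :func:`sigscan.selection.corrected_region_indel_frequency`.
    """
    shares = location_shares or dict(DEFAULT_LOCATION_SHARES)
    if abs(sum(shares.values()) - 1) > 1e-9:
        raise ValueError("location shares must sum to 1")
    mult = location_rate_multipliers or {}
    rng = _rng(seed, 4)

    locs = list(shares)
    loc = rng.choice(len(locs), size=n_runs, p=[shares[x] for x in locs])
    comp = np.where(rng.random(n_runs) < cg_fraction, "CG", "AT")
    p_len = np.array(
        [
            (location_length_geom_p or {}).get(locs[i], length_geom_p)
            for i in range(len(locs))
        ]
    )[loc]
    lengths = 5 + rng.geometric(p_len)
    location = np.array(locs, dtype=object)[loc]

    runs = pd.DataFrame(
        {
            "contig": "chr1",
            "start": np.arange(n_runs, dtype=np.int64) * 50,
            "end": np.arange(n_runs, dtype=np.int64) * 50 + lengths,
            "unit": np.where(comp == "AT", "A", "C"),
            "unit_count": lengths,
            "length": lengths,
            "kind": "homopolymer",
            "composition": comp,
            "location": location,
        }
    )

    g = np.maximum(np.minimum(lengths, 20) - 5, 1) ** length_exponent
    w = g * np.array([mult.get(t, 1.0) for t in location])
    lam = n_indels * w / w.sum() / m_samples
    rows = []
    for s in range(m_samples):
        counts = rng.poisson(lam)
        nz = np.flatnonzero(counts)
        rows.append(
            pd.DataFrame(
                {
                    "run_id": np.repeat(nz, counts[nz]),
                    "sample": f"S{s+1:02d}",
                }
            )
        )
    indels = pd.concat(rows, ignore_index=True)
    indels["variant_class"] = "deletion"
    return runs, indels


# ----------------------------------------------------------------------
# marker cohorts
# ----------------------------------------------------------------------

def generate_marker_cohort(
    n_deficient: int,
    n_proficient: int,
    deficient_rates,
    proficient_rates,
    missing_rate: float = 0.0,
    seed: int = 0,
):
    """Samples x markers genotype matrix with known MMR status.

    Genotypes are 1 (positive), 0 (negative) or NaN (missing); deficient
    samples draw marker positivity from ``deficient_rates``, proficient
    samples from ``proficient_rates``.  Returns ``(matrix, truth)`` with
    truth True for deficient samples.
    """
    d = np.asarray(deficient_rates, dtype=float)
    p = np.asarray(proficient_rates, dtype=float)
    if d.shape != p.shape:
        raise ValueError("rate vectors have unequal length")
    if d.size == 0:
        raise ValueError("at least one marker required")
    for arr, name in ((d, "deficient"), (p, "proficient")):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} rates must be in [0, 1]")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")

    rng = _rng(seed, 2)
    n = n_deficient + n_proficient
    rates = np.vstack([np.tile(d, (n_deficient, 1)), np.tile(p, (n_proficient, 1))])
    geno = (rng.random((n, d.size)) < rates).astype(float)
    if missing_rate > 0:
        geno[rng.random((n, d.size)) < missing_rate] = np.nan
    samples = [f"D{i+1:03d}" for i in range(n_deficient)] + [
        f"P{i+1:03d}" for i in range(n_proficient)
    ]
    markers = [f"M{j+1:02d}" for j in range(d.size)]
    matrix = pd.DataFrame(geno, index=samples, columns=markers)
    truth = pd.Series([True] * n_deficient + [False] * n_proficient, index=samples)
    return matrix, truth


def default_marker_rates(n_markers: int = 59, deficient_mean: float = 0.35,
                         proficient_mean: float = 0.005, seed: int = 0):
    """Per-marker positivity rates emulating a recurrent-indel panel:
    deficient tumors average well above the 3-marker calling threshold,
    proficient tumors well below it."""
    rng = _rng(seed, 3)
    d = np.clip(rng.normal(deficient_mean, 0.08, n_markers), 0.05, 0.9)
    p = np.clip(rng.normal(proficient_mean, 0.003, n_markers), 0.0, 0.05)
    return d, p
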