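# Methods

## Repeat definitions and context classification

A homopolymer is a maximal mononucleotide run of at least six bases; a
run of 3–5 bases is a *short homopolymer*; a microsatellite is a maximal
tandem repeat of a primitive 2–6 bp unit with total length ≥6 bp and at
least two units. N breaks runs, and a mononucleotide run is never also
reported as a microsatellite of a doubled unit (units must not be a
repetition of a shorter word). Maximality is per period: a
microsatellite span may legitimately overlap a homopolymer (a poly-A
tract extends any period-k match across it), so classification applies a
fixed precedence — homopolymer > microsatellite > short homopolymer >
non-repeat — and base-count denominators use the same precedence so the
classes partition the callable genome.

An indel *affects* a run when its inserted/deleted sequence is a whole
number of that run's units (rotation-tolerant, since left-normalization
can rotate the unit) and its first changed base falls inside the run;
left-normalized repeat indels are anchored one base before the run
start. An indel inside a run that is not a whole-unit change keeps the
positional context but no affected-run link. Coordinates are 0-based
half-open everywhere except the VCF/BED boundary.

## Spectra

The dinucleotide spectrum indexes substitution counts by (mutated base,
following base on the reference strand, new base) — 48 categories with
no reverse-complement collapsing, carrying both a per-million-dinucleotide
rate (count / genome abundance of the dinucleotide × 1e6) and a
per-million-substitution composition. Substitutions at a contig end or
followed by N go to an explicit boundary bucket. Spectrum similarity is
the squared Pearson correlation over the 48 entries; the composition
normalization is the default, but because the two cohorts being compared
usually share a genome, the abundance-normalized rates give a sharper
contrast between mutational processes and can be selected via
`normalization="per_million_dinucleotides"`. Note R² cannot distinguish
an identical from an inverted contrast (it is sign-blind), so
dissimilarity statements are tested against a process with *no*
transition structure rather than an anti-correlated one.

Replication profiles bin windows into 7 quantile bins of the replication
track; G:C>A:T transitions in CpG context (mutated C followed by G, or
mutated G preceded by C) are excluded from the transition series, and
the covariate-adjusted trend p-value comes from the window regression
below. The nearest-distance null redraws each cohort's variant count
uniformly over the callable mask (200 replicates by default) and
compares observed to mean-expected histograms over log2-spaced distance
bins {0–1, 2–3, 4–7, …}; randomization deliberately ignores local GC.

## Window regression

Nine features per fixed window (1 Mb by convention; any size that yields
≥10 windows): distance from window midpoint to the nearer chromosome
end, replication time, simple-repeat bases, GC fraction
(G+C)/(A+C+G+T), CpG dinucleotide bases, CpG-island bases, gene-content
bases, and DNase/lamina track densities. Windows with more than half
uncallable bases are dropped. Counts per window are modelled by ordinary
least squares on all nine features jointly; features are standardized
first so the t-values share an axis, and significance is
Bonferroni-corrected per model (0.05/9). Collinearity triggers a warning
with a variance-inflation report but the fit is returned. A count model
(Poisson/negative-binomial) was deliberately not used; the linear model
on per-window counts is the convention this analysis follows, and the
type-I calibration suite verifies its family error control empirically.

## Selection-normalization cascade

Per location t, composition c ∈ {AT, CG} and length l (capped at 30 with
a pooled top stratum), the affected fraction Freq, its ratio to the
genome-wide stratum (rFreq), the length weight within (t, c), and the
composition weight within (t, l) are chained exactly as the formulas in
the README; strata with zero runs or zero genome-wide frequency are
excluded (logged). A run's location is the region of its leftmost base,
or by majority overlap when it straddles a boundary. Three statistics
are offered: `union` (a homopolymer is affected if any cohort indel maps
to it — the headline binary statistic), `per_sample` (binary per
(run, sample) pair), and `rate` (indel events per (run, sample) pair).
The rate mode is exactly linear in per-sample hit rates and is therefore
used for parameter recovery, where the binarized modes would be biased
by saturation at high hit rates. Two caveats are inherent to the
formulas and documented rather than patched: the genomic denominator
contains the location under test (so a depleted location's recovered
ratio sits slightly above the injected multiplier, by a factor
1/(1−s·(1−r)) for locus share s and multiplier r), and the composition
weighting makes the null fixed point exact only when the AT/CG split is
independent of length — which holds for the generator and approximately
for real genomes.

## Recurrence and markers

Loci are keyed by run coordinates, not indel alleles: different-length
deletions at one run are one recurrent locus, because a genotyping assay
interrogates the locus. The null expectation stratifies by homopolymer
length only (pooling compositions): with per-sample hit rate p̂(l)
estimated from the cohort's marginal affected fractions, the expected
number of loci of length l affected in ≥k of m samples is
n(l)·P(Bin(m, p̂(l)) ≥ k). This independence null is a reconstruction —
the original analysis does not specify its expectation model — and is
validated against a 1e5-replicate Monte-Carlo oracle. Marker candidates
must recur in ≥6 samples, be observed in every required tissue (both
endometrial and colorectal in the motivating design), and sit in
homopolymers of at most 12 bp; the length bound is configurable because
the source texts state it both as "<12" and "≤12" — the inclusive bound
is the default.

## MSI classifier

Samples are scored by their number of positive markers; missing
genotypes are excluded from the count (a fixed-denominator mode exists),
and an all-missing sample is flagged uncallable rather than called
negative. The threshold scan evaluates every θ from 0 to the panel size;
MCC is defined as 0 when a confusion marginal is zero, and ties break
toward the smaller θ (maximal sensitivity, appropriate for screening).
Bethesda categories follow the 0 / 1–2 / ≥3 out of 10 cutpoints
(configurable).

## Synthetic cohort generator

The generator's defaults are the study conditions: a 50× somatic burden
in MMR-deficient tumors, 80% of mutations being indels, 74% of
substitutions transitions, 81% of indels deletions, indel context
enrichments of 40× (homopolymers) and 2.3× (microsatellites),
substitution enrichments of 3× and 1.5×, a 3× substitution excess at
bases immediately flanking homopolymers (1.3× for microsatellites) with
the excess converting the flanking base to the repeat base, CpG islands
mutating at 0.5 the outside rate, exonic indels retained at 0.09, and
region proportions of 1.12% exonic / 34.01% intronic / 0.78% 3'UTR /
0.14% 5'UTR / 2.81% ncRNA / 0.58% upstream / 0.58% downstream / 59.98%
intergenic. Where the motivating analyses state no value, defaults are
one-time choices: homopolymer lengths are 6 plus a geometric tail
(p=0.5, so lengths 6–12 dominate, matching the observed recurrence bias
toward 7–9 bp runs), 7% of homopolymers are C/G with a 0.25 relative
indel rate, per-run indel rates grow as (l−5)^1.5 saturating at l=20,
the replication track is a sinusoid (binned into quantiles downstream),
and the DNase/lamina proxies are normalized random walks. The default
problem size (10 Mb, ~1e5 variants across 3+2 tumors) keeps every
estimator's sampling error a small fraction of its recovery tolerance.

Placement is engineered so each configured fold is the *expectation* of
its estimator: per-class placement mass is the fold times the class's
callable-base share, with the non-repeat class absorbing the
normalization; within a class, mass is distributed over runs by the
length/composition/region multipliers and rescaled, so the class-level
folds are exact while within-class structure (e.g. exonic thinning)
holds in relative terms. Runs whose start lies inside a
higher-precedence overlapping run receive no placement mass, so
placement round-trips through context classification. Chance
homopolymers in the random background are sterilized (a middle base is
replaced) so homopolymer density is exactly the configured parameter;
chance tandem repeats of longer units are left in place — they are
intrinsic to random sequence, as they are to real genomes, and the
fold normalization accounts for them through the scanned base counts.
Flanking-base weights are set to fold × the genome-mean weight before
island dampening is applied to all bases, and the background transition
probability is analytically compensated for the expected
repeat-templated conversions so the cohort-wide transition fraction
matches the configured value. Indel hits are Poisson per (locus,
sample); repeated hits are kept as separate events, so event counts are
exactly linear in rates (deduplication would thin dense loci
preferentially). One seed drives everything through fixed spawn keys —
reference (seed, 0), sample i (seed, 1, i), marker cohorts (seed, 2),
stratum cohorts (seed, 4) — giving byte-identical outputs for any
cohort size.

A second, stratum-level generator bypasses sequence entirely: it draws
homopolymer loci with locations, compositions and (optionally
location-specific) length mixtures, and Poisson hits per (locus,
sample) with a length effect and optional per-location multipliers. It
exists to calibrate the cascade at scale without the cost of sequence
simulation.

What the generator does *not* emulate: read-level errors and coverage,
subclonal structure, copy number, mappability, interrupted
microsatellites, genuine gene structure (regions are shuffled blocks),
or any joint distribution linking covariate tracks to mutation rates
beyond the single replication-time gradient — the covariate-effect
sizes are free parameters of the simulation, not estimates. Passing
recovery tests therefore demonstrate estimator correctness under the
modelled processes, not performance on real sequencing data.

## Numerical and engineering choices

Interval arithmetic is vectorized numpy over sorted half-open intervals;
same-kind overlapping runs are flattened for lookup so every base maps
to one run per kind. MCC uses exact integer arithmetic in the products.
The discovery-set worked example builds a marker matrix from the
published confusion counts (40/41 detected, 1/184 false-positive), with
sub-threshold counts distributed so that every threshold other than 3 is
strictly worse — the printed counts pin the θ=3 row; the shape of the
rest of the ROC is illustrative. Test suites use fixed seeds throughout;
tolerance bands are set at 3–5 standard errors of the relevant estimator
at the simulated problem size.

## Known limitations

The cascade's genomic-denominator dilution (above) is inherent to the
published formulas. The flanking-slippage fold estimator has the widest
sampling variance of the recovery suite (flanking bases are ~0.5% of the
genome), so its recovery band is correspondingly wide. The microsatellite
definition admits any two-unit tandem of a 4–6 bp word, which makes
"microsatellite" bases ~12% of random sequence; this matches the stated
definition and is handled by the fold normalization, but absolute
microsatellite base fractions should not be compared against annotations
that use stricter definitions.
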