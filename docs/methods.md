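# Methods

This note documents the statistical models, the defaults and the design
choices behind each stage of the pipeline, and what the synthetic-data
validation does and does not establish about real array data.

## Probe-level model and expression indices

Probe intensities within a probe set are modelled multiplicatively
(Li–Wong, PM-only form):

    PM_ij = θ_i φ_j + ε_ij,    ε_ij ~ N(0, σ²),

with one expression index θ_i per array and one affinity φ_j per member
probe, identified by Σ_j φ_j² = J. The fit is alternating least squares:
θ given φ, φ given θ, rescaling φ to the constraint each round with θ
absorbing the inverse factor so the fitted matrix — and hence the residual
sum of squares — is unchanged by the rescale. With non-negative intensities
and a non-negative start the least-squares updates remain non-negative on
their own, so the non-negativity constraint on θ and φ never requires an
active projection in practice. Convergence is declared when the maximum
relative change of θ falls below `tol` (default 1e-6, `max_iter` 100);
on exactly rank-one data the fit converges in two sweeps.

Outlier handling is a deliberate reduction of the original iterative
array/probe/single-outlier machinery: after convergence, cells with
|residual| > 3 residual SDs are flagged and the set is refitted once with
those cells excluded. One round reliably catches isolated moderate
corruption (a single cell inflated ~3–8×, at 10% noise) but a sufficiently
extreme single cell (~20×) can leverage the rank-one fit enough to mask
itself; users needing full robustness should inspect `outlier_flags_` and
`residual_sd_`. The residual SD uses IJ − (I + J − 1) degrees of freedom.
Degenerate all-zero probe sets get θ = 0, converged, zero residual.

## Normalization

`median_scale` rescales every array so its median equals the baseline's
median. `invariant_set` iteratively keeps probes whose rank-difference
proportion against the baseline is < `rank_tol` (default 0.02, floor
max(100, 1% of probes), falling back to median scaling with a warning when
the set collapses), then maps intensities through a monotone
piecewise-linear curve: quantile-bin medians of the invariant scatter
(~40 points per knot), made non-decreasing by isotonic regression, linearly
interpolated and end-extrapolated so extreme intensities are rescaled
rather than clipped. The baseline `"auto"` rule picks the array whose
overall median is closest to the median of the per-array medians.

Median scaling is the default. Note one consequence visible in synthetic
runs: when a few percent of probes are genuinely up in one group, median
scaling slightly deflates those arrays, which shifts the null distribution
of the SAM statistic. The permutation null absorbs the shift (calls remain
correct), but the π0 estimate — the share of observed d inside the null
quartile window — drops well below the true null fraction, making the FDR
estimate more liberal. The rank-invariant method resists this because
differential probes leave the invariant set.

## SAM screen

For groups of sizes n1, n2 the statistic is d = r/(s + s0) with
r = mean₂ − mean₁ and s² = (1/n1 + 1/n2)/(n1 + n2 − 2) × (SS₁ + SS₂), so
s0 = 0 recovers the pooled two-sample t exactly. The fudge factor s0 is
selected from {0} ∪ {percentiles 0, 5, …, 100 of s} to minimize the
coefficient of variation of the median absolute deviation of d across
quantile windows of s (windows of ~25 sets, at most 100); ties go to the
smallest candidate, and an all-equal scatter returns 0 with a warning.

The null is built by relabeling the pooled samples of the two groups. With
3 + 3 replicates there are only C(6,3) = 20 distinct splits, so they are
enumerated exhaustively (variance-free); the nominal permutation count
(default 800) acts as a cap and as the sample size for larger designs,
drawn uniformly with replacement. Expected order statistics d̄_(i) are the
per-rank means of the sorted null statistics.

Calling is per-gene and conjunctive: in rank space, up-calls require
d_(i) − d̄_(i) > δ **and** linear fold change ≥ `fold_min` (default 2);
`direction="both"` adds the mirrored rule with fold ≤ 1/`fold_min`. Fold
changes are ratios of group means of θ with an additive floor (default 1.0)
in numerator and denominator, since MBEI values are linear-scale and can
be near zero. The median FDR at δ is

    median over permutations of #{d* ≥ cutup} (+ #{d* ≤ cutdown}) × π0 / n_called,

clipped to [0, 1], with cutup/cutdown the innermost called d in each
direction and π0 = min(1, share of observed d inside the (q25, q75) window
of the pooled d* ÷ 0.5). δ is chosen on a 200-point grid from 0 to
max|d − d̄| as the smallest value whose median FDR is strictly below the
target (default 0.01) — on a monotone table this maximizes calls subject
to the bound. The screen defaults to one-sided (up-in-target) calling, the
direction of an enrichment screen for a sorted cell population; two-sided
calling is available.

On fully null data every call is a false discovery (FDP = 1); simulation
(50 seeds, 2,000 null sets, exhaustive 20-split null, three call levels)
shows the clipped median-FDR estimate reaches 1 in ≥ 95% of seeds, i.e. it
is a conservative estimate of the realized FDP.

## Probe-set consistency f-ratio

Each member probe is z-scored across the sample series (sd with S − 1;
constant probes are dropped and recorded rather than zero-filled, which
would deflate the two variance terms asymmetrically). With m_s the
per-sample mean of the z-scores,

    f = Var_s(m_s) / [ Σ_s Σ_j (z_js − m_s)² / (S (J − 1)) ].

The between-variance deliberately omits the J multiplier of a classical
one-way ANOVA mean square: with the multiplier the null expectation is ≈ 1
and a cutoff of 1.0 could not separate coherence from noise, whereas
unscaled, independent-noise sets concentrate near 1/J ≪ 1 and coherent
sets exceed 1. The classical scaling and a group-mean variant of the
between-variance are available as options. The filter keeps sets with
f strictly > 1.0; a zero within-variance (perfect coherence, including
numerical rounding dust below 1e-12 of the between term) maps to +∞ and
passes. The statistic is exactly invariant to per-probe affine transforms
of the raw intensities and to probe or sample permutations, and requires
≥ 2 usable probes and ≥ 3 samples.

Because the f-ratio needs per-sample *variation* to detect coherence, it is
informative only for probe sets whose transcript actually varies across the
sample series — which is exactly the candidate population it is applied to
(SAM-called sets). Flat expression profiles score ≈ 1/J regardless of probe
quality.

## Keyword filter

A local, pinned annotation table (probe-set id → GO term strings; two-column
TSV or GAF-like input) replaces interactive web queries for
reproducibility. Matching is case-sensitive substring by default — 'GTP' is
a chemical abbreviation, and lowercase 'gtp' in free text would be a
different token — with word-boundary and case-insensitive modes as options.
The five canonical 'GTP' ontology terms all match in substring mode; 'ATP
binding' never does.

## Synthetic data generator

The generator emulates the screen's design: 4 populations (whole P8 retina,
GFP− P8, GFP+ P8, GFP+ adult) × 3 replicate arrays, 16 probes per set,
rank-one signal θ_g(s)·φ_g(j) with log-normal baselines (ln-mean 6, ln-sd
1; median intensity ≈ 400), log-normal positive affinities rescaled to
Σφ² = J, additive Gaussian noise at `noise_sd` × the set's baseline
(default 0.1), and intensities floored at 1. Truly differential sets
(default fraction 1623/36701 ≈ 4.4%, the called fraction of the original
screen used as the true fraction) have θ multiplied by `de_fold` (default
3) in the target population only — one-directional, matching an enrichment
screen. Inconsistent sets (default 5%) replace a fraction of member probes
(default half) with an independently drawn group-level profile; they are
kept disjoint from the differential class so that truth-based accounting is
unambiguous. Annotation simulation tags each set with ≥ 1 'GTP' term by an
independent Bernoulli draw (default p = 96/1623 ≈ 5.9%) and fills in
non-matching terms from a small vocabulary.

What passing tests on this generator do show: the algebra and calibration
of every stage (exact t-equivalence, conservative null FDR, recovery at
known effect sizes, f-ratio separation at known discordance). What they do
not show: robustness to real-array phenomena the generator deliberately
omits — mismatch probes, background, spatial artifacts, saturation,
cross-hybridization, correlated noise, probe-sequence effects — nor the
original screen's exact counts, which depend on the deposited arrays and a
contemporary annotation build. A full-size synthetic screen (36,701 sets)
reproduces the funnel's *shape*: ~1,900 SAM calls containing all true
positives plus inconsistent sets with apparent differential signal, ~6% of
calls keyword-matched, and the f-ratio stage removing precisely the
inconsistent contaminants.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds; identical
config + seed reproduces every artifact byte-for-byte (floats are written
with 12 significant digits; reports are serialized with sorted keys and no
timestamps). Zero-scatter SAM inputs map to signed-infinity sentinels and
are excluded from s0 estimation; degenerate δ searches warn and return the
grid maximum (zero calls). The filter cascade's stage order is
configurable; membership is order-independent because the keyword and
f-ratio filters do not depend on the SAM result, so order affects only
compute cost — asserted in tests.

Problem sizes used by the validation suite — 1,000–2,000 probe sets for
recovery and calibration runs, 10⁴ draws for the f-ratio null, 20–50 seeds
for the seed-level checks, and one 36,701-set full-size cascade — were
chosen to make each estimate's Monte-Carlo error comfortably smaller than
the margins being asserted.
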