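# Methods

`lcmirna` implements the analysis chain of a two-card TaqMan low-density
array (TLDA) miRNA screen comparing two small groups of postmortem brain
donors (by default 11 controls vs 9 cases, ~377 miRNA assays per card).
This note records the model, the numerical conventions, and the design
choices made where the procedure was genuinely open.

## Quantification model

qPCR reports a cycle threshold Ct per well; abundance is proportional to
2^(−Ct), so **lower Ct means higher expression**. All direction language
in outputs ("up", "higher expression in females") is stated on the
expression scale with this inversion applied.

1. **Detectability.** Wells above Ct 35 are unreliable on TLDA cards;
   an assay is retained only if the fraction of samples with detectable
   Ct ≤ 35 reaches `min_fraction` within *every* group (default 1.0 —
   rank tests and correlations need complete vectors). Cells recorded as
   `Undetermined` are undetectable with no stored value; a display
   ceiling may be imputed for plots only, never for statistics. The
   plant-specific negative control (ath-miR-159a) is always excluded.
   `min_fraction` is exposed because the retention rule of the original
   two-card design is not fully recoverable from published totals.
2. **ΔCt (differential expression).** ΔCt = Ct − per-sample median Ct of
   retained assays, per plate (cards were run as replicates and
   normalised separately). The median of an even count is the midpoint
   of the two central values. ΔCt is invariant to per-sample additive
   shifts (pipetting/input-amount effects), which is the point of the
   normalisation.
3. **Global-mean centring (co-expression).** For correlation analysis,
   Ct is instead centred by the per-sample mean over *all* retained
   assays, plates pooled — removing differences in overall miRNA
   content between individuals that would otherwise induce spurious
   positive correlations everywhere.
4. **ΔΔCt fold change.** ΔΔCt = mean ΔCt(case) − mean ΔCt(control);
   fold = 2^(−ΔΔCt). A positive ΔΔCt therefore maps to fold < 1
   (down-regulated in cases).
5. **Endogenous controls.** The per-sample geometric mean (on the Ct
   scale, exp(mean(ln Ct))) of U6/RNU44/RNU48 is compared between groups
   per plate with a pooled t test; a group difference would invalidate
   the normalisation.

## Per-miRNA testing

The two groups are independent and of unequal size, so the nonparametric
test is the **Wilcoxon rank-sum (Mann–Whitney)** test, two-sided.
Exact p-values are computed by complete enumeration of the C(n, n1)
group assignments whenever that count is ≤ 5000 (covers every design
with n1 + n2 ≤ 14), defining the two-sided p as the proportion of
assignments whose U deviates from n1·n2/2 by at least the observed
deviation — valid under ties because U is symmetric about its mean
under exchangeability. Larger designs use the tie-corrected normal
approximation with continuity correction; its measured type-I error at
α = 0.05 (n = 9 vs 11, normal nulls, 2000 replicates) is 0.049.
Significance at p = 0.05 is boundary-inclusive. No Bonferroni
correction is applied: miRNAs are heavily cross-correlated (often
co-transcribed), violating its independence premise.

## Permutation FDR (SAM-type, two-class unpaired, Wilcoxon statistic)

Per assay, the standardised rank-sum statistic
d = (W − μ_W)/σ_W (tie-corrected σ) is computed. Group labels are
permuted — distinct assignments drawn uniformly without replacement,
or exhaustively enumerated when fewer exist than `n_perm` — and the
expected order statistics d̄₍ᵢ₎ are the means of the sorted permuted
vectors. A threshold Δ on the deviation of the ordered observed d₍ᵢ₎
from d̄₍ᵢ₎ induces cut points on the statistic scale (the smallest
observed d whose positive-side deviation reaches Δ, and symmetrically
below); the called set is every assay beyond a cut, and

FDR(Δ) = (mean over permutations of the number of permuted statistics
beyond the cuts) / max(1, #called) × 100,

clipped to [0, 100] and made monotone non-increasing in Δ by a running
minimum. The numerator is the *expected* number of falsely called
assays, the original SAM formulation; the later median variant is
unstable for small call sets, where the cut is the observed extreme
statistic and the median permutation exceedance collapses to zero about
half the time, admitting spurious calls. No fudge factor s₀ is applied
(it is undefined for a rank statistic) and π₀ is not estimated (the
estimate is therefore conservative). The call set at a requested FDR
ceiling is the largest one whose estimated FDR is at or below the
ceiling. Seeded permutation sampling makes the whole procedure
reproducible bit-for-bit.

Calibration measured at the defaults: with 20 two-cycle shifts planted
among 300 null assays (σ = 0.5, n = 10/group, 1000 permutations), all
planted assays are recovered at FDR ≤ 5% with ≤ 2 false calls in
≥ 9/10 seeded runs; a tiny 4-vs-4 instance reproduces an exhaustive
brute-force oracle exactly.

## Differential co-expression networks

Pearson correlations are computed for all assay pairs within each group
separately on the globally centred values. A pair is an edge of the
*case-specific* network iff

1. r_case > 0.7,
2. −0.7 < r_control < 0.7, and
3. r_case − r_control > 0.8,

with strict inequalities; the control-specific network mirrors the
criteria. The 0.7 threshold is the conventional rounding of the
critical correlation at α = 0.05 for these group sizes:
r\*(n) = t_c/√(df + t_c²) with df = n − 2 gives 0.666 at n = 9 and
0.602 at n = 11. Criterion 2 as stated also excludes strongly *positive*
control correlations; criterion 3 makes that partially redundant, and
the literal rule is kept. Known limitation, quantified by Monte Carlo at
n = 9/11: a null pair passes all three criteria with probability
≈ 0.008, so on large panels the networks carry a substantial
sampling-noise background; and a truly case-correlated pair at r = 0.85
is recovered with probability only ≈ 0.50 (≈ 0.74 even at r = 1),
because the gap criterion absorbs the control-group sampling noise
(sd(r̂) ≈ 0.32 at n = 11). Detecting differential co-expression reliably
at these group sizes requires either larger n or weaker criteria; the
published thresholds are kept as-is.

Networks are undirected, self-loop-free, carry (r_case, r_control) on
every edge, and export to GraphML and TSV with lossless re-import.
Hubs are nodes at or above the top-decile degree.

## Clustering

Hierarchical clustering of ΔCt profiles uses Euclidean distance with
complete linkage (monotone merge heights). Items are sorted
lexicographically by id before clustering, making the result invariant
to input order; remaining distance ties resolve through scipy's fixed
agglomeration order. Values are not scaled before clustering (only the
median normalisation is applied); a z-score option exists.
Chromosome-level clustering groups significant miRNAs sharing a
chromosome (≥ 2 members) at whole-chromosome granularity — the
annotation schema carries no base-pair coordinates — and reports strand
makeup and direction concordance (fraction sharing the majority
direction of change).

## Confound analyses

Group comparisons of age, postmortem interval, brain pH and RIN use the
pooled-variance Student t (df = n1 + n2 − 2). Welch's form differs only
in the third decimal here, but pooled is the form consistent with the
integer df = 18 reported for an 11-vs-9 design, so it is the default
and only form. Covariate screens are marginal Pearson correlations of
each assay with age/PMI/pH within each group, flagged at α ≤ 0.05;
sex effects reuse the pooled t per assay. The packaged 20-subject
demographic table ships verbatim (11 controls including the eleventh
listed subject — the printed df = 18 confirms 11 + 9 even though the
accompanying text says ten controls; the discrepancy is documented, not
resolved).

## Synthetic experiment generator

The generator emulates the study conditions so every stage is testable
without any download:

| parameter | default | meaning |
|---|---|---|
| n_control / n_case | 11 / 9 | group sizes of the study design |
| n_assays_per_plate | 377 | two cards, 754 miRNA assays total |
| baseline Ct | U(18, 33) per assay | abundance spread of brain miRNAs |
| sample_offset_sd | 0.5 cycles | per-sample global content shifts |
| noise_sd | 0.5 cycles | well-to-well technical noise |
| planted_de | 13 assays, folds 0.486–1.577 | magnitudes of the reported hits |
| planted_blocks | one 10-assay block per group, loading 1.19 | pairwise r = L²/(L²+σ²) = 0.85 |
| dropout | 0.02 | probability a well exceeds the Ct-35 limit |

Group effects enter on the Ct scale as −log2(fold) so the ΔΔCt pipeline
recovers the configured fold unbiasedly on the log scale; co-expression
enters through latent single factors (shared upstream-regulator model)
rather than explicit covariance matrices. Dropout cells are recorded as
undetectable. Endogenous controls are generated per plate with no group
effect; the negative control never amplifies. Demographics are drawn to
match the packaged subject-table moments and are independent of
expression by default (`covariate_coupling` exists for power tests of
the confound screen).

What the generator does **not** emulate: amplification-efficiency
differences, plate spatial effects, correlated dropout near the Ct
ceiling, and the real (unknown) correlation structure among the 754
assays. Passing recovery tests therefore demonstrates correctness of
the computations under the stated model, not performance on real
tissue panels.

## Problem sizes and numerical conventions

Tests and the reproduction script run the permutation analyses at
1000 permutations, 10 seeded replicates, and panels of 60–320 assays —
sizes chosen so the full statistical behaviour (exact enumeration
switchovers, FDR calibration, recovery rates) is exercised while a
complete run stays in the seconds-to-minutes range. Floating-point
comparisons against brute-force oracles are at 1e-10; correlation
matrices are clipped to [−1, 1] with unit diagonal; all RNG is
`numpy.random.default_rng` with explicit seeds, and every pipeline
output embeds a hash of the analysis configuration (resuming into an
output directory with a different hash is refused).
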