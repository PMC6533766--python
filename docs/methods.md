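# Methods

## Statistical model

Each CpG's methylation level (percent, from very deep amplicon bisulfite
sequencing) is modelled over the repeated blood draws of one cohort with a
random-intercept linear mixed model,

    level_ij = β0 + Σ_t β_t · 1[time_ij = t] + u_i + ε_ij,
    u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²),

where `i` indexes subjects and time is categorical with the pre-dose draw
(0 h) as reference — the response is not monotone in time (it peaks at
3–6 h and reverts), so no trend is imposed. Fits use REML via
`statsmodels.MixedLM`; maximum likelihood is used only where AIC
comparisons require it (stepwise covariate selection, with
AIC = −2·maxlogL + 2k and k counting fixed effects plus the two variance
parameters). Negative subject-variance estimates are truncated at zero and
degenerate fits (e.g. a constant response) return a flagged result with NA
statistics instead of raising.

The omnibus treatment test is the Wald chi-square over all time
coefficients, b′Cov(b)⁻¹b ~ χ²(T−1) under the null. Per-time-point
contrasts refit the model on the {baseline, t} subset — deliberately a
pairwise refit rather than a joint-model contrast, so each contrast uses
only the data that inform it and unbalanced subsets are handled naturally.
A differentially methylated CpG (DMC) requires Benjamini–Hochberg
q ≤ 0.05 across all CpGs tested in the batch **and** an absolute contrast
of ≥ 1 percentage point at a time point whose (uncorrected) contrast
p ≤ 0.05; per-time-point p-values are intentionally not FDR-corrected.
The Wald test is asymptotic: in very small designs its type-I error runs a
few points above nominal, which is why calibration checks use designs with
enough subjects for the normal approximation to hold.

Genotype moderation pools risk-allele carriers (CT/TT) against CC and, per
post-baseline time point, fits `level ~ time + group` (additive) and
`level ~ time * group` (interaction) on the {baseline, t} subset, reporting
Wald p-values for the group and interaction terms plus the sign of each
group's within-group delta. Cross-study concordance of effect directions
is tested exactly: with n sites whose direction could agree by chance with
probability ½, the reported p is the binomial upper tail P(X ≥ k). The
direction compared defaults to the sign of the interaction coefficient at
the peak time point; group-wise delta signs are also emitted so either
reading can be reproduced.

Power is estimated by simulation from the fitted model: the tested time
coefficients (default 3 h/6 h) are set to the minimum effect of interest
(default 1 point), responses are drawn from the estimated variance
components, the model is refit, and power is the fraction of `n_sim`
(default 100) replicates with omnibus p ≤ α; its 95% CI is a binomial
bootstrap over the replicate outcomes. The parametric bootstrap
(simulate-from-model → refit, default 100 draws) reports bias, SE and
2.5/97.5-percentile intervals per fixed effect and is flagged unreliable
if more than 20% of refits fail. qPCR expression is summarised with the
efficiency-calibrated ratio E_t^ΔCt_t / E_r^ΔCt_r against a reference
gene.

## Read processing

Reads are assigned to the amplicon panel in "three-letter" space: the
reference and the read are both collapsed on the bisulfite-variable base
(C/T for top-strand assays, G/A in top-strand coordinates for
bottom-strand assays), so a molecule's methylation state cannot bias where
it maps. Each mate is aligned (edlib infix alignment, both orientations)
against every converted amplicon; pairs are `unmapped` below 90% identity,
`discordant` when the mates prefer different amplicons, and `ambiguous`
when the best amplicon beats the runner-up by fewer than 2 edits. The
defaults are chosen so random 150-mers essentially never map to a small
panel; edit distance (rather than gapped affine alignment) is adequate
because amplicon reads are near-exact and indels are out of scope.

Assigned mates are fused in amplicon coordinates: inside the overlap each
position takes the base of the mate with the higher Phred quality (ties to
mate 1, consensus quality the maximum); disjoint mates yield a record with
a flagged internal gap so no position is ever double-counted — one
molecule contributes at most one call to any site. Calling then reads the
original (uncollapsed) bases at every interrogated cytosine: template base
→ methylated, converted base → unmethylated, anything else → `other`.
Counts from amplicons sharing a CpG are summed; uncovered sites are
missing, never 0%. CpG sites are keyed by the forward-strand C of the
dyad, so top- and bottom-strand assays of the same CpG collapse onto one
identifier.

## Quality control

Conversion is estimated per sample as `100 − 100·Σmeth/Σ(meth+unmeth)`
pooled over CHH sites — pooling weights sites by coverage and has lower
variance than averaging per-site levels (both estimators agree in
simulation). The cascade runs strictly in order: (0) whole-amplicon
exclusion when mean per-sample reads fall below a floor or pooled CHH
methylation exceeds 5%; (1) PCR-artifact cells, defined as coverage below
10% of the amplicon's median coverage in that sample at a level of exactly
0 or 100% — the artifact notion is inherently relative, so this rule is
configurable and every removal is logged; (2) samples with conversion
< 95% (strict inequality; a sample estimating exactly 95.0% is kept);
(3) cells under the absolute coverage floor (1000 reads at full study
scale). Removals are disjointly attributed and the report reconciles cell
counts exactly. Because the artifact rule is relative to the current
matrix's median, the cascade is idempotent on realistic coverage
distributions but not in adversarial ones where the median shifts by more
than the artifact factor after filtering.

## Synthetic data

The generator emulates two designs: a deep time course (19 men, draws at
0/1/3/6/23 h, genotype 6 CC / 6 CT / 7 TT) and a validation cohort (89
subjects, 0/3/~18 h, 50/30/9, 67 men / 22 women, 59 depressed
in-patients). True methylation is additive on the proportion scale —
deltas are reported in percentage points, not logits —

    level = clamp(π₀ + u_subject + g·δ(t)/100 + covariate terms + ε,
                  0.001, 0.999),

with subject SD 3 points, occasion-level noise 1.5 points (`residual_sd`;
without it the random-intercept model would be degenerate on truth-level
data), responsive sites following the canonical shape 40%/80%/100%/20% of
the peak delta at 1/3/6/23 h (linear interpolation in between, so the ~18 h
draw of the second design maps to partial recovery), peak deltas spanning
−17…−1 points with a ~26% hypermethylated minority, and genotype
moderation as a multiplier on δ(t) for T-allele carriers. Covariate slopes
act on mean-centred covariates; lymphocyte counts are time-varying with a
DEX-induced drop to ~50–55% of baseline at 3–6 h. CHG/CHH methylation is
fixed at 0 (negligible in blood), which is exactly what makes conversion
failure estimable from CHH context. The ~18 h draw-time heterogeneity of
the second design is modelled as a single nominal time point, as the
analysis treats it.

Reads are generated per molecule (Bernoulli methylation per CpG,
conversion failure with probability 1−c, uniform base substitution with
probability e, Phred qualities ~ N(37, 2.5) clipped); mate 1 covers the
amplicon 5′ end, mate 2 the 3′ end reverse-complemented. Defaults:
conversion 0.995, error 0.002, 1000× coverage, 150 bp reads. FASTQ output
is gzip with zeroed mtime, so identical configurations are byte-identical.
What the generator does **not** model — PCR duplicates and amplification
bias, indels, quality miscalibration, cell-composition shifts as a
methylation confounder, real sequence context — bounds what passing tests
show: they validate the inference machinery under the stated noise model,
not robustness to every artefact of real libraries.

## Numerical and design choices

Coordinates are 1-based inclusive internally and in TSVs (matching
position-style CpG ids); BED I/O converts to 0-based half-open. Each
amplicon interrogates exactly one bisulfite strand. Site distance to a
feature is measured from the forward-strand C to the feature centre
(negative = left of centre); "in motif" uses the feature's full span and
"in window" a ±50 bp centre distance, and both flags are reported because
"located in a binding site" admits either reading. Overlap-tie bases go to
mate 1; nearest-feature ties go to the lower coordinate; BH q-values come
from `statsmodels.multipletests` and are cross-checked against a direct
step-up enumeration in the tests, as is the exact binomial tail against
exhaustive enumeration. MixedLM occasionally fails at the σ_u ≈ 0 boundary
with the default optimizer; fits retry with Powell before being flagged.

Test and acceptance problem sizes are scaled to a single CPU: ~300 CpGs
for calibration runs, ~200 read pairs per amplicon and sample with QC
floors scaled accordingly (50 instead of 1000), 100 simulations for
power/bootstrap, and 8–12 seeded replicates for detection-rate checks.

## Known limitations

* The mixed model is Gaussian on percent methylation; no beta/binomial
  response, random slopes or autoregressive residuals.
* Alignment is substitution-only; indel-containing reads inflate edit
  distance and may be dropped at the identity threshold.
* The artifact filter is a declared, configurable convention (the
  low-coverage/extreme-level rule); other reasonable formalisations exist.
* Stepwise AIC inherits the known ~16% per-candidate false-inclusion rate
  of the AIC penalty; it selects, it does not test.
* Reproducing published probe/CpG counts for a specific locus requires the
  corresponding vendor manifest, assay coordinate table and reference
  genome, which are external inputs to this package.
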