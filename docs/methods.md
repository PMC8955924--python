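# Methods

## Scope and model

berrydeg implements the downstream analysis of a two-treatment deficit
irrigation berry transcriptome study starting from per-sample transcript
read counts (or precomputed RPKM): normalisation, filtering, replicate
validation and merging, ratio-based differential expression, set
partitioning of active transcripts, functional-category profiling, a
water-potential regression screen, and ΔΔCq RT-qPCR quantification.
Upstream steps — sequencing, trimming, read mapping and annotation transfer
— are out of scope; the pipeline's contract begins at a count or expression
table.

## Quantification and filtering

RPKM is computed cell-wise as `count / (library_size/1e6) / (length_bp/1e3)`.
The library size is taken from the sample sheet when supplied for every
sample, otherwise as the count-matrix column sum; which source was used is
logged, because the two differ whenever reads were filtered between mapping
and counting. A permissive reader mode accepts fractional (estimated)
counts; the default insists on integers.

Two inclusive filters define the working universe: annotated length ≥ 150 bp
(an assembly-quality filter — very short fragments are unreliable) and RPKM
≥ 1 (the activity threshold). Both are applied matrix-wide before every
downstream stage; per-stage overrides exist but default off. Whether the
length filter in the emulated protocol was global or per-analysis is not
determinable; global removal is the default here because it keeps every
stage's universe consistent.

## Replicate validation and merging

Pearson correlation is computed between the two biological replicates of
each condition on ln(RPKM). ln(0) is undefined, so cells where either
replicate is zero are dropped for the correlation only (the
pairwise-complete convention once −∞ is coded missing); an optional
pseudo-offset mode (`ln(RPKM + ε)`) keeps all cells instead. Replicates are
merged by the arithmetic mean on the RPKM scale, not the log scale, because
downstream ratios are ratios of expression, not of log-expression. More
than two replicates is supported as a mean-pairwise-r mode; p-values are
then not reported. The p-value floors at machine precision; no software
reporting floor is emulated.

## Signed-ratio differential expression

The ratio statistic is deliberately simple: no dispersion model, no
shrinkage, no multiple-testing correction — a replicate-merged
treatment/control RPKM ratio with the sub-unity branch inverted to −1/r so
both directions read on the same scale. The significance cutoff |ratio| >
1.5 is strict (the printed convention `|>−1.5|` is ambiguous between > and
≥; strict is the default and configurable). Division by zero is not given
±∞: transcripts expressed on one side only are assigned sentinel states
(exclusive_treatment / exclusive_control / undefined) and routed to the set
partition analysis, which is where exclusive expression is meaningful.

The ratio histogram bins by magnitude with sign: |x| ≤ 1.5 is the central
"unregulated" bin — consistent with strict significance, ±1.5 exactly is
central — and |x| ∈ (lo, hi] maps to the signed bin on x's side, with
open-ended bins beyond ±5. Bin counts plus sentinel counts always equal the
row count. Top-k ranking breaks ties lexicographically by transcript id so
results are deterministic.

## Set partition

Condition-level activity is defined on the replicate-merged matrix (merged
RPKM ≥ 1, length ≥ 150), matching the merged-matrix convention used by the
ratio; a stricter active-in-every-replicate mode is provided. The partition
enumerates all 2ⁿ − 1 subset signatures (including empty regions) for n ≤ 6
conditions; exclusive counts are the singleton projections. Region sizes
are disjoint by construction and sum to the union exactly.

## Functional profiling

Percent-active per category is `100 · n_active / n_total` with the
denominator taken inside the current (post-filter) transcript universe;
whether the emulated protocol normalised pre- or post-length-filter is not
stated, and post-filter is the default because it keeps the ratio a true
fraction of the analysable category. DEG breakdowns count significant calls
per direction × category (× sub-category when annotated) and conserve the
significant-call total per direction exactly. A transcript carries exactly
one category; the first listed wins if an annotation supplies several.

## Water-potential screen

ΔΨ = max − min over each condition's diurnal series (MPa, Eq. form
max(Ψ)−min(Ψ)). Each transcript's expression across all samples (replicates
included) is regressed on the ΔΨ of its sample's condition by simple OLS;
R² is the squared Pearson correlation. With the canonical 2×2×2 design
there are 8 points but only 4 distinct amplitudes, which makes R²
thresholds permissive — `n_points` and `n_distinct_x` are reported so users
can judge support. Fits on fewer than 3 points are refused (a 2-point line
is always perfect); zero-variance transcripts are flagged undefined and
fail both thresholds. Expression enters untransformed by default
(`log_expression` flag available). The screen applies no multiple-testing
control, by design fidelity.

## ΔΔCq quantification

Technical replicates are averaged per (gene, sample, biological replicate)
before any normalisation. Multi-reference normalisation subtracts the
arithmetic mean Cq of the three references — at the assumed 100 %
amplification efficiency this equals the geometric mean of reference
quantities, the standard convention. Efficiency is fixed at 2 per cycle;
per-gene efficiency correction is out of scope. ΔΔCq differences use the
biological-replicate means; the t-test (Student's, two-sided; Welch by
flag) runs on per-biological-replicate ΔCq values, so with the canonical
2 × 2 plates it is an n = 2 vs n = 2 test — reported as such, with NaN
p-values when a side has fewer than 2 replicates. Magnitude significance
(|log₂| > 2) is strict at the boundary.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design (SDI/RDI × V/M × 2 replicates)
with: log-normal baseline expression (`exp(N(2, 1.5))` RPKM — a heavy right
tail like real bulk RNA-seq marginals); planted 4-fold up/down DEG sets per
stage in the RDI columns; ψ-linked transcripts whose expression scales
linearly with the condition's ΔΨ (amplitudes 0.4–1.0 MPa, larger under
RDI); sub-150-bp and sub-threshold transcripts to exercise both filters;
multiplicative log-normal replicate noise (σ = 0.05 on the log scale by
default); and Cq plates with stable references and fold changes encoded as
−log₂(fold) cycle shifts with 0.1-cycle noise. Expression is realised as
rounded expected read counts through length and a 20 M-read nominal library
so that RPKM quantification is exercised, not bypassed. Planted transcripts
have baseline expression clipped to ≥ 5 RPKM so they are active and never
hit the zero-count sentinel path. ψ-linked transcripts receive only their
own relative noise (`psi_noise_sd`, default 1 % of signal), not replicate
noise, so the screen's noise level is exactly the documented one.

All randomness flows from one `numpy.random.Generator` seeded from the
config; runs are bit-reproducible, and the qPCR plate derives its stream
from a seed sequence so plate and counts are independent.

Known limitations. Counts are rounded expectations, not Poisson/negative
binomial draws, so technical count noise is understated at low expression
and quantisation dominates below ~10 expected reads. Library-size
composition is real, though: because ψ-linked transcripts scale with ΔΨ,
total library size itself co-varies with amplitude, and constant-count
transcripts (RPKM ∝ 1/library size) can reach R² ≥ 0.90 spuriously — in
default simulations up to ~5 % of null transcripts, seed-dependent. This
is the same depth-confounding a real single-regressor screen faces and is
left in deliberately; the screen's correctness is established on a
construction with independent nulls. No batch effects, GC/length bias,
isoform structure or dropout beyond the planted inactive set are modelled,
so passing tests demonstrate algorithmic correctness under the documented
generative model, not robustness to those artefacts.

## Problem sizes and numerical choices

Default simulations use 2000 transcripts × 8 samples (tests use 200–500),
sizes chosen so the full suite and the acceptance run complete in seconds
while leaving >100 transcripts per planted class for stable rates.
Tolerances: RPKM and ratio algebra are checked to 1e-12 relative;
regression and correlation against independent oracles to 1e-10 absolute;
Monte-Carlo recoveries (50 plates) to 0.1 in log₂. Ties in top-k are
lexicographic; histogram boundary points resolve to the magnitude-lower
bin; threshold comparisons are ≥ for filters and R², strictly > for the
ratio cutoff and |log₂| rule, each matching its printed convention.
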