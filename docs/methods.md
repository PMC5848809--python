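# Methods

This note records the models implemented in `metarep`, the parameter
defaults and why, the synthetic world the validation rests on, and the
numerical choices and known limitations a maintainer should know about.

## Overall-accuracy quality control (`oa_qc`)

**Model.** Per-base accuracy `p_i = 1 − 10^(−q_i/10)`; the overall
accuracy of a fragment is `OA = Π p_i`, the probability the fragment is
error-free. A window of length `W` slides with step 1 from the 5′ end;
the read is truncated immediately before the start of the first window
with `OA < threshold`; if no window fails the read is kept whole; a
retained prefix shorter than `min_retained_length` discards the read.
Reads shorter than `W` are judged as a single fragment of their own
length. Retained reads are always unmodified prefixes of the input.

**Why the product.** With a mean-based definition a ~Q30 read would
score ≈ 0.999 and a 0.8 threshold would never fire; with the product, a
100 bp read at Q30 has whole-read OA ≈ 0.999¹⁰⁰ ≈ 0.905, which is the
scale on which a 0.8 fragment threshold meaningfully separates good
from locally corrupted fragments. This reading is a reconstruction (the
original pipeline's exact formula is in supplementary material not
available here); the window length `W = 10` and `min_retained_length
= 30` are this package's defaults and both are configuration-exposed.
No additional whole-read OA floor is applied.

**Numerics.** Window products are computed as cumulative sums of log
accuracies. Accuracy 0 (q = 0) is floored at 1e-300 before the log so
that any window containing such a base fails deterministically instead
of producing NaN. %Q30 is computed over retained bases.

## Rarefaction and relative abundance (`quantify`)

Downsampling to a fixed depth uses a multivariate hypergeometric draw
(reads are physical items subsampled without replacement), so the output
total is exact and each gene's count never exceeds its input. Columns of
a table are rarefied independently with child seeds spawned from one
`SeedSequence`, so adding a sample does not perturb the others. Gene
relative abundance is the length-normalized ratio
`a_g = (c_g/L_g)/Σ_j(c_j/L_j)`, an imported convention from reference
gene-catalog practice; it is invariant to global count rescaling and to
rarefaction at full depth.

## Fluctuation bands (`fluctuation`)

**Model.** Given replicate-1 count `c₁ ≥ 1`, the replicate-2 count is
modeled `X ~ Poisson(c₁)` (equal-depth resampling limit; a
`binomial(depth, c₁/depth)` alternative is selectable). The band is the
equal-tail discrete interval

    lo = max{k : P(X < k) ≤ (1−level)/2},
    hi = min{k : P(X ≤ k) ≥ 1−(1−level)/2},

with the CDF accumulated by direct pmf summation on a 12-σ grid and
ties resolved toward the wider interval. `c₁ = 0` gives the degenerate
band [0, 0] and such genes are excluded from coverage summaries. The
detectability threshold — the smallest `c₁` with `lo ≥ 1` — is 6 at the
99% level (`e^−6 ≈ 0.0025 ≤ 0.005`), so a 10-read gene is comfortably
predicted detectable in its replicate.

**Known under-coverage on twin replicates.** The band conditions on
`c₁` as if it were the true mean. On twin replicates both counts are
draws around a common mean λ, so `c₂ − c₁` has variance 2λ while the
band half-width is ≈ 2.576·√c₁; the asymptotic two-sided coverage is
Φ(2.576/√2)-based, ≈ 93.1%, and only the strong conservatism of the
discrete band at small counts pulls the aggregate up. In the package's
stated synthetic world (100,000 genes, log-normal σ = 2 community, two
independent 1,000,000-read multinomial replicates) the measured
concordance is ≈ 96.2–96.3%, stable across seeds, with per-stratum
coverage ≈ 97–98% at counts 1–4 falling to ≈ 94% at counts ≥ 10. A band
with nominal twin-replicate coverage would need to model both draws
(e.g. the conditional binomial `c₂ | c₁+c₂ ~ Bin(c₁+c₂, ½)`); the
Poisson-on-`c₁` form is kept as the package's stated model, and the two
validation tests that assume nominal twin coverage (≥ 99.5%) therefore
fail by design and are left failing rather than widened.

## HR-gene reproducibility statistics (`repro_stats`)

A gene is *highly reproducible* in a pair when it has ≥ `min_count`
(default 10) mapped reads in **both** members; for multi-pair analyses
it must qualify in ≥ `min_pairs` (default 6) pairs. On HR genes:

* **Spearman ρ** with average ranks for ties (scipy).
* **ALC** — per-gene `d_g = |log₂(a_g/b_g)|`; the area left of the
  empirical cumulative curve of `d` equals its mean (the identity
  `∫ x dF = E[x]` for non-negative `x` is verified numerically in the
  tests), reported also as the fold change `2^ALC ≥ 1`.
* **Paired tests** — a paired *t* test on log₂ abundances (variance
  stabilization on the heavy-tailed relative-abundance scale; the scale
  choice is this package's) and an exact two-sided sign test on raw
  differences with zero differences dropped from *n*. Each family is
  Benjamini–Hochberg adjusted separately (the two discovery counts are
  reported separately in the motivating study) and a gene is significant
  when either q-value < α. The t test requires ≥ 3 pairs of positive
  abundances; genes failing that fall back to the sign test alone.

BH is the standard step-up `q_(i) = min_{j≥i} min(1, p_(j)·m/j)`,
implemented directly (it is load-bearing here) and cross-checked against
statsmodels in the tests.

## GC-bias analyses (`gc_bias`)

**Per-species robust regression.** Assumption: within a species, gene
abundance is even and independent of gene GC, so a nonzero slope of
log₁₀ gene abundance on GC fraction indicates platform GC bias. The fit
is a Huber M-estimate via IRLS (statsmodels RLM: tuning c = 1.345, MAD
scale ×1.4826, convergence on coefficients, ≤ 50 iterations) — standard
robust-regression defaults, since only "robust linear model" is
specified upstream; on outlier-free data it coincides with least
squares. Species with < 3 positively-abundant genes or constant GC are
skipped with a warning list. The median slope across species is the
platform summary; under the synthetic exponential tilt `e^{β(gc−½)}`
the platform-B-minus-A median slope recovers β/ln 10 almost exactly,
because the same community underlies both platforms and the gene-level
log-normal scatter cancels in the difference.

**Log-linear LRT.** Species observations (per-platform mean abundance)
are dichotomized at the *pooled* abundance median and the species GC
median — cutpoints are data-derived, not imported constants. The
no-three-way-interaction hierarchical log-linear model (all three
two-way margins preserved) is fitted by iterative proportional fitting
(tolerance 1e-10 on all margins simultaneously, ≤ 1000 cycles), and
`G² = 2 Σ n_ijk ln(n_ijk/μ̂_ijk)` over non-empty cells is referred to
χ²₁ — df 1 for the single omitted three-way term, i.e. the test asks
whether the abundance–GC association differs between platforms. The IPF
deviance matches a Poisson GLM with all two-way interactions to
machine precision (tested). Cells tied exactly at a median go to the
"low" side; with few species this discreteness can leave slabs
imbalanced, which IPF absorbs into the margins.

## Synthetic world (`synthetic`, `workflows`)

Desk-scale defaults emulate a gut-metagenome platform comparison:

* **Catalog** — 100,000 genes (2,000 in the bias experiments) across
  ≥ 20 species with log-series-like size skew; GC from a two-component
  truncated-normal mixture (means 0.38/0.55, sd 0.05, weight 0.55),
  bimodal like real reference-catalog GC densities; log-normal lengths,
  median 750 bp, floor 100 bp.
* **Community** — i.i.d. log-normal gene masses, σ = 2 (natural log),
  normalized; most genes carry few reads at 1M-read depth, matching the
  count skew of a 9.9M-gene catalog sequenced at 20M reads. GC-independent
  by construction: the null for every GC analysis.
* **Replicates** — independent multinomial draws of 1,000,000 reads per
  replicate, 8 pairs; this *is* the technical-replicate model (shared
  template pool, independent sampling), with no overdispersion from
  library preparation.
* **Platform tilt** — `a_g ∝ a_g·e^{β(gc_g−0.5)}`, the simplest
  monotone GC enrichment; β = 0 is the identity.
* **FASTQ** — linear quality ramp 38→30 with Gaussian jitter (sd 2),
  clipped to [0, 45]; with probability `drop_rate` one 10 bp segment at
  a uniform offset is set to Q2.

What a green test on this world does establish: the statistics are
computed correctly, the null produces no discoveries, and an injected
GC tilt is detected and quantified with the right sign and magnitude.
What it does not establish: agreement with any real platform's numbers —
real data add mapping ambiguity, library-preparation overdispersion and
between-subject composition differences that the generators deliberately
omit, so study-specific values (retained-read percentages, exact ρ or
ALC values, species counts) are not reproduction targets. Notably the
synthetic twin replicates give ρ ≈ 0.946 and ALC fold ≈ 1.23 at the HR
threshold — inside the 1.008–1.323 fold range and near the ρ ≈ 0.93
reported for real intra-platform replicates — which is the Poisson
noise floor at this depth, not a defect of the generators.

## Numerical and design choices

* Discrete interval ties widened (conservative); levels nest.
* Quality ceiling 60 on FASTQ decode catches +33/+64 encoding mix-ups;
  4-line records only.
* Missing species labels exclude a gene from species-level analyses
  only, never from gene-level statistics.
* `hypothesis` property tests run derandomized; all simulations are pure
  functions of (parameters, seed) via `numpy.random.default_rng` /
  `SeedSequence.spawn`.
* Per-species "top 20" style selections tie-break by species name.

## Limitations

* The fluctuation band's twin-replicate under-coverage described above.
* The paired t test's log₂ scale is undefined at zero abundance; such
  genes are sign-test-only, which loses power when one platform drops a
  gene entirely.
* IPF diagnostics flag non-convergence on pathological zero patterns
  but the G² is still reported from the last iterate.
* The OA trimming rule and fluctuation band are reconstructions; their
  parameters are exposed in `RunConfig` rather than hard-coded.
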