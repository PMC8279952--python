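# Methods

This note records the mathematical model, the statistical procedures, the
default parameters and their rationale, and the known limitations of the
implementation. Nothing here asserts an empirical result that is not computed
by the test suite or by `scripts/acceptance.py`.

## 1. CpG-dyad inheritance model (`dyadkin.kinetics`)

### States and transition law

A dyad state is the ordered pair of strand marks at one CpG:
UU, MU, UM, MM (plus strand first). One cell division is modelled as:

1. **Semiconservative dilution.** The daughter keeps one parental strand
   (probability ½ each); the other strand is newly synthesised and
   unmethylated.
2. **Mark loss.** A kept methylated strand loses its mark with probability λ
   (passive-independent demethylation; default 0).
3. **Parental-strand de novo.** A kept unmethylated strand gains a mark with
   probability δₚ (default 0).
4. **Nascent-strand methylation.** If the kept strand is methylated after
   steps 2–3, the nascent strand is methylated with the maintenance
   efficiency μ; otherwise with the nascent de novo rate δₙ.

The 4×4 transition matrix is assembled by enumerating kept strand × mark
outcome × nascent outcome (`transition_matrix`). Two exact consequences are
pinned by tests:

- With all rates zero, MM → ½MU + ½UM → ¼MU + ¼UM + ½UU (pure dilution).
- With δₚ = λ = 0, the per-strand marginal f obeys
  f′ = (f(1+μ) + (1−f)δₙ)/2, with fixed point f\* = δₙ/(1−μ+δₙ);
  μ = 0.9, δₙ = 0.05 gives f\* = 1/3 (`stationary_marginal` uses the closed
  form when it applies, otherwise iterates to 1e−12; the conserved corner
  μ = 1, δₙ = 0 has no unique fixed point and raises).

### Observation layer

Bisulfite errors act per strand: an unmethylated cytosine is read as
methylated with probability e (conversion failure) and a methylated one as
unmethylated with probability c (inappropriate conversion). The dyad-level
observation matrix is the per-strand 2×2 error matrix applied to both
strands (`observation_matrix`). Defaults e = c = 0.005, typical of
well-converted libraries; both are fixed (not fitted) by default because
with few timepoints they trade off against δₙ.

### Estimation

`fit_kinetics` maximises the multinomial log-likelihood of observed dyad
counts over a `TimeCourse` of (label, cumulative divisions, counts)
observations. The initial distribution p₀ is fixed to the first-timepoint
observed frequencies (the first observation must be at 0 divisions).
Optimisation is L-BFGS-B with multi-start (midpoint plus seeded uniform
starts; default 8) because the likelihood can be multimodal for short
courses. A single-timepoint course with both μ and δₙ free is rejected as
non-identifiable. Tests verify that the optimum is never beaten by a 41×41
grid and that truth parameters are recovered within ±0.03 on 50,000-dyad
courses in ≥90% of seeds.

**Divisions per passage (g = 6).** Cultures are passaged roughly every three
days and embryonic stem cells divide about every 12 hours, so one passage is
taken as six divisions. This scales the division axis of the time course;
fitted per-division rates scale inversely if g is changed, which is why g is
an explicit argument rather than a constant.

## 2. Pairwise comparison (`dyadkin.compare`)

Fixed non-overlapping windows (default 5 kb) are tiled from coordinate 0;
the last window may be short. Window/element means are unweighted means of
per-CpG beta values (not coverage-pooled) so deeply covered CpGs do not
dominate; a pooled mode exists as an option. A unit is *defined* only when
both methylomes yield a mean; undefined units are excluded from summary
denominators and counted. Gain/loss uses a strict inequality at the
threshold (default |Δ| > 0.05), with an inclusive `ge` comparator available.

## 3. DMR caller and control regions (`dyadkin.dmr`)

### Caller

Within each contig, windows of 5 consecutive CpGs covered ≥ min_cov (default
5) in both samples, step 1. Each window is tested with a pooled
two-proportion z-test; p-values are Benjamini–Hochberg adjusted across all
windows. Significant (q < 0.05) windows with pooled gain ≥ min_delta
(default 0.1) are merged when separated by ≤ 250 bp. A merged region is
reported when it contains ≥ 10 covered CpGs and its unweighted mean-beta
delta is ≥ min_delta. Only gains are called: the biological question is
re-methylation, and losses from a near-zero baseline are not meaningful.

The z-test is a deliberate simplification: with ≥5 CpGs × ≥5 reads the
normal approximation is adequate, it vectorises over hundreds of thousands
of windows, and the caller's guarantees (tested) are about recovering
planted blocks exactly, not about calibrated genome-wide inference.

### Control regions

For each DMR, `n_per_dmr` (default 1000) regions of identical length are
placed uniformly at random over the non-gap genome; placement weights each
gap-free segment by its number of valid start positions, so the distribution
is exactly uniform over all valid placements. Overlaps among CRs are allowed
(they are a null sample, not a partition). Each CR carries its source DMR's
label, which is what lets depth normalisation match CRs to their DMR.

### Enrichment test

Per region, the fraction of length overlapped by a (merged) feature class;
DMR fractions are compared to CR fractions with a one-sided Mann–Whitney
test (DMRs greater). Overlap-fraction vectors are heavily tied (many exact
zeros), and SciPy's exact method refuses ties, so for min(n, m) ≤ 8 the
p-value is computed by explicit enumeration of all C(n+m, n) midrank
assignments — tests pin it to an independent enumeration oracle and, on
tie-free data, to SciPy's exact method. Larger samples use the tie-corrected
normal approximation. The reported effect size is the common-language
U/(n·m).

## 4. Long-read cross-validation (`dyadkin.longread`)

**Deletion detection.** Candidate intervals are within-read alignment gaps.
An interval is called when ≥ 5 reads have a gap spanning it entirely and 0
reads have any aligned block inside it (both thresholds configurable);
calls strictly contained in a larger call are dropped. CpGs inside called
deletions are removed from methylomes before DMR calling (`mask_cpgs`,
half-open semantics).

**Region methylation.** Per CpG, beta = M calls / total calls pooled over
reads; a region mean averages covered CpGs and is undefined (NaN) below 10
covered CpGs — enough to keep a single miscalled site from defining a
region.

**High-confidence filter.** A DMR whose long-read delta (sample − baseline)
is *less than* 0.05 is excluded; exactly 0.05 is retained. DMRs with an
undefined mean are retained with an `uncovered` flag by default (the filter
only *excludes on evidence*); `uncovered="exclude"` gives the stricter
behavior. The three output sets are an exact partition of the input,
asserted at runtime and in tests.

**Depth normalisation.** Mean aligned-block depth over each DMR divided by
the mean depth over its own label-matched CRs; ratios near 1 indicate no
repeat-mapping bias, zero CR depth yields NaN rather than infinity.

## 5. Interaction-proteomics statistics (`dyadkin.proteomics`)

Missing log2 LFQ intensities are imputed per sample column from
Normal(mean − 1.8·sd, (0.3·sd)²) of the observed values — the standard
down-shift that encodes missing-not-at-random dropout near the detection
limit; observed cells are never altered, and columns with <3 observed values
fall back to whole-matrix moments with a warning.

Differential abundance uses an equal-variance two-sample t-test, and
significance is assigned by a SAM-style permutation FDR: the moderated
statistic d = Δmean/(pooled SE + s₀) with s₀ = 0.1 damps low-variance
artefacts; the null is built from distinct balanced relabelings of the
columns *excluding the identity labelling and its mirror* (both reproduce
the observed grouping exactly and would bias the estimated FDR upward); for
a candidate cutoff t the estimated FDR is the median permutation count of
|d| ≥ t over the observed count, and the largest rejection set with
estimated FDR ≤ q is reported. When no informative permutation exists
(or `n_perm=0`), the method falls back to Bonferroni on the plain t-test and
says so. Known property (tested as such): very large true effects inflate
the permuted null, making the procedure conservative rather than
anti-conservative.

## 6. Synthetic data (`dyadkin.simulate`)

One contig is partitioned into annotated features (IAPEz-int 5–7 kb,
IAP-LTR, ERV1, LINE, SINE, CGI, gene), intergenic spacers (Dirichlet-split)
and assembly gaps, in seeded random order. CpG counts per feature are
deterministic (round(length × class density); CGI density ≥5× intergenic)
with positions on the even grid so dyads never collide. WGBS draws Poisson
coverage and binomial methylated counts at p_obs = p_true(1−c) + (1−p_true)e;
zero-coverage CpGs are dropped as in real coverage files. Passage series use
the kinetics module as the single source of truth: per class the dyad
distribution starts at (1−f)UU + f·MM, evolves by the class's transition
matrix, and emits multinomial dyad counts (through the observation matrix)
and WGBS levels from its strand marginals. Long reads have lognormal lengths
(median 25 kb), blocks split around injected deletions, and per-CpG calls
with a symmetric call-error flip. LFQ matrices spike `effect_log2` into the
bait group and apply logistic intensity-dependent dropout.

Realism limits, by design: a single contig; no sequence (CpGs are abstract
positions); independent CpGs within a class (no spatial autocorrelation of
methylation); uniform read-start positions; no strand bias, PCR duplicates
or mapping error; dyad counts are class-pooled rather than per-molecule
spatial.

## 7. Conventions and numerics

- Coordinates are 0-based half-open internally; the Bismark coverage format
  (1-based inclusive) is converted only at the I/O boundary; BED is 0-based
  half-open. Writers emit a `# dyadkin v… config_hash=…` header.
- Interval arithmetic is cumulative-sum + binary-search based (no per-bp
  loops); overlap against a region set merges it first unless multiplicity
  is wanted (read depth).
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the acceptance script derives sub-seeds deterministically and keeps
  them below 2³¹.
- Multinomial log-pmf uses `gammaln`; impossible states (probability 0 with
  nonzero count) give −inf rather than NaN so the optimiser can reject them.
- Benjamini–Hochberg is the monotone step-up with clipping at 1.

## 8. Limitations

- The kinetics fit assumes a homogeneous dyad population per class; real
  elements mix fast and slow loci, which biases μ/δₙ toward their
  count-weighted compromise.
- The DMR caller's FDR is per-window, not per-region; region-level error
  control is inherited only approximately through merging.
- The exact rank test enumerates C(n+m, n) assignments and is practical only
  for min(n, m) ≤ 8; beyond that the tie-corrected approximation is used.
- `detect_deletions` is quadratic in the number of distinct gap intervals
  and intended for targeted structural checks, not genome-wide SV calling.
- The SAM permutation FDR needs enough columns for informative relabelings;
  tiny designs fall back to Bonferroni.
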