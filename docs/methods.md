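# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `haplocnv`. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from external
results.

## Synthetic cohorts

The generator (`simcohort`) exists because the method's target data —
biobank-scale phased haplotypes plus exome read counts — cannot ship with
code. It produces cohorts in which every downstream quantity has queryable
ground truth.

**Haplotype model.** Founder-mosaic copying rather than a coalescent: each of
the `2n` sample haplotypes copies a founder haplotype in tracts whose lengths
are geometric with mean `copy_tract_mean` sites (per-site switch probability
`1/copy_tract_mean`, memoryless). The founder id per (haplotype, site) — the
genealogy — is recorded, so IBD sharing is exact and queryable, which is what
the neighbor-pooling tests need. A value of `copy_tract_mean >= n_sites`
disables recombination entirely, giving verbatim founder copies (the
degenerate limit used by some tests). A linear genetic map (default 1 cM per
100 sites) converts match lengths to cM; the IBD thresholds of the caller can
be expressed in either unit. This model deliberately omits realistic LD,
mutation and gene conversion: tests on it demonstrate the machinery's
correctness given IBD structure, not performance on real human haplotypes.

**CNVs.** Events are attached to founder haplotypes over a bin interval. A
sample haplotype carries an event iff its genealogy equals the event's
founder over the whole interval; sample copy number per bin is
`2 + sum(carried changes)`. Overlapping events on one founder are rejected.

**Read counts.** `n(s,b) ~ NB(mean, size = nb_dispersion)` with
`mean = depth_mean * e(b) * lot(s,b) * g(s) * cn(s,b)/2`: per-bin log-normal
capture efficiency `e` (sd `capture_sd`), a per-bin multiplicative batch
effect applied to the first `lot_fraction` of samples (two reagent lots,
mirroring the two-lot structure of real exome cohorts), and a per-sample
log-normal coverage scale `g`. Defaults are the study conditions used
throughout: 30x diploid depth, NB size 10, `capture_sd = 0.3`,
`lot_effect_sd = 0.1`, `lot_fraction = 0.1`, 100-bp bins. A zero NB mean
yields a zero count, so homozygous deletions produce empty bins.

**Trios.** Parents are cohort samples taken pairwise; each child haplotype
is a recombined gamete of one parent (switch probability `1/copy_tract_mean`
per site), so Mendelian consistency holds by construction, and child copy
numbers derive from the composed genealogy. Note one subtlety the trio tests
rely on: a *single-site* copy-number locus transmits a parent's haplotype
value intact, giving the analytic mid-parent/child correlation `1/sqrt(2)`
for an additive noiseless trait; a multi-site event interval attenuates the
correlation because gametes recombining inside the interval break the
carried tract.

**PSVs.** At a collapsed repeat locus with diploid repeat count `k_tot` and
`k_psv` variant-bearing units, pileup totals are
`t ~ Poisson(depth * k_tot/2)` and variant reads `a ~ Binomial(t, k_psv/k_tot)`.

## Depth normalization

A bin passes QC when (a) mean coverage exceeds `min_cov = 5` in both lots,
(b) the lots' mean coverages agree within `|log2 ratio| <= 0.2`, (c) at least
half the aligned reads map with positive quality (`mappable_fraction >=
0.5`), and (d) the bin is *calibratable*: the cross-sample normalized depth
either has robust CV `<= 0.5` (rare-CNV regime) or clusters within 0.12 of
half-integer multiples of 0.5 for 90% of samples (discrete copy-number
regime). The CV ceiling is set just above the intrinsic NB sampling CV of a
diploid bin (`sqrt(1/mu + 1/phi)`, about 0.37 at 30x with size 10) so that
bins whose variance is dominated by sampling noise pass while bins carrying
common copy-number variance fail; it was chosen from this noise argument on
simulated cohorts.

Expected diploid depth `mu(s,b)` comes from a per-sample reference panel:
the `k = 20` same-lot samples with the highest Pearson correlation of
log1p fractional coverage (ties broken by sample id). The baseline is the
*median* of coverage-scaled reference counts per bin — median, not mean, for
robustness to CNV carriers inside the panel — rescaled by the target's
total-coverage factor. Because the median of a right-skewed NB sits 1–3%
below its mean, a final recalibration rescales `mu` so its sum over retained
bins equals the sample's observed total; this pins normalized depth
(`count/mu`) to 1.0 at diploid bins, which the calibration of Bayes factors
to absolute copy number requires. Reference-panel size trades robustness for
per-bin noise (`sd(mu)/mu ~ CV * 1.25 / sqrt(k)`); experiments in this
package use `k` of 20 for calling and up to 72 where tighter `mu` is needed.

NB dispersion is per sample, by method of moments on retained bins:
`Var(n) = mu + mu^2/phi` pooled gives
`phi = mean(mu^2) / (Var_hat − mean(mu))`, clipped to `[1, 1e6]`.
Overdispersion is declared only when the variance excess exceeds twice the
standard error of the pooled variance estimate; below that the sample is
treated as Poisson (upper clip). Region-specific structure enters through
`mu`; per-bin `phi` is left as an extension.

## PBWT haplotype matching

`build_pbwt` maintains, per site, the haplotype ordering by reversed prefix
and the divergence (match-start) array, in O(haplotypes x sites) — the
per-site update is vectorized as a segmented running maximum over the
divergence array. Matches are exact allele matches (no error model); their
length in sites or cM is the IBD proxy, longer sharing implying a more
recent common ancestor.

`neighbors_at` anchors at a site: divergence running-maxima give every
haplotype's backward match start in one pass, forward extensions are read
off the allele matrix, and candidates with spanning match length at or above
the threshold are ranked by length (ties by haplotype id), excluding the
target's own sample, capped at `max_neighbors`. A quadratic brute-force
matcher ships alongside as the validation oracle; on panels whose two
founders are complementary, allele identity coincides with genealogy
identity, making exact genealogy-truth checks possible (with many founders,
chance allele agreement past a breakpoint extends matches by a site or two,
so exact set equality against genealogy is only well-posed on that
construction).

## Rare CNV calling

**Emissions.** `BF(state) = NB(n; mu*c/2, phi) / NB(n; mu, phi)` with `c = 1`
(DEL) and `c = 3` (DUP); `BF(DIP) = 1` identically. These diploid-normalized
ratios equal full likelihoods up to a per-bin constant that cancels in
posteriors and Viterbi. The model is 3-state; a homozygous deletion (CN0) is
still captured by the DEL state, and an explicit CN0 evaluation floors the
mean at `0.05 * mu` to keep the likelihood proper. Numerically, the expected
per-bin log BF at 30x with size 10 is about +1.4 nats for a true
heterozygous deletion and −2.0 nats at a true diploid bin, which sets the
scale for all threshold choices below.

**Pooling.** For each bin of a target individual, up to ten neighbor
*samples* (both target haplotypes' neighbor lists merged, deduplicated by
sample keeping the longest match) contribute their own Bayes factors, each
only over bins inside its matched tract — outside the tract a neighbor's BF
is treated as 1, preventing off-tract noise pooling.

**HMM.** States DEL/DIP/DUP; per-bin entry probability `tau_enter = 1e-4`,
mean CNV length 10 bins (exit 0.1), no direct DEL<->DUP transition,
stationary start distribution. `tau_enter` and the length prior were tuned
on simulation, not taken from data. Forward–backward and Viterbi run in log
space; an exhaustive 3^L enumeration is the oracle on short tracks
(agreement to ~1e-15). Two boundary behaviors are worth knowing: with
exactly-neutral flanks (BF = 1) the MAP path legitimately extends a strong
CNV segment outward, because the stationary start and segment persistence
are cheaper than a mid-track entry; and trimming at a track end requires the
flanking evidence to outweigh the ~2.3-nat exit penalty. Real diploid bins
(~−2 nats) satisfy both, so segmentation is exact in practice.

**Calls.** Maximal Viterbi CNV runs with mean posterior >= 0.9 and positive
score become calls; score is the summed per-bin log10 combined BF. Calls are
recomputed at each IBD threshold in the ladder (defaults 10, 4, 2, 1 cM;
simulated cohorts use sub-cM ladders matched to their map length) and
compiled: same sample, same type, >= 50% reciprocal overlap merges to the
union interval with max score and full threshold provenance; residual
overlaps are unioned (same type) or resolved by score (cross type), so the
compiled set is non-overlapping per sample. Filtering removes samples with
more than 300 calls, calls in user-supplied mask regions, and calls below 2
log10 units of score.

**pLOF annotation.** Deletions overlapping any coding base are `pLOF_del`.
Duplications wholly containing a gene are `whole_gene_dup`; duplications with
both endpoints strictly inside one gene body that touch coding sequence are
`internal_dup_pLOF` — presumed tandem and reading-frame-disrupting, which is
the conservative reading for internal exonic duplications; duplications
straddling a single gene boundary are left as `other`.

## Common-dosage analysis

**Trio screen.** Per region, Pearson correlation of child versus mid-parent
normalized depth, one-sided p (r > 0), Bonferroni-retained at
`alpha = 0.05` across screened regions; cataloged CNV regions bypass the
screen. Zero-variance regions are reported untestable.

**Phase/denoise.** Initialization `v(h) = measurement/2`; update
`v(h) <- mean over cluster N(h) of (measurement(sample(h')) − v(partner(h')))`
with `N(h)` the IBD neighbors at the region's anchor site (nearest panel
site to the region midpoint) plus `h` itself; fixed haplotype-id update
order (Gauss–Seidel), `tol = 1e-6`, `max_iter = 50`. Haplotypes without
neighbors keep their running value. The scheme is a documented stand-in with
the same contract as more elaborate estimators: it converges in ~10 sweeps
on the two-class benchmark and roughly triples accuracy (RMSE 0.53 -> 0.17
at noise sd 0.5), but it carries a weakly damped antisymmetric mode — a
near-gauge freedom that shifts one haplotype class up and the other down
while preserving every diploid sum. Its residual noise scales with the
cluster-mean noise, so denoising clusters default to 30 neighbors (the
ten-neighbor cap belongs to the CNV HMM), and per-replicate class means
still wander by ~0.05; unbiasedness holds on average over replicates.

**Imputation.** A target haplotype takes the mean value of its measured IBD
neighbors; diploid value is the sum over the two haplotypes; targets with an
uncovered haplotype are missing with a reason.

**WES–WGS consistency.** Regions keep their heritable status only if WES and
WGS dosage correlate (`r >= 0.3`) over at least 50 shared samples — the
guard against capture-bias pseudo-heritability.

## PSV genotyping

Pileups from all paralog copies are summed onto collapsed coordinates
(minus-strand copies position-reversed); copies must be equal length.
`AF = a/t` with a Wilson 95% interval; genotypes below `t_min = 10` reads are
missing. PSV copy number is `AF * cn_tot` continuous, with the nearest
integer (clipped to `[0, round(cn_tot)]`) and the rounding residual reported
as a quality metric. Association should use the continuous value; the
integer is for interpretation. At 30x and `cn_tot = 4` the integer is
correct ~98% of the time.

## Association

Phenotypes are prepared per stratum: rank-based inverse normal transform
with offset `(r − 0.5)/n` (midranks for ties), OLS residualization on
covariates, re-standardization. Association is OLS with covariates — a
deliberate simplification: no mixed model, hence no relatedness or
population-structure modeling beyond covariates supplied by the caller
(principal components can be passed as covariates). Burden masks are carrier
unions per gene across variant classes, produced both with and without CNV
carriers so the gain from CNVs is measurable. The LD filter ranks local
variants linked to the target (`r^2 >= 0.01`) by marginal p, conditions the
target on up to 10 of them, and passes the association iff the conditional p
stays below 0.01 with at least half the marginal effect retained; a local
variant with `r^2 ~ 1` fails it outright. The validation-rate statistic
counts WGS depth directions over calls: `V = frac(correct) − frac(opposite)`,
with an ambiguity band `|estimate − 2| < 0.1`; because false positives fall
on either side by chance, V estimates the true-positive fraction regardless
of the band width.

## Study sizes and determinism

The replicated experiments use cohorts of 2,000 samples (pooling study; 50
replicates, one planted ~1% deletion, 30x), 5,000 bins (dispersion
recovery), 2,000 trios (heritability oracle), 704 trios x 1,000 null regions
(screen calibration), 500 samples (denoising), 5,000 samples (PSV), and
n = 50,000 with 100 replicates (effect-size coverage) — sizes at which every
targeted property is measurable with comfortable Monte-Carlo margins on a
single CPU in minutes. All randomness flows from explicit seeds
(`numpy.random.default_rng` with per-operation substreams), so reruns are
bit-identical; gzip outputs are written with zeroed timestamps for the same
reason.

## Known limitations

* IBD is exact allele matching: no genotyping-error tolerance, so a single
  mismatch truncates a match — acceptable on simulated panels, optimistic
  for real array data.
* The 3-state HMM folds CN0 into DEL and CN4+ into DUP; multi-allelic loci
  belong to the dosage pipeline instead.
* OLS association ignores relatedness; effect sizes at very rare variants
  inherit OLS small-count behavior.
* The founder-mosaic simulator underrepresents real LD structure; passing
  tests demonstrate algorithmic correctness and calibration under the stated
  model, not end-to-end performance on real cohorts.
* The denoiser's antisymmetric mode (above) limits per-replicate class-mean
  accuracy; diploid sums are unaffected.
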