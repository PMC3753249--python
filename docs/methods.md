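# Methods

## Scope and data model

`cnvscreen` implements a complete CNV case–control analysis for
SNP-array cohorts: signal adjustment, segmental copy-number calling,
post-calling QC, locus definition, Fisher-exact association, burden
statistics, and signal-level validation.  All stages share one marker
scaffold (`MarkerMap`: name, chromosome, 1-based position, population
B-allele frequency, GC fraction) to which every sample's LRR/BAF vectors
are aligned.

Coordinates are 1-based inclusive throughout; BED export converts to
0-based half-open.  A call's length is defined as `end − start` bp.
This is deliberately the convention of the text call dialect the
pipeline reads and writes (`.rawcnv`), in which segment boundaries are
the positions of the first and last genotyped markers of the run, and
printed segment lengths equal the coordinate difference rather than the
inclusive span.  Strand is ignored; the genome build is treated as
opaque coordinates.

## Emission model

LRR at a marker carried at copy number cn is modelled as
Normal(μ_cn, σ_cn) with defaults

| cn | μ (LRR) | σ |
|----|---------|------|
| 0  | −3.5    | 1.0  |
| 1  | −0.66   | 0.30 |
| 2  | 0.0     | 0.30 |
| 3  | +0.40   | 0.30 |
| 4  | +0.68   | 0.30 |

These are the canonical per-state values used by HMM-based array CNV
callers; they are synthetic stand-ins, not estimates from any particular
dataset, and are configurable.  BAF is a binomial genotype mixture: a
sample with cn copies at a marker with population B-allele frequency p
holds b ~ Binomial(cn, p) B alleles and emits BAF ~ Normal(b/cn, σ_BAF)
clipped to [0, 1] (σ_BAF = 0.03); cn = 0 emits uniform noise.  Per-sample
GC waviness adds w_s·(gc − mean gc) to LRR at every marker, with
w_s ~ Normal(0, 0.3).  The waviness scale was chosen so that 2σ samples
shift by ~±0.1 LRR across the GC range, a moderate real-array regime.

The synthetic cohort generator draws marker positions with uniform
jitter around a mean spacing (default 4 kb, emulating a ~733K genome-wide
array), PFB uniform on [0.05, 0.95], and GC as a smooth superposition of
Mb-scale sinusoids rescaled to [0.3, 0.7].  Carrier status per sample and
planted locus is Bernoulli with the group's carrier frequency; carriers
of a het loss, hom loss, or gain receive cn 1, 0, or 3 over the locus.
Each sample draws from a substream derived deterministically from
(seed, sample index), so enlarging a cohort never perturbs existing
samples.  The default cohort is 115 cases / 106 controls.

What the generator does *not* emulate: linkage disequilibrium, genotype
miscalls, batch/plate effects beyond GC waviness, intensity saturation,
mosaicism, and the X chromosome.  Passing tests therefore demonstrate
correctness of the statistical machinery under a clean, well-specified
noise model — not calling performance on real arrays, where boundary
error and false-call rates are higher.

## GC adjustment

Per sample, LRR is regressed by OLS on window-averaged GC (window
1 Mb, centred); the returned signal is the residual re-centred at the
sample's mean (equivalently, residual plus intercept when the regressor
is centred).  A degenerate (constant) regressor leaves the signal
untouched.  This removes the first-order waviness the generator plants
and is the same correction idea used before calling on real arrays.

## Caller

A five-state hidden-Markov chain over cn 0–4 per chromosome, decoded by
Viterbi.  Transitions are uniform off-diagonal with stay probability
p_stay = 0.999 (expected diploid segment ≈ 1,000 markers); the initial
distribution is the diploid state's transition row.  Emission
log-likelihood is the LRR Gaussian plus the log BAF mixture density for
the state (boundary clipping mass ignored — adequate for state
discrimination).  Ties in Viterbi resolve to the lower copy number,
making decoding fully deterministic.  Maximal non-diploid runs spanning
≥ 3 markers become calls; confidence is the emission log-likelihood
ratio of the called state against diploid summed over the run.  Missing
markers are skipped; a sample whose observed LRR is > 5% non-finite is
rejected.

The copy-neutral LOH state of full-featured callers is omitted (no
analysis step here needs it), and there is no X-chromosome or
family-based handling.

## QC

Fixed filter order: (1) drop whole samples with more than
`max_calls_per_sample` (default 100) calls — excessive call counts
signal residual waviness; (2) drop calls with confidence < 10, unknown
confidence counting as below threshold.  The threshold is inclusive:
conf = 10.0 passes.  Samples dropped here are also removed from the
group denominators used downstream.  Filtering is idempotent and never
modifies calls.

## Locus definition

Gains (cn > 2) and losses (cn < 2) cluster separately per chromosome.
A locus is the common intersected core of its member calls: the longest
unassigned call seeds a locus; any unassigned call overlapping the
current core by ≥ `min_intersection` (default 1 kb) is admitted, the
core shrinking to the running intersection; when no call qualifies the
locus is emitted and the next seed chosen.  Admission scans in a
deterministic order (longest first, then leftmost, then sample id), and
equal-length seeds break ties by smallest (chromosome, start).  By
construction every member contains the final core, so any two members
overlap by at least the core length.  Chaining of pairwise-overlapping
calls with no common core is resolved greedily by this rule; on
jittered-boundary data (calls scattered around shared true loci) the
greedy partition attains the exhaustive-search minimum number of loci,
which is verified in the test suite on all call sets of ≤ 6 intervals.

Losses containing both cn = 1 and cn = 0 members form one het-loss locus
with per-zygosity counts recorded; a locus is homozygous only when every
member is cn = 0.  Carrier frequency uses post-QC group sizes; a locus
is common when either group's frequency exceeds 5%.  Gene annotation is
an optional any-overlap join against a user-supplied BED; novelty is an
input flag, never computed.

## Association and burden

The association statistic is the one-sided Fisher exact probability,
computed by direct summation of hypergeometric point probabilities in
log-factorial arithmetic (no normal approximation): with N samples, K
carriers, and a carriers among n_case cases, p = P(X ≥ a) when cases
are at least as enriched as controls, else P(X ≤ a).  The one-sided
convention is the default because it reproduces published
contingency-table p-values in this study design exactly; a two-sided
option (sum of outcomes no more probable than observed) is available.
Significance is claimed at p < 0.05 for common loci only; rare loci are
reported without significance claims.  No multiplicity correction is
applied by default (a Benjamini–Hochberg option exists).

Burden statistics reproduce the standard cohort summary: per-individual
call counts (zero-call individuals included), per-call lengths in kb
(1 kb = 1,000 bp, `end − start`), marker counts, and per-type splits
(duplication / het deletion / hom deletion), each compared between
groups by the two-tailed Mann–Whitney U test — the exact null
distribution when both groups have ≤ 50 observations, the tie-corrected
normal approximation otherwise.

## LRR validation

For a candidate locus, group A is all carriers (cases and controls
pooled — only carrier status matters, and the report is invariant to
relabeling carriers' cohorts) and group B is non-carrier controls.
Every in-locus marker and `flank_snps` = 2 markers on each side are
tested for a mean LRR difference by a two-sample t-test and a two-tailed
Mann–Whitney U test at α = 5×10⁻⁴ per SNP.  Verdict rule: validated iff
≥ 80% of in-locus SNPs are significant by *both* tests, no flanking SNP
is significant (`max_flank_fraction` = 0), and every significant
in-locus SNP shifts in the direction the copy-number change implies.
Fewer than two usable samples in either group yields verdict
`undeterminable`.

Two numerical choices here were genuinely open and deserve their
rationale:

* **Pooled-variance t by default.**  The emission model gives equal LRR
  variance across copy-number states, so the pooled Student t is exact
  for the data this package simulates.  With ~10 carriers, Welch's
  approximation leaves so few degrees of freedom that p < 5×10⁻⁴ is
  nearly unreachable even for a true deletion of canonical effect size
  (−0.66 LRR), defeating the purpose of validation; Welch remains
  available (`equal_var=False`) for data with genuinely unequal spreads.
* **80% in-locus fraction.**  Per-SNP power at α = 5×10⁻⁴ with ~10
  carriers is ≈ 0.9 for either test; demanding every SNP pass would
  reject a third of true CNVs through single-SNP sampling dips, while a
  null locus has essentially zero probability of clearing 80% of SNPs
  at this α.  Both knobs are configurable.

* **Flank placement.**  Flanking markers are taken outside the *union*
  of member-call intervals, not merely outside the intersected core:
  markers between core and union lie inside some carriers' calls
  (boundary uncertainty) and belong to neither a clean inside nor a
  clean outside set, so they are excluded from the verdict.

## Pipeline, determinism, problem sizes

The `run` command executes simulate (optional) → read → GC-adjust →
call (skipped when a `.rawcnv` is supplied) → QC → loci → association +
burden → validation of significant common loci, writing TSV/BED/JSON
outputs whose headers carry the seed and a config hash.  One seed
governs every draw; identical config and seed give byte-identical
outputs, and re-running from an intermediate `.rawcnv` reproduces the
end-to-end tables.

The reference synthetic experiments (`cnvscreen.experiments`) use a
2 Mb single-chromosome map at 4 kb spacing (~500 markers) with a 41 kb
planted heterozygous deletion carried by 1.75% of 114 cases and 10.38%
of 106 controls — the size class and carrier-frequency regime of a top
protective locus in a small cohort.  These sizes keep a 200-replicate
end-to-end benchmark to a few minutes on one core while leaving ~490
diploid markers per sample to exercise the false-call path.  Note the
intrinsic ceiling of this design: with perfect calling, the binomial
carrier draws alone yield a significant protective Fisher test in only
≈ 83% of cohorts, so end-to-end recovery rates just above 80% indicate
near-lossless downstream stages, not a weak caller.

## Known limitations

* The caller is a clean-room stand-in: its emission parameters are not
  trained, and no claim is made that its boundary accuracy matches
  production callers on real intensity data.
* Validation assumes carriers share one event; overlapping distinct
  events at one locus dilute the contrast.
* The exact Mann–Whitney null presumes exchangeability and handles ties
  by midranks without a tie-adjusted exact distribution (groups ≤ 50).
* Locus definition guarantees all-member core overlap but resolves
  ambiguous chaining greedily; pathological nestings (one call spanning
  two distant loci) can split differently than a global optimum.
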