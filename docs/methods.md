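# Methods

## The analysis model

All computation starts from per-site, per-sample read counts at biallelic SNV
positions relative to a reference genome, for one donor sampled across
storage time points. The day-0 sample of each (matrix, condition) series is
taken as the donor's true genotype; every later difference is attributed to
storage. This rests on three assumptions: the donor's germline does not
change over weeks; the sequencing runs are exchangeable apart from storage
effects; and read counts at a site are binomial draws from the template
allele fraction.

**PRV.** The percentage of reads of the variant at an observation with
`alt` alternative reads and `n` total reads (all detected alleles, so reads
supporting neither recorded allele inflate the denominator but never the
numerator) is `PRV = 100·alt/n`. PRV is undefined at zero coverage; callers
must branch on the FAILED state first.

**Genotype allocation.** The literal mapping (0 % → 0/0, 100 % → 1/1,
otherwise 0/1) would let a single error read produce a heterozygous call, so
genotypes are allocated with a band caller: FAILED below the coverage floor
(default 1 read, i.e. FAILED means exactly "no coverage"); 0/0 when
PRV < 5 % *or* fewer than 2 alt reads; 1/1 when PRV > 95 % *and* fewer than
2 ref reads (the symmetric guard); 0/1 otherwise. All four thresholds are in
`CallingConfig`. With the band edges pushed to 0/100 and the read guard at
one, the caller provably reduces to the literal rule (property-tested).

**Trajectory classes.** Within one series, a site's ordered calls map to one
label: coverage loss at any later time point pre-empts everything
(FAILED_ONSET, tabulated separately from genotype changes); the exact
three-step patterns 0/0→0/1→1/1 and 1/1→0/1→0/0 are the homozygote
switches; all remaining trajectories are labelled by their (day-0, last)
pair — equal pairs STABLE, 0/0→0/1 GAIN_HET, 1/1→0/1 LOSS_HET, 0/1→hom
RESOLVE_TO_HOM — and anything else (e.g. a hom-to-opposite-hom jump without
an observed het step) is OTHER. Sites FAILED at day 0 have no truth
reference; they are excluded from classification and surfaced as a QC count.
The classifier is verified against brute-force enumeration of all 64 call
triples.

**Changed sites.** A site changed if, in any series, a stored sample's call
differs from the day-0 call, or its PRV moved by more than a tolerance
(default 5 points) *and* beyond what binomial sampling at the observed
depths explains (two-proportion z-score > 4.9). The z-gate matters: at 30×
depth a heterozygous site's PRV wobbles by ~10 points between undamaged
aliquots, and counting that wobble as change would make even a damage-free
experiment appear full of changes. With z > 4.9 the family-wise false-flag
expectation stays well below one across a 10⁵-site study.

**Spectrum.** Each site's (ref, alt) pair maps to type 1 transition
(A>G, T>C), type 2 transition (G>A, C>T — the deamination signature),
transversion, or spanning deletion (`*`). Counting is on the reference
strand with no reverse-complement folding, so G>A and C>T are reported
separately; complementing all pairs swaps those two counts and preserves
class totals (property-tested). Spanning deletions are excluded from
substitution spectra and counted in their own category.

**Gradual drift.** "Gradual" PRV change is formalized as tolerance-bounded
monotonicity: every step may backslide at most `per_step_tolerance`
(default 2 points, absorbing binomial noise at ~30×) and the total change
must reach `min_total_delta` (default 20 points). The delta threshold is the
operational proxy for an "ideally distributed" profile — no sharper
criterion separates ideal from merely monotone positions, so it is an
explicit, configurable knob rather than a hidden heuristic.

**Marker selection.** Candidate TsD markers pass, in order: (1) the spectrum
gate — (ref, alt) in the allowed set, default {G>A, C>T}; (2) day-0
homozygosity in every series (disable with a flag; heterozygous positions
can still be informative but complicate the drift direction); (3) the
read-count threshold — every sample in every series must have ≥ 10 reads at
the site, inclusive. The threshold is interpreted as minimum *total* depth;
a configurable alternative thresholds variant reads instead
(`depth_mode="alt"`). Survivors become candidates when the gradual-drift
test passes with the *same direction* in every required series — identical
direction, not identical magnitude, since damage kinetics differ by
condition while the sign should not. Attrition is reported per gate and is
conservative by construction.

**Statistics.** Mann–Whitney U (midrank ties; exact enumeration when both
samples are ≤ 25 and tie-free, tie-corrected normal approximation
otherwise), one-way ANOVA computed from explicit sums of squares (zero
within- and between-variance raises instead of returning NaN), and Pearson
chi-square on count tables without continuity correction by default. The
distributional tails come from scipy. PRVs are pooled across positions per
series for the ANOVA/rank tests (per-position testing at three time points
is underpowered); the spanning-deletion chi-square contrasts
deletion-vs-substitution changed-site counts between matrices. All reported
p-values are unadjusted; a Benjamini–Hochberg helper exists but is applied
nowhere by default.

## The simulator

The generator emulates the study's data-generating process forward:

1. **Truth.** `n_sites` biallelic sites with exact role quotas — null
   (background only), damage-prone (deamination at the base rate), planted
   marker (elevated rate → gradual drift), planted switch (rate high enough
   to saturate within the window). Planted roles get C>T/G>A alleles and a
   0/0 day-0 genotype; null alleles are uniform over the 12 substitutions
   with a small share of spanning-deletion (`*`) sites. Genotypes are drawn
   from configurable day-0 frequencies (default 70/20/10 % for 0/0, 0/1,
   1/1).
2. **Damage.** Deamination acts on the per-read conversion probability:
   after `t` days at rate λ (times the humid multiplier `m`), a fraction
   `d(t) = 1 − exp(−λmt)` of reference-bearing templates reads as alt, so
   the template alt fraction is `f = g + (1−g)·d(t)` for true alt fraction
   `g ∈ {0, ½, 1}`. Damage never edits the genotype state directly — partial
   PRV drift and (at high rates) full homozygote switches both emerge from
   the same mechanism.
3. **Reads.** Depth is Poisson with mean `30·exp(−λ_c·m·t)`. Coverage decay
   uses a two-class fragility mixture: most sites decay slowly
   (0.002/day) while a small depurination-prone fraction (2 %) decays fast
   (0.05/day) — a single site-independent rate cannot both preserve ≥ 10×
   depth at most sites and produce a visible zero-coverage population, and
   heterogeneous fragility is also the more realistic picture of abasic-site
   accumulation. Given depth, reads are multinomial with
   `p_alt = f(1−e) + (1−f)e/3` and `p_other = 2e/3` for per-read error rate
   `e`.
4. **Randomness.** One master seed; substreams are derived per
   (series, time point) with stable spawn keys, so adding series or time
   points does not perturb draws elsewhere.

### Default rates and why

| parameter | default | rationale |
|---|---|---|
| `deam_rate` | 0.005 /day | conversion 10 % at day 22, 37 % at day 92: clear het-ward drift of 0/0 sites within the window |
| `marker_deam_rate` | 0.01 /day | dry-series PRV ≈ 0 → 20 → 60: the gradual profile a medium-term TsD marker should show |
| `switch_deam_rate` | 0.05 /day | saturates (d ≈ 0.99 dry, day 92): full 0/0→0/1→1/1 switch inside the window |
| `cov_decay_rate` | 0.002 /day | normal sites keep ≳ 20× at day 92 humid, so the 10-read gate rarely censors them |
| `fragile_decay_rate` / `fragile_fraction` | 0.05 /day, 2 % | the fragile class reaches near-certain zero coverage by day 92 humid, ~70 % dry: failed calls grow with time and humidity |
| `humid_multiplier` | 1.5 | humid storage accelerates every hydrolytic process; 1.5 separates humid from dry failed-call counts without collapsing humid day-22 switch sites past the het band |
| `seq_error_rate` | 0.001 /read | short-read platform scale; with the ≥ 2-read guard it almost never flips a call at 30× |
| `spandel_rate` | 0.002 /day | spanning-deletion evidence accumulates slowly relative to deamination |
| `saliva_prestorage_days` | 0 (off) | optional: saliva collected from the oral cavity may carry pre-damaged cell-free DNA; enabling adds effective storage time to saliva series |

These rates are the package's own choices: no quantitative damage rates are
available for this setting, so they were fixed once to reproduce the
qualitative directions the analysis is built to detect (type-2-dominated
spectra, failed-call growth stronger under humidity, gradual marker drift,
within-window switches) and are all exposed in `DamageModel`.

### What the simulator does not model

Read-level artifacts (no FASTQ, alignment, or mapping bias), fragment-length
physics, PCR duplicates, contamination or non-human background, position-
within-read damage profiles, and linkage between sites (every site is
independent). Passing recovery tests on this generator therefore shows the
*analysis logic* is sound under the assumed statistical structure — it does
not validate behavior against alignment artifacts or cross-donor variation,
which need real multi-donor data.

## Numerical and degenerate-input choices

- Zero-coverage observations are stored explicitly as (0, 0, 0) rows, so
  failed-call counting never re-touches the input files.
- Multi-allelic VCF records decompose into one biallelic record per alt;
  depth on remaining alts becomes `other_reads`, conserving totals exactly.
  Symbolic alleles other than `*` are skipped and counted.
- PRV at exactly the band edge: 5 % calls 0/0 is false (`<` is strict), 95 %
  calls 0/1 (`>` is strict); the 10-read filter threshold is inclusive.
- The rate estimator `estimate_deam_rate` inverts the conversion curve at
  each stored time point and averages; it errors on saturated (PRV ≥ 100 %)
  means and ignores NaN (failed) observations per column. Sequencing error
  biases it upward by about `e/3` on the conversion scale — negligible
  against its 15 % accuracy contract at the default design size.
- All report tables are assembled in memory before anything is written, so a
  failing stage leaves no partial output; TSVs are LF, fixed column order,
  genomically sorted — reruns are byte-identical.

## Problem sizes used in the checks

Validation runs use 20 000 sites for end-to-end recovery (600 planted
markers, 400 switches), 100 000 for the spectrum share, and 5 000
single-series damage-prone sites for rate recovery — sizes at which binomial
noise on the tested aggregates is far below the asserted margins while a
full run stays in seconds.

## Known limitations

- The PRV-band caller is a deliberate, deterministic substitute for a
  likelihood-based joint caller; its thresholds are transparent but not
  calibrated to any specific upstream pipeline.
- "Gradual" is a two-knob heuristic; with only three time points, no test
  can distinguish exponential from linear drift.
- Statistics pool positions within a series, treating sites as independent
  observations; true site-to-site correlation (shared fragments, regional
  coverage) would shrink effective sample sizes.
- The package selects candidate markers; estimating TsD from a marker panel
  (regression/prediction) is out of scope.
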