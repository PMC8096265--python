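# Methods

## Screen model and scoring chain

The screen scored here couples an shRNA library to a silencing reporter:
cells carry one guide each, and a guide against a gene required for
silencing leaves the reporter active ("escape"). Sorting splits cells into
a reporter-positive gate (default fraction 0.07, the midpoint of the 6–8%
sorting window) and a reporter-negative gate (0.775, midpoint of 75–80%),
and each sorted population is sequenced.

Scoring runs: per-lane normalisation → per-replicate pos/neg ratio with a
depletion floor of 1e-3 (zero numerator count) and cap of 1e3 (zero
denominator; symmetric choice, logged) → average enrichment score (AES,
geometric mean across replicates) → gene score (sum of AES over guides,
reported as natural log) → significance (Poisson per guide × replicate,
Fisher combination, Bonferroni over scored genes).

Choices made where the design was open:

- **Gene score mode.** `sum` is the default; `mean` is a switch. The two
  differ by ln(n_guides) on the log scale and can reorder genes when guide
  counts differ. Under `mean` a null screen centres log gene scores on 0,
  which is the natural scale for a ranking plot.
- **Poisson reference.** λ for guide *i* is its negative-population
  frequency times the positive lane total — the minimal enrichment test
  against the matched sorted reference. Zero reference counts floor λ at
  0.5 so P stays positive. The test is one-sided (enrichment), since the
  screen direction of interest is persistence of the reporter.
- **Gene-level combination.** All guide × replicate P-values of a gene
  enter one Fisher step (k = n_guides × n_replicates). A two-stage variant
  (per-guide combination, then across guides) yields a valid χ² as well;
  the pooled form is used throughout.
- **Bonferroni m** is the number of genes actually scored; controls are
  excluded from gene scoring and reported separately.
- P-values are clipped below at 1e-300 so log-scale summaries stay finite;
  values at the clip are reporting floors, not estimates.

## Calibration of the Poisson/Fisher statistic

The Poisson test treats λ as known, but λ is estimated from the negative
population of the same replicate: under a null screen the statistic
pos_i − λ̂_i has variance ≈ 2λ rather than λ, so per-test P-values are
anti-conservative even with unlimited sorted cells. Finite cell sampling
in the narrow positive gate (order 10²–10³ cells per guide at realistic
scales) adds further overdispersion that read depth cannot remove. Fisher
combination amplifies the small-P excess. Consequently null combined gene
P-values are **not** uniform under this simulator — a Kolmogorov–Smirnov
check against uniformity fails clearly (KS ≈ 0.4 in the infinite-cell
limit, worse with realistic cell numbers), and more than 1% of null genes
can reach Bonferroni significance. A control experiment with the true λ
(oracle rate) is calibrated, isolating the cause as reference-rate
estimation plus cell sampling, not the implementation. The test suite
contains this check at desk scale; it documents expected behaviour of this
class of screen statistic (the reason dedicated screen tools model
overdispersion explicitly). Ranking by log gene score is unaffected: the
planted-hit recovery checks pass with wide margins, and the screen's hit
calls should be read as a ranking with nominal, not exact, error control.

## Synthetic screen generator

What it emulates: uniform single-copy guide assignment, Bernoulli escape
per cell (hit genes' guides escape with probability 0.9, background 0.05
by default; controls are neutral), a latent reporter value (escapers
1 + ε, silenced ε, ε ~ N(0, 0.1)) that makes gates meaningful without
modelling fluorescence physics, disjoint top/bottom gates, and multinomial
read sampling at fixed depth per lane (no PCR bias — the simplest model
under which a Poisson count statistic is a reasonable approximation).

What it does not emulate: retroviral copy-number variation, growth/dropout
over the induction period, sort impurity, sequencing error. Passing tests
therefore demonstrate correctness of the scoring arithmetic and ranking
behaviour under idealised noise, not robustness to those real-data
artefacts.

Defaults are the reference study conditions: 1010 genes at 4–6 guides per
gene totalling 5451 target shRNAs plus 8 controls, 5 replicates, 3×10⁶
cells per replicate, 10⁷ reads per sample (≈2000 reads/guide). Property
and acceptance checks run a scaled-down 200-gene screen (5×10⁵ cells,
2×10⁶ reads per sample — the same per-guide coverage), the package's
standard desk-scale configuration. FASTQ emission writes 150-nt reads
with the guide at offset 30, flanked by fixed 8-nt vector anchors so that
offset-scan matching is exercised realistically; filler bases are uniform
random. Counting is exact 22-mer matching (no mismatch tolerance; guides
are unique at 22 nt), leftmost window wins in scan mode, and no read
quality filter is applied.

## Binding fit

Single-site equilibrium, Signal(c) = BL + F·c/(c + K_D), fitted by
box-constrained least squares (K_D > 0; F and BL free in sign, since
anisotropy may decrease). Ligand depletion is ignored (free ≈ total
protein), matching the total-concentration form of the model.
Initialisation: BL₀ = min signal, F₀ = signal span, K_D,0 = concentration
at half-rise by interpolation — robust for monotone saturation curves.
Standard errors come from the Jacobian covariance ("curvature") or a
bootstrap over replicates (over points when only one replicate exists);
the bootstrap is the more honest choice when replicate-level systematic
differences dominate. Non-convergence returns a flagged result with
diagnostics rather than raising. When K̂_D > 5× the highest tested
concentration the estimate is reported as a lower bound ("K_D > max
concentration"), the usual convention for weak binders whose saturation
was never approached. Buffer-only controls are subtracted pointwise with
linear interpolation between control concentrations.

## qPCR relative quantification

Enrichment = E^(adjusted input Cq − IP Cq) with E the amplification
efficiency (default 2, perfect doubling; configurable — no efficiency
calibration is modelled) and the input Cq shifted by log_E(1/input
fraction) (10% input → 3.32 cycles). Spike-in normalisation is a ratio of
ratios: the target's percent input divided by the spike amplicon's percent
input, cancelling IP-efficiency factors shared between target and spike.
IgG measurements are carried through for reporting but never subtracted.
In the Cq table, spike-in rows use role `spike_in` with the `target` field
naming the compartment (IP or input) of the spike amplicon, since the
spike is measured in both materials of every sample.

Treated/control scaling is two-step: divide each replicate's values by
that replicate's mean, then divide everything by the mean of the control
condition, leaving the control mean exactly 1. Significance uses a
pooled-variance unpaired t-test, one-tailed in the direction of the
observed difference (equal means → P = 0.5), with star annotation at
P ≤ 0.05 / 0.01 / 0.001 / 0.0001.

The Cq generator plants known fold enrichments on the log-efficiency
scale (default pulldown 5% of input, IgG 0.1%, spike pulldown constant
across samples) with independent Gaussian cycle noise per measurement, so
the noise-free chain returns the planted folds exactly; with noise the
recovery is unbiased on the Cq (log) scale, i.e. geometric-mean unbiased
for the folds.

## Numerical notes and limitations

- All generators are bit-reproducible under their seed (one
  `numpy.random.Generator` per call, sequential draws).
- Count matrices are validated as non-negative integers; lanes with zero
  matched reads raise an error naming the sample.
- The enrichment floor/cap interact with monotonicity at the boundary: a
  guide moving from 0 to 1 positive read can drop below the 1e-3 floor
  value when its negative-population share is large; away from the
  boundary AES is monotone in the positive count.
- Ties in gene ranking break by smaller combined P, then lexicographic
  gene id (stable sort), so output order is deterministic.
- The pipeline writes all intermediates, the echoed configuration and a
  log; identical inputs and configuration give byte-identical outputs.
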