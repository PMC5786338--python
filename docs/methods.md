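# Methods

## The translation model

Translation on a single transcript is modelled as a continuous-time
Markov jump process on a 1-based codon lattice of length L (position 1 =
start codon, position L = stop codon). A ribosome is identified with its
A-site position; its 30-nt (10-codon) footprint covers codons
[i−5, i+4], and positions below 1 impose no constraint at initiation.

* **Initiation** places an A-site on codon 2 at exponential rate α
  (units 1/s), allowed only while the 5′-most A-site is at position
  ≥ 2+ℓ (ℓ = footprint = 10 codons).
* **Elongation** moves an A-site from i to i+1 at rate λ_i, allowed only
  if the next A-site downstream is more than ℓ codons away (so steady
  states have inter-A-site gaps ≥ ℓ).
* **Termination** removes the ribosome at position L at rate λ_L; the
  protein production flux J is the termination count divided by elapsed
  simulated time.
* **Drop-off** (optional): every completed hop is followed by unbinding
  with probability r, independently per event.

Two ribosomes with inter-A-site distance ≤ 12 codons (free gap ≤ 2) are
*closely stacked*; a detection scenario assigns each stacked ribosome an
independent probability (1, 0.5 or 0) of appearing in the footprint
library, while isolated ribosomes are always detected.

## Simulation

The simulator is a next-reaction event loop (numba-compiled): every
ribosome carries one pending exponential event time; a blocked
ribosome's clock is suspended and redrawn when the site ahead opens,
which is exact by memorylessness. Defaults: 10⁴ burn-in reaction events,
3×10⁴ snapshots, one snapshot per ~50 reaction events.

Snapshots are taken on a fixed **time** grid (spacing = 50 × the mean
inter-event time measured during burn-in), not at event boundaries.
States sampled at event boundaries follow the jump-chain law, which
overweights configurations with high total exit rate; on small systems
this produces occupancy errors far outside sampling noise, while
time-grid sampling agrees with the exact stationary solution (see
below). Dwell times and flux come from an exact event log (entry/exit
times per position), so observed rates (1/mean dwell, including blocked
time) are unbiased; only fully observed dwells after burn-in are
counted. Positions never visited are reported as missing, not zero.

An exact oracle (`exact_steady_state`) enumerates all admissible A-site
configurations (guarded at 10⁵ states), builds the sparse generator and
solves the stationary distribution directly. Property tests hold the
simulator to agreement with this oracle within batch-means standard
errors on randomized small models.

## Inference

Given a detected footprint profile p(i) and a target detected density
(TE divided by the calibration constant c, estimated by a through-origin
fit of TE against polysome densities below 1 ribosome/100 codons):

1. **Naive rates.** λ_i ∝ 1/p(i), rescaled so the mean finite rate is 10
   (arbitrary pre-normalization units); zero-count sites are capped at
   λ_max = 50. This inversion is exact without interference because
   occupancy is then flux × dwell = J/λ_i. Codon position 1 is
   structurally unobservable (the A-site enters at codon 2) and always
   receives the cap.
2. **Initiation search.** The simulated detected density rises with α
   and then *falls* once jamming stacks (and thus censors) most
   ribosomes, so the search first walks up the ascending branch in
   geometric steps and then bisects inside the bracket (relative
   tolerance 2%), using a fixed simulation seed at every evaluation
   (common random numbers). A target above the detected-density peak is
   reported as non-convergent.
3. **Error-site correction.** Both profiles are normalized to sum 1;
   positions where |sim − exp| exceeds 0.3 × the mean normalized density
   are error sites. Starting from the 5′-most site, α and the λ's within
   ±2 codons are jointly optimized by bounded Nelder–Mead on log rates
   (α constrained within ×3 of its fitted value; λ within
   [0.01, λ_max]), warm-started by rescaling the site's rate by the
   local profile ratio; the objective is the summed squared profile
   difference, evaluated on a coarser common-random-number simulation
   (1.2×10⁴ snapshots) than the final detection pass. Accepted
   corrections trigger re-detection strictly downstream; a
   non-improving site is kept at its best value and flagged unresolved.
   Because the profile shape constrains α only weakly, a final
   initiation-rate re-fit restores the TE density constraint whenever
   any correction was accepted.
4. **Normalization.** The exclusion process is distribution-invariant
   under joint scaling of α and all λ (time rescales), so one simulation
   measures the mean observed speed over codons [150, L] — defined as
   the number of visited positions divided by their summed mean dwell
   times — and all rates are multiplied by k = 5.6 / measured speed.
   Genes must exceed 150 codons (in practice the >200-codon gene filter
   applies) so the 5′ ramp does not bias the calibration region.

For the inference objective the simulated detected profile is the
*expectation* of the one-footprint-per-snapshot sampling scheme given
the snapshots (each detected ribosome weighted 1/n_detected): same mean
as the literal resampling, strictly less variance, and deterministic for
detection probabilities 0 and 1. The literal sampling scheme is kept in
`sample_profile` and used by the data generator.

## Synthetic data

The generator emulates the statistical structure of flash-freeze yeast
ribosome profiling:

* **Codon base rates** follow the empirical mean-elongation-rate
  grouping: 4 codons at 4–6 codons/s, 13 at 6–8, 13 at 8–10, 16 at
  10–12, 15 above 12, with usage weights proportional to the observed
  per-codon appearance frequencies per group (0.25/0.9/1.6/1.9/2.25%),
  i.e. fast codons are used more often. The codon-to-group assignment is
  a fixed seeded permutation.
* **Per-site rate jitter**: log-normal with σ = 0.3 on top of codon
  identity, reflecting positional rate variation beyond the decoded
  codon (nascent-chain and structural effects); per-site rates then span
  roughly 2.5–23 codons/s, matching the width of empirical per-codon
  rate distributions.
* **Initiation rates**: log-normal, median 0.1/s (median time between
  initiations 10 s), σ = 0.4 (5th–95th percentiles ≈ 5.5–20 s between
  events). **Termination**: 3 codons/s — slow, reproducing the queueing
  signature one footprint upstream of the stop codon.
* **Speed calibration**: each gene's true (α, λ) are jointly rescaled so
  its simulated mean observed speed over [150, L] is 5.6 codons/s,
  putting ground truth on the same scale the inference normalizes to.
* **Profiles**: sampled one footprint per snapshot, with snapshots
  thinned by at least one lattice length (≥ L events) so draws are
  effectively independent — the generator's sampling model is
  multinomial. Default depth is 300 reads per codon, a well-covered gene
  (the empirical coverage filter, mean > 10 reads/codon, is a floor, and
  well-expressed genes run to hundreds of reads per codon). At 100
  reads/codon the inverse-count estimator is noise-limited: the
  per-gene Pearson correlation between estimated and true rates has a
  sampling ceiling of ≈ 0.94 (Var_noise ≈ E[λ³]/((N/L)·harmonic-mean λ))
  regardless of implementation, rising to ≈ 0.98 at the default depth.
  Recovery tests therefore probe the method, not the shot noise.
* **TE values**: detected density (per 100 codons) × 0.83, plus the true
  total density for calibration closure tests.
* Planted feature effects enter multiplicatively, λ ← λ·exp(βx), so
  Eq.-style additive deviations are recovered approximately for small β
  (linearization caveat) and exactly in noise-free constructions where y
  is built directly from the computed features.

What the generator does **not** emulate: sequencing noise beyond
multinomial sampling, nuclease-digestion length distributions, codon
autocorrelation along real ORFs, UTRs, or gene-to-gene codon-usage
variation. Passing recovery tests therefore demonstrate correctness of
the estimator under the model's own assumptions, not robustness to
protocol biases in real libraries.

## Feature regression

The dependent variable y_i is the mean over genes of λ_i − λ̄_c, with
λ̄_c the codon-type mean over all genes and positions. Features are
windowed aggregates, inclusive on both ends: upstream window [a:b] at
A-site i covers positions i−b..i−a (counts of K/R or D/E; mean
Kyte–Doolittle hydropathy), downstream [a:b] covers i+a..i+b (mean
per-codon PARS, a codon's PARS being the mean of its nucleotides'
scores). Windows truncated by the ORF boundary aggregate what is there;
an empty truncated window counts 0 for charges and is missing for
means. Fits are OLS with an intercept (deviations need not be mean-zero
over a sub-region; the intercept is reported separately, and a
no-intercept variant is exposed). Window scanning is exhaustive over
a ∈ [0, 15], b ∈ [a, 45]: one or two feature kinds are scanned jointly
(the two-kind R² is computed in closed form from correlation matrices),
three or more by coordinate ascent from each kind's best single window;
ties break toward smaller windows. Collinear designs trigger a
condition-number warning.

## Tunnel potentials

The centerline fit is total least squares (first principal axis); R² is
the explained-variance fraction, and the arc coordinate is the
projection with the PTC end at 0. Charges are placed on single
representative atoms: −1 on each nucleotide phosphorus, +1 on LYS NZ and
ARG CZ, −1 on ASP CG and GLU CD; histidine is uncharged (standard pH).
The entropic potential is S(x) = ln(πr(x)²); the Coulomb potential sums
q_j/d over charges within 20 Å of the evaluated centerline point (the
per-point interpretation keeps V(x) local), with unit prefactor —
potentials are in arbitrary units, as no dielectric model is imposed.
Gradients use central differences on the arc coordinate; smoothing is a
10 Å moving average truncated at the ends. Charges coinciding with a
centerline point are excluded with a warning.

## Drop-off estimation

Genes covering the fitted region are mean-normalized, averaged within
25-codon bins across genes, and the log bin means are fit by OLS on the
1-based bin index: value = A·e^(−QX). The per-codon, per-event drop-off
probability is r = 1 − e^(−Q/25) (per-codon survival compounds to e^(−Q)
per bin); negative Q yields r = 0 with a warning. A gene-level bootstrap
(resampling genes with replacement) gives the sampling distribution of
Q. Note 1 − e^(−0.048/25) = 0.00192, i.e. the ramp-region rate is 0.002
only at one significant figure.

## Numerical and scope choices

* Seeds: every stochastic component takes an explicit seed; identical
  (model, config, seed) reproduce identical event streams. Kernel seeds
  are reduced modulo 2³¹.
* The error-site threshold and λ_max are configuration with documented
  defaults (0.3 × mean normalized density; 50), not asserted empirical
  constants.
* Convergence of the correction loop: no remaining downstream error
  sites, a non-improving site (flagged unresolved), or the round cap
  (20).
* Problem sizes in the test suite: oracle checks use L ≤ 8, ℓ ≤ 2 with
  2×10⁴ snapshots; recovery uses 20 genes of 300 codons; the scan uses
  60 genes. These sizes give comfortable statistical resolution for the
  assertions made.
* Out of scope: read alignment, RPKM computation, tunnel cavity
  detection, Poisson–Boltzmann electrostatics, Fick–Jacobs diffusion
  solving, multi-gene shared-parameter fitting, and reproduction of
  empirical yeast curves that require the original sequencing datasets.
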