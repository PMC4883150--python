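# Methods

## Problem and scope

`gcconnbench` measures how reliably four linear connectivity detectors
recover the directed structure of a multichannel stationary process from a
finite record of length K, in the Neyman–Pearson sense: does an α-level test
of "no connection j → i" actually reject with probability α when the
connection is absent, and how fast does its miss rate vanish when the
connection exists?  The detectors are

* **GCT** — the time-domain Granger causality Wald test on the fitted VAR
  coefficients from source to target;
* **iPDC / iDTF** — per-frequency tests on the squared information partial
  directed coherence and information directed transfer function, using
  their asymptotic null distributions;
* **cMVGC** — pairwise-conditional multivariate Granger causality, the
  Geweke log-ratio of reduced-model to full-model residual variances.

All inputs are synthetic and generated internally, so every detection
decision can be scored against known ground truth.

## Generative models

Three toy networks, simulated with independent N(0,1) innovations, zero
initial state and a 5000-sample burn-in:

* **Model 1** (7 channels, VAR(2)): a closed loop over x1..x5 — x1 is a
  resonant AR(2) oscillator (poles 0.95·e^{±iπ/4}, i.e. modulus 0.95 at
  normalized frequency 1/8), driving x2 and x3, with x3 → x4 ⇄ x5 → x1
  closing the loop — and a disconnected pair x6 → x7 whose x6 carries the
  same oscillator polynomial.  8 of the 42 ordered pairs are direct edges;
  within x1..x5 every node reaches every other.
* **Model 2** (5 channels, VAR(3)): the same oscillator in x1 driving x2
  (lag 2), x3 (lag 3) and x4 (lag 2), plus the x4 ⇄ x5 rotation pair.
  5 of 20 ordered pairs are edges.
* **Model 3**: Model 2's coefficient skeleton, but the disturbance of
  channel i is e_i(t) + a_i·e6(t) + b_i·e7(t−1) + c_i·e7(t−2) with shared
  exogenous e6, latent serially-correlated e7, a_i ~ U(0,1) redrawn every
  trial, b_i = 2, c_i = 5.  The observed 5-channel process is **not** a
  finite-order VAR; it deliberately violates the assumption every detector
  relies on.  Its scoring truth is Model 2's graph: the contamination adds
  no directed edge.

Seeding: each trial owns a `SeedSequence`; innovation sources e1..e7 take
substreams 0..6, so setting a = b = c = 0 in Model 3 replays Model 2 sample
for sample.  Identical (model, K, seed) gives bitwise-identical series.

## Estimation

* **Nuttall–Strand** (used for GCT/iPDC/iDTF): multichannel Burg-type
  lattice.  At stage m the partial cross-covariance ρ between forward and
  backward prediction errors solves the harmonic-mean Sylvester equation
  (P̂f Pf⁻¹)ρ + ρ(Pb⁻¹ P̂b) = 2 P̂fb; reflection matrices A_mm = ρPb⁻¹,
  B_mm = ρᵀPf⁻¹; coefficients assembled by the Levinson recursion.  Fitted
  models are always stable.
* **LWR** (used for cMVGC): Whittle's recursion solving the block-Toeplitz
  multivariate Yule–Walker equations on biased (1/K) sample
  autocovariances; the 1/K normalization keeps the block-Toeplitz regressor
  covariance positive semi-definite.
* Channel means are subtracted before fitting (the models are zero-mean;
  harmless for user data).
* **Order selection**: AIC(p) = ln det Σ̂w(p) + 2pN²/K, minimized over
  p = 1..p_max with ties to the smaller order; p_max defaults to 30,
  shrunk to (K−1)/(2N) on short records so the search stays identifiable.
  Both lattices sweep all candidate orders in a single pass.  On Models 1–2
  with K ≥ 2000 the true orders (2 and 3) are selected essentially always;
  at K = 500 on Model 2 the lag-3 term of x3 is largely predictable from
  lags 1–2 of the oscillator, so AIC occasionally picks order 2, a genuine
  pre-test effect of the protocol rather than an estimator defect.  On
  Model 3 the selected order grows with K, as expected for a process with
  no finite VAR order.

## Asymptotic statistics

Vectorizing the coefficients lag-major with the target index fastest, the
large-sample covariance of the estimates is (Γ̂_p⁻¹ ⊗ Σ̂w)/K, with Γ̂_p the
block-Toeplitz sample covariance of the stacked lag vector.  Every test
below projects this one object.

* **GCT**: W = âᵀC⁻¹â over the p coefficients of the pair, C the matching
  covariance sub-block; W ~ χ²_p under H0.  The chi-square (not
  finite-sample F) form is used throughout, consistent with the asymptotic
  framing; at the record lengths studied the difference is negligible.
* **iPDC**: |ιπ_ij(f)|² = (|Ā_ij(f)|²/σ_ii)/(ā_j(f)ᴴ Σw⁻¹ ā_j(f)) with
  Ā(f) = I − Σ_r A_r e^{−i2πfr}.  Under H0, [Re Ā_ij, Im Ā_ij] is
  asymptotically a zero-mean bivariate Gaussian obtained by projecting the
  coefficient covariance through (cos 2πfr, −sin 2πfr); K·|ιπ̂|² is then a
  two-term weighted chi-square whose weights are the eigenvalues of that
  2×2 covariance divided by the (plug-in) denominator.  At f = 0 the
  imaginary part vanishes and the null collapses to a single term.
* **iDTF**: |ιγ_ij(f)|² = |H_ij(f)|²·ρ_jj/(h̄_i(f) Σw h̄_i(f)ᴴ) with
  H = Ā⁻¹ and ρ_jj = 1/(Σw⁻¹)_jj.  Same construction with the delta-method
  derivative dH = −H·dĀ·H; the gradient is a rank-one outer product, so the
  2×2 projection reduces to a handful of quadratic forms in Γ̂⁻¹ and Σ̂w.
* **Weighted chi-square tail**: Patnaik's two-moment scaled chi-square by
  default.  Exact Imhof integration is available as a cross-check; the two
  agree within 0.0025 wherever p ≤ 0.05 (the decision region at α = 1%).  In
  the distribution body (p ≳ 0.5) Patnaik can deviate by up to ~0.02,
  irrelevant to detection.
* **cMVGC**: the reduced model drops the source channel and is *refit* by
  LWR at the same order as the full model; F = ln(Σ̂ʳ_ii/Σ̂ᶠ_ii), K·F ~ χ²_p
  under H0.  Tiny negative F (numerical, nested fits by different
  recursions) is clipped to zero.  This is a clean conditional-GC
  implementation: it is expected to be correctly calibrated, and the test
  suite verifies that; idiosyncrasies of other published implementations
  are out of scope.

Both squared measures lie in [0, 1] entrywise (Cauchy–Schwarz in the Σw
metric).  The column sums of squared iPDC and row sums of squared iDTF
equal 1 exactly when Σw = I; for correlated innovations the sums can exceed
1 even though each entry cannot.

## Detection protocol and scoring

α = 1% throughout.  Frequency-domain tests are evaluated on 32 uniform
frequencies f_k = k/64, k = 0..31, and a pair is declared detected if
*some* frequency has p < α — a deliberately lax scan (no across-frequency
correction) that is expected to inflate false positives relative to GCT.
Optional Bonferroni / Benjamini–Hochberg corrections across the N(N−1)
pairs are available.  GCT, iPDC and cMVGC are scored against direct
adjacency; iDTF against reachability (transitive closure), because it
responds to influence through any pathway.  FP rate per absent pair and FN
rate per present pair are fractions of valid trials; failed trials
(singular fits) are recorded and excluded, never dropped silently.

Cross-method slope comparisons regress, per ordered pair, the per-trial
−log10 p of one method on the other's (frequency methods contribute their
minimum-p over the grid) with a least-squares line through the origin —
the line's slope is the natural summary of "clustered above/below the 45°
diagonal"; ordinary least squares with intercept is available as an
alternative but the through-origin fit is the default and what the
aggregate statistics report.

## Problem sizes and tolerances

Monte Carlo experiments default to 1000 replications.  The test suite and
the acceptance script use 300–1000 replications depending on the cell
(larger K cells use fewer), with binomial tolerance bands widened by
√(1000/n_reps) accordingly; each suite or script run states its n.  All
randomness descends from a single master seed; archives are identical for
any worker count because every trial owns a spawned substream.

## Known limitations

* The iPDC/iDTF null uses plug-in denominators; at K ≤ 100 the
  per-frequency test is only approximately calibrated (visible as mildly
  inflated FP rates, consistent with the benchmark's own findings).
* Model 3's composite disturbance makes every fitted VAR misspecified by
  design; FP rates there *increase* with K for all methods.  This is the
  phenomenon under study, not an artifact.
* Generators are restricted to stationary Gaussian processes with constant
  coefficients; no nonstationary or non-Gaussian variants.
* No bootstrap-based nulls; all tests are asymptotic.
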