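# Methods

## Model and procedure

The unit of analysis is an n × m matrix of raw p-values whose rows are
features and whose columns are outcomes. The working model behind 2dGBH is
the two-group model applied cell-wise: each cell is null with probability
π₀ᵢⱼ, and π₀ᵢⱼ is assumed to factor through the row and column memberships.
The procedure estimates π₀ along both margins, combines the margins into a
per-cell estimate, converts it to a weight w = (1−π₀)/π₀, and runs the BH
step-up on the weighted p-values. The FDR guarantee is inherited from the
weighted-BH argument of the one-way adaptive group BH procedure; the
two-dimensional extension is heuristic in the same way the one-way adaptive
procedure is (estimated, not oracle, weights), which is why the shrinkage
step exists.

## Null-proportion estimators

* **storey** (default): π̂₀ = #{p > λ} / ((1−λ)·k), λ = 0.5. The unmodified
  tail-proportion form, without the finite-sample +1 correction; estimates
  are clipped to [10⁻⁸, 1].
* **lsl** (least slope): with sorted p-values, slopes
  lᵢ = (1−p₍ᵢ₎)/(k+1−i) rise through a signal-rich head and fall where the
  null tail begins; the slope just before the first strict decrease gives
  π̂₀ = (1/l + 1)/k. If the slopes never decrease the estimate is 1. A
  right-to-left scan variant was rejected because floating-point noise in
  tied slopes triggers it spuriously.
* **tst** (two-stage): BH at level α/(1+α); π̂₀ = (k−r)/k with r the
  rejection count.

All estimates, global and per-group, are computed on the *raw* p-values;
weighting happens strictly afterwards.

## Parameters

| parameter | default | meaning |
|---|---|---|
| S (shrinkage) | 0.1 | convex weight pulling group π₀ estimates toward the global one; 0 = none, 1 = collapse to global. Larger S improves null calibration at small m but costs power at high signal density. |
| λ (Storey threshold) | 0.5 | tail cutoff of the Storey estimator. |
| combine | weighted | `weighted`: row^(1−R)·col^R with data-driven R; `geometric`: R fixed at 0.5; `arithmetic`: (row+col)/2. |
| π₀ floor | 1e−8 | lower clip for every π₀ estimate; prevents infinite weights and zero weighted p-values without materially changing estimates. |
| α | 0.05 | target FDR level. |

## The balance factor

R = (σ̂₂/m) / (σ̂₁/n + σ̂₂/m), with σ̂₁ the sample standard deviation (ddof 1)
of the n shrunken row estimates and σ̂₂ that of the m shrunken column
estimates. Spread across a direction's group estimates signals that the
grouping is informative; dividing by the *other* dimension's count means the
direction whose groups contain more p-values (and are therefore better
estimated) dominates. For a typical 1000 × 20 matrix R ≈ 0.9–1: the 20
column estimates, each based on 1000 p-values, carry almost all the weight.
The formula is implemented literally as stated; an alternative reading with
standard errors (σ̂/√count) exists but is not used. When both standard
deviations are zero R defaults to 0.5 — inconsequential, since both
directions then give identical per-cell estimates.

## Degenerate inputs and tie-breaking

* A cell with π̂₀ᵢⱼ = 1 gets weight 0; its weighted p-value is +∞ and it is
  never rejected. If *every* group estimate clips to 1 the procedure
  rejects nothing at any α.
* Weighted p-values above 1 are left untruncated; the BH step-up never
  rejects them, so capping is unnecessary.
* BH ties are handled by the standard cumulative-minimum adjustment; no
  explicit tie-breaking is needed.
* Matrices with missing, non-finite or out-of-range entries are rejected at
  load. Silent NA handling would change group sizes and hence every π₀
  estimate.
* Reductions (standard deviations, the mean of the per-cell π₀ surface) are
  computed over sorted copies, making the output bit-identical under row or
  column permutations of the input despite floating-point non-associativity.

## Simulator

The generator emulates a z-score matrix from large-scale association
testing: null cells z ~ N(0,1), ⌊n·m·θ⌋ signal cells z ~ N(μ, σ²) placed
uniformly at random (without replacement) inside an enriched sub-rectangle
of ⌈n·pᵢ⌉ random features × ⌈m·pⱼ⌉ random outcomes, and one-sided p-values
p = 1 − Φ(z). Defaults μ = 2, σ = 1. Correlated settings draw the noise per
outcome column from an equicorrelated block structure (shared-factor
construction, 20 features per block by default) or an AR(1) chain
(exact recursion), both with ρ = 0.7 and unit marginal variance; the signal
mean μ is then added to the noise. Columns are independent of each other.

What the simulator does *not* emulate: estimation of p-values from raw
counts or abundances (no library-size, compositionality or zero-inflation
effects), dependence *across* outcome columns, heavy-tailed or miscalibrated
test statistics, and two-sided tests. A green benchmark therefore
establishes calibration and power under idealised normal-theory p-values
with the stated enrichment patterns — not robustness to a misspecified
testing pipeline upstream.

## Benchmark conventions

FDP is FP/max(R,1); TPR is TP/#nonnull and is reported as NaN (excluded)
under the global null; the per-run average of FDP over *all* runs is the
"observed FDR" in signal settings, while under the global null the observed
FDR is the any-discovery frequency (the two coincide in expectation there).
Per-run seeds derive from the master seed by a counter-based scheme
(SeedSequence with a (scenario, run) spawn key), so results are independent
of execution order. Default 100 runs per signal setting and 1000 under the
global null, at α = 0.05.

## Known limitations

* With few outcomes (m ≈ 20) the any-discovery rate of 2dGBH under the
  global null measures ~6–7% at the 5% target in this implementation —
  adaptive weight estimation is slightly anti-conservative there, as it is
  for one-way adaptive GBH. Raising S tightens calibration at a power cost.
* The Storey q-value comparator uses the fixed-λ estimator (λ = 0.5), not
  the smoothing-spline estimator of the reference q-value software, so its
  numbers can differ slightly from that package at high signal density.
* The one-way adaptive GBH comparator follows the published algorithm
  (per-group Storey estimates, size-weighted overall π₀); single-member
  groups fall back to the overall estimate with a warning.
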