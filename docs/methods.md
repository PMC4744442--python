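# Methods

## Model and null hypothesis

For a gene set of size `p` with expression block `X` (n samples) and
phenotype `Y`, the question "is this set associated with the phenotype?" is
phrased through sufficient dimension reduction: if `Y | X` and `Y | ηᵀX`
share the same distribution for some `p × d` matrix `η`, the column space of
`η` is a dimension-reduction subspace, and the smallest such subspace (the
central subspace) has dimension `d`, the structural dimension. No
association is exactly `d = 0`, and that is the null the package tests. No
subspace is ever estimated — only the `d = 0` test is implemented.

The test statistic is built from the SAVE kernel
`E[Var(Z|Y) − Var(Z)]²`, estimated by slicing the sample on `Y`:

    T = Σ_s p̂_s tr(Σ̂_{Z|s} − I_p)²,

the weighted squared Frobenius deviation of within-slice covariances of the
standardized data from the pooled (identity) covariance. A population
decomposition of `T` shows it carries three kinds of deviation: within-slice
variance changes, within-slice covariance changes, and a term in the slice
means that vanishes when conditional means are uncorrelated across genes —
hence a mean-shift alternative can leave `T` underpowered. The modified
statistic

    V = Σ_s p̂_s [ tr{(Σ̂_{Z|s}^{1/2} − I_p)²} + ‖Z̄_s‖² ]

adds the squared slice means explicitly. We take the square root *inside*
the square in both `V` and `V*` at face value; no tuning weight is put on
the mean term. `T` decomposes exactly as `Σᵢ Tᵢ` with
`Tᵢ = Σ_s p̂_s Σⱼ (σ̂_{i,j|s} − σ_{i,j})²`; the implementation computes `Tᵢ`
first and sums, so the decomposition identity holds to machine precision.

## Standardization

`Z = Σ̂_X^{-1/2}(X − X̄)` with the symmetric inverse square root by
eigendecomposition. Three modes:

* `exact` — requires numerical nonsingularity: eigenvalues below
  `1e-10 ×` the largest are treated as zero and trigger an error naming the
  deficient rank. In practice this requires `n > p`.
* `shrinkage` — Ledoit–Wolf shrinkage toward a scaled identity
  (scikit-learn's analytic intensity; no cross-validation, so the transform
  is deterministic). The shrunk matrix is positive definite for any `p/n`.
* `identity` — centering only; feeds the unstandardized statistics
  `T* = Σ_s p̂_s tr(Σ̂_{X|s} − Σ̂_X)²` and its `V*` analogue, which replace the
  identity/zero references by the pooled covariance/mean.

The default `auto` picks `exact` when possible, else `shrinkage`, and the
chosen mode is recorded in every result. Covariances (pooled and
within-slice alike) use the maximum-likelihood divisor `n` by default — the
convention in the SDR literature — so a single slice containing the whole
sample reproduces the pooled moments and `T = V = 0` exactly; a `ddof=1`
flag switches both divisors together.

## Slicing

Categorical phenotypes slice naturally, one slice per level in sorted level
order, each level needing ≥ 2 samples. Continuous phenotypes are ranked and
cut into `H` contiguous groups with sizes differing by at most one (any
remainder goes to the lowest slices); ties are ordered by original sample
index, deterministically, and a boundary inside a tie group is logged. This
rank-based rule makes the partition invariant under strictly increasing
transforms of the phenotype. The default is `H = 2` equal slices — the
choice used throughout the continuous analyses here, and a sensible one at
genomic sample sizes where each slice must support a `p × p` covariance
estimate; `slices="auto"` applies the `max(2, round(0.1 n))`
rule of thumb. `V` is robust to the slice count; `T` is less so, so users of
`T` on continuous phenotypes are advised to try a few values of `H`.

## Permutation inference

Phenotype labels are permuted uniformly (default B = 1000); the p-value is
the add-one estimator `(1 + #{stat_b ≥ stat_obs})/(B + 1)`, never zero, with
ties counted against the null — a conservative choice. Standardization
depends on `X` only, so the transform is computed once and reused across
replicates (asserted equivalent to re-standardizing per replicate in the
tests); label permutation preserves slice sizes, so each replicate merely
reassigns which samples fall in which slice. All permutation orders are
pre-generated from one seeded generator, making results independent of any
execution chunking. Per-gene significance for `T`-type statistics compares
each observed `Tᵢ` with its own permutation stream from the same replicates;
no multiplicity adjustment is applied by default (an optional
Benjamini–Hochberg column across sets is clearly labelled an extension).
When a whole collection is screened, every set is tested against the same
permutation stream, which makes the report invariant under gene reordering
within a set and preserves correlation between set-level p-values.

Inside the permutation loop, `V` with an identity reference is evaluated
from the singular values of the centered slice block rather than an
eigendecomposition of the `p × p` covariance (the `p − min(n_s, p)`
structurally zero eigenvalues each contribute 1 to the trace term); the
engine is asserted equal to the moment-based statistics in the tests.

## Simulation designs

Three families, matching the size/power study conditions:

* **Binary**: groups of `n/2` from `N(0, Σ₁)`, `N(0, Σ₂)`. Homogeneous:
  unit variances; heterogeneous: variances ~ U(1, 5), redrawn independently
  per replicate and per group under the alternative (shared between groups
  under the null, where `Σ₂ = Σ₁`). Alternative: first `γp` genes
  equi-correlated at `ρ` in group 2, `γ ∈ {0.25, 0.5, 0.75, 1}`,
  `ρ ∈ [0.1, 0.9]`. Covariances assembled as `D^{1/2} R D^{1/2}` — `ρ` acts
  on correlations, not covariances — and checked positive definite.
* **Three-class**: groups of `n/3`; `Σ₁` diagonal with U(1, 5) variances;
  `Σ₂`, `Σ₃` block-diagonal with four blocks of `p/4`, the first `γp/4`
  positions per block correlated in `Σ₂` and the last `γp/4` in `Σ₃`.
* **Continuous**: `X ~ MVN(0, Σ_X)` with unit variances, genes `1..p₁`
  equi-correlated at `ρ`, genes `p₁+1..2p₁` AR-correlated (`ρ^{|i−j|}`),
  independent otherwise. Null: `Y ~ N(0,1)` independent of `X`. Alternatives:
  `Y|x ~ N(xᵀβ, 1)` (linear) or `N(exp(xᵀβ), 1)` (nonlinear), with five
  random signal genes per correlated block, `βⱼ ~ N(ν, |ν|)` in the first
  and `N(−ν, |ν|)` in the second (`|ν|` read as the variance); signal
  positions are redrawn per replicate, and `ν = 0` gives `β = 0` exactly.

The size/power harness spawns an independent generator stream per dataset
from one master seed, so rejection-rate estimates are deterministic in the
seed; binomial standard errors are attached, and the closed-form calibration
(`SE = √(α(1−α)/N)` with its 97.5% normal upper limit) is exposed as
`calibration_limits`.

**What the generators do not emulate**: real expression data are
non-Gaussian, heteroskedastic beyond U(1, 5), and carry batch structure and
probe-level noise; slices of a real continuous phenotype need not be
equally informative. Passing the simulation checks therefore establishes
level correctness under exchangeability (which the permutation construction
gives for any data distribution) and power behaviour under Gaussian
alternatives — not power guarantees on any particular real dataset.

## Problem sizes in the shipped checks

The acceptance checks run at desk scale chosen to keep the full suite in
the minutes range while leaving 3-standard-error resolution: 500 null
datasets × 300 permutations for type-I-error rates (binomial SE ≈ 0.01 at
a true rate of 0.05), 300 datasets × 200 permutations for power
comparisons, and 1000 datasets × 99 permutations for the super-uniformity
property (resolution 0.01, the smallest α checked). Covariance-construction
checks use a 50 000-draw moment oracle.

## Numerical choices

* Symmetric matrix powers by `eigh` with eigenvalues clipped at zero;
  results re-symmetrized. Asymmetry beyond `1e-10` (relative) is an input
  error.
* Within-slice covariances are accepted as PSD up to a `−1e-10` relative
  eigenvalue tolerance (round-off), clipped before square roots; anything
  worse raises.
* A statistic refuses slice moments whose reference covariance does not
  match its contract (e.g. `T` on unstandardized moments) rather than
  silently producing a number.
* `γp` (and `γp/4`) are rounded to the nearest integer when fractional; the
  standard parameter grids avoid this case.

## Known limitations

* Only the `d = 0` marginal test: no direction estimation, no tests of
  `d ≥ 1`, no SIR kernel, no asymptotic reference distributions.
* Permutation cost scales with `B × H × min(n_s, p)` covariance/SVD work
  per set; screening thousands of sets at B = 1000 is minutes, not seconds.
* Whether shrinkage standardization or the unstandardized `T*/V*` is
  preferable for `p ≫ n` power is an open practical question; both are
  exposed, the permutation test is level-correct either way, and the
  shrinkage route is the default fallback.
* The gene-level p-values are self-contained (each gene against its own
  permutation distribution) and unadjusted by default.
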