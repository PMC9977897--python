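# Methods

## Model and assumptions

An ordinal pair (X, Y) with I and J categories is assumed to arise by
thresholding a continuous latent vector Z = (Z₁, Z₂) at strictly
increasing deterministic cutoffs.  The latent marginals F₁, F₂ are taken
as *known*, continuous, strictly increasing, and of finite positive
variance; the copula C of Z is unknown.  Under these assumptions the set
of latent Pearson correlations compatible with the observed cumulative
probability matrix Π is a closed interval [ρ_L, ρ_U], attained by the
extremal (Carley-type) extensions of the observed subcopula.  If the
marginals are not restricted at all, any ρ in (−1, 1) is attainable for
any Π, so fixing the marginals is what gives the problem content; the
package therefore always takes two `Marginal` objects as input.

Two observation regimes are covered:

* **Fully ordinal** (`latentcorr.ordinal`): only Π is observed.  The
  endpoint formulas integrate F₁⁻¹(u)·F₂⁻¹(v(u)) along IJ slope-±1 mass
  segments whose limits are the row-major flattenings of the auxiliary
  matrices α, γ (u-grids) and β, δ (v-offsets).  Row-major order is what
  makes the u-grids nondecreasing: consecutive α entries within a row
  differ by a cell mass, and α_{i+1,1} = Π_{iJ} ≥ α_{iJ}.  The
  γ/δ matrices use the reversed column order so that the antitone system's
  u-grid is increasing as well; the package treats the cumulative-form
  (Π-index) expressions as authoritative and validates them structurally
  (tiling and cell-mass invariants of `SegmentSystem`, LP oracle
  agreement) rather than against prose probability identities.
* **Polyserial-type** (`latentcorr.polyserial`): X is ordinal, Z₂ is
  observed, so V = F₂(Z₂) is uniform and the observable is the curve
  family Π*_{iv} = C(c_i, v) at the I−1 interior cut levels c_i.  The
  compatible copulas are enveloped by

      M(u,v) = min(u, v, min_i [Π*_{iv} + (u − c_i)⁺]),
      W(u,v) = max(0, u+v−1, max_i [Π*_{iv} − (c_i − u)⁺]),

  with the min/max running over the finite cut set only, and the interval
  is [ρ(W; F₁, F₂), ρ(M; F₁, F₂)] via Höffding's covariance formula.

Degenerate inputs: zero-mass categories are merged before the bound
construction (`tables.collapse`); they correspond to zero-length segments
and cannot change the interval, but they break strict monotonicity checks.
A table that collapses to 1×1 carries no information and returns the
Fréchet–Hoeffding endpoints for the given marginals (±1 for identical
symmetric marginals).  Computed endpoints are clamped to [−1, 1].

## Numerical choices

**Segment quadrature.**  Within a segment the integrand is smooth, so a
fixed-order Gauss–Legendre rule (default order 32) is applied per segment,
vectorized across all segments.  Unbounded quantile functions (normal,
Laplace) have integrable singularities where u or v(u) reaches 0 or 1;
exactly the segments touching those boundary values are re-integrated by
geometric grading: the interval is repeatedly halved toward the singular
endpoint, the regular half integrated at each step, stopping when the
remaining contribution falls below `refine_tol` (default 1e-10, absolute)
or the interval underflows.  The reported `quad_error` is the difference
between the full- and half-order estimates on regular segments plus the
refinement remainders — an honest, slightly conservative diagnostic.  For
polynomial quantiles (uniform) the rule is exact; the hand-derivable 2×2
independence case reproduces ±13/16 to ~1e-15.

**Höffding integral.**  Evaluated in x-space as
∬ [C(F₁(x), F₂(y)) − F₁(x)F₂(y)] dx dy / (sd₁·sd₂) over the quantile box
[F⁻¹(ε), F⁻¹(1−ε)]², ε = 1e-7, with a tensorized panel Gauss–Legendre
rule (order 12 per panel, starting at 8 panels per axis) whose panel count
doubles until two successive estimates differ by less than `tol`
(default 1e-4).  The neglected tail is bounded via
|C − uv| ≤ min(u, 1−u, v, 1−v) ≤ ε.  Working in x-space avoids
differentiating quantile functions; the change of variables is exact for
the continuous strictly increasing marginals assumed.  Copula evaluations
on large tensor grids are chunked to bound memory.  Non-convergence at
the panel cap raises `QuadratureError` with the last two estimates.

**Gaussian copula.**  C_ρ(u,v) is computed from the one-dimensional
integral of the bivariate normal density over the correlation parameter
(64-point Gauss–Legendre on [0, ρ]), fully vectorized; it agrees with
per-point bivariate normal CDF routines to ~1e-16 and is fast enough to
discretize 200×200 grids and feed million-node quadratures.

**LP oracle.**  The brute-force check discretizes couplings onto the union
of a uniform n-grid and the Π cut values per axis (so block-sum
constraints are exact), with uniform-margin row/column constraints and one
block-sum constraint per Π cell; cell representatives are midpoints mapped
through the quantiles.  The resulting transportation LPs are solved with
HiGHS interior point, which is fast here because the constraint system has
only O(n) rows, and deterministic for fixed inputs.  LP endpoints approach
the analytic ones from inside at rate O(1/n).

**Mesh-convergence checks.**  The identification set contracts to the
point ρ(C; F₁, F₂) as the X- and Y-meshes (largest marginal cell
probabilities) shrink; with I fixed and only the Y-mesh shrinking it
contracts to the polyserial interval.  The test suite verifies the former
on the reference configuration at I = J ∈ {2, 5, 10, 50, 200} and the
latter at I = 4 with uniform Y-cuts j/J at J = 500, where the endpoint gap
is below 0.01.  Uniform Y-cuts are used for the limit check because their
mesh is exactly 1/J; Beta-quantile cuts thin out near 0 (mesh ≈ 0.067 at
J = 500 for Beta(2.3, 1.2)) and converge visibly more slowly.

## Synthetic study configuration

`synthetic.Example1Config` reproduces the reference setup: a Gaussian
copula with parameter ρ = 0.7 discretized on cutoffs Q₁(i/I), Q₂(j/J)
where Q₁, Q₂ are the Beta(2.7, 1.1) and Beta(2.3, 1.2) quantile functions.
The Beta parameters emulate the right-skewed marginal frequencies of
6-point agreeableness rating items, so the generated tables resemble real
questionnaire cross-tabulations at any category count.  Under standard
normal marginals the generating latent correlation is 0.7; under uniform
marginals it is (6/π)·arcsin(0.35) = 0.68291 (0.683 to three decimals) and
under standard Laplace marginals 0.68645 (0.686), both recomputed by the
package's own quadrature and cross-checked against the closed form in the
uniform case.

What the generator does *not* emulate: sampling noise is available only
through `sample_counts` (multinomial draws with mandatory seeds); the
population-level tests say nothing about estimation error in Π̂, and no
inference (standard errors, confidence sets for the bounds) is provided —
the analysis is at the population level throughout.  Real questionnaire
batteries are multivariate; simultaneous identification sets for whole
correlation matrices are out of scope, as is any restriction of the copula
class (symmetry, ellipticity, parametric families), which would shorten
the intervals but requires different machinery.

## Problem sizes used in the checks

The oracle-agreement check uses 20 random tables up to 4×4 against the LP
at grid resolution n = 400 (tolerance 0.01, the oracle's own O(1/n)
resolution scale).  Convergence checks use up to 200×200 tables (40 000
segments) and J = 500 for the polyserial limit.  The Höffding quadrature
converges at 16–32 panels (192–384 nodes per axis) for the copulas
involved.

## Known limitations

* Empirical tables are treated as exact: `from_counts` produces the plug-in
  Π̂ and the interval is the identification set of that point estimate.
* The polyserial empirical curves use mid-rank pseudo-observations; with
  heavy ties in z the Fréchet-consistency invariants hold only up to the
  step granularity 1/n.
* `hoeffding_correlation` assumes the copula callable is accurate near the
  corners of [0,1]²; a user-supplied copula violating uniform margins will
  bias the result (use `CopulaSpec.validate`).
* The LP oracle is exact only in the n → ∞ limit and is intended for
  verification at small table sizes, not as a production bound computer.
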