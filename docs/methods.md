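# Methods

## Model and design problem

Responses to a calibration item follow the two-parameter logistic model:
an examinee with ability θ answers item i correctly with probability
`p_i(θ) = 1/(1 + exp(-a_i(θ - b_i)))`, with discrimination `a_i > 0` and
difficulty `b_i`.  The model is treated as a generalized linear model with
logit link `η_i = a_i(θ - b_i)`; the GLM weight is `ν_i = p_i(1 - p_i)` and
the link gradient with respect to (a, b) is `u_i(θ) = (θ - b_i, -a_i)ᵀ`.
The standardized per-item information of a design is block-diagonal across
items, so the D-criterion separates into `-Σ_i log det M_i`.

The population of examinees is described by a continuous ability density g.
A calibration design assigns to each item a sub-density `h_i ≤ g`; the
designs considered here are exactly the restricted class `h_i = g` on a
finite union of intervals, 0 elsewhere, with all items' intervals pairwise
disjoint and total sampled mass `Σ_i ∫ h_i = s`.  This is the optimal class:
the directional derivative `F_D(h, θ, i)` of the D-criterion is, for each
item, a smooth curve with at most two local minima, and an optimal design
samples item i exactly on `{θ : F_D(h, θ, i) = min_j F_D(h, θ, j) ≤ c*}`,
where the threshold c* is the largest value whose sub-level set carries
population mass at most s.  For one item this yields at most two intervals;
for several items, intervals may abut where two items' curves cross
(the items then compete for the same examinees), and more than two
intervals per item can be needed.

Locality: the design is optimal *at the best-guess parameter values*.  The
package makes no attempt to model parameter uncertainty (no Bayesian or
maximin criteria); a poor initial guess yields a design optimized for the
wrong item.

## Optimization

Boundaries are optimized on the probability scale `u = G(θ)` (G the
population cdf), where the mass-equality constraint and the left-to-right
ordering constraints are linear; SLSQP handles the resulting smooth
constrained problem.  For n ≥ 2 items with K intervals allowed per item,
every left-to-right interleaving of the n·K interval slots is solved
separately (for n = 2 there are binomial(2K, K) of them; enumeration is
capped at 500).  K starts at 2 and escalates when the equivalence check
fails; the best K-level solution, padded with zero-width slots, seeds the
next level, so the criterion is non-increasing in K by construction.
Multistart (default 8 per ordering) combines a start anchored at the
unrestricted design points `b ± c/a`, an equal-mass spread start, a
deterministic family of interior-gap starts for single items, and seeded
random perturbations; all randomness flows from the configured seed.

When the whole population is used (s = 1), there is no non-sampling region
and the support is partitioned into contiguous segments; the two unbounded
tails are anchored to the item with the smallest discrimination, whose
weight function decays slowest — sampling the extreme abilities for it
costs least information.

### Newton refinement of the boundaries

The D-criterion is *second-order flat* in each boundary at the optimum
(moving a boundary reallocates mass whose marginal information equals the
threshold value), so an SQP solve that converges in criterion still leaves
boundaries off by O(√ftol) ≈ 1e-2.  That is invisible in det M but fails
the sharp equivalence check.  After SLSQP, the package therefore solves the
first-order system directly, holding the interval structure fixed: a
boundary shared by two items satisfies `F_i(θ) = F_j(θ)`, a boundary
against the non-sampled region satisfies `F_i(θ) = c`, and the total mass
equals s — a square nonlinear system in the boundaries and c, solved with
a Newton-type root finder (information blocks recomputed inside the
residual).  Plain best-response iteration ("resample the sub-level set of
the current curves") is *not* used: when two items' derivative curves
nearly coincide over an interval, that fixed-point map is linearly
unstable — boundary errors amplify by two orders of magnitude per pass —
whereas the Newton solve converges to ~1e-15 violations.  The refinement
is rejected (and the SQP solution kept) if it degrades the criterion by
more than 1e-6 or moves any boundary by more than 0.5 ability units.

When a polished design still fails verification, one structure-discovery
step is attempted before escalating K: the design is rebuilt as the
sub-level set (mass s) of its own lower envelope, assigned pointwise to the
argmin item at grid resolution, and then Newton-polished.  This recovers
structures the ordering solve collapsed — typically a third interval for an
item — directly from the curves, and is accepted only if the refined design
both passes verification and does not worsen the criterion.  Repeated
best-response iteration of this map is deliberately avoided (see above);
one step followed by Newton refinement is stable.

## Optimality verification

The verifier evaluates all directional-derivative curves on 4001 equally
spaced abilities over the truncated support, refined tenfold within 0.1 of
every interval boundary; c* is found by monotone bisection on the weighted
grid mass.  A design passes when, up to tolerance 5e-3 (matching 3-decimal
reporting), (i) on every sampled interval the sampling item attains the
minimum of all curves and stays below c*, and (ii) off the sampled set the
lower envelope stays above c*.  Two measure-theoretic details matter in
practice.  The optimality condition holds almost everywhere with respect to
the design measure, so violations supported on less than 1e-6 population
mass are ignored — otherwise a boundary parked in the flat far tail (the
criterion is indifferent to ~1e-8 of mass there) produces spurious
violations near 2.  Second, a thin 1e-7 skin at interval boundaries is
excluded from the non-sampled check so that a grid point falling into the
hairline crack between two abutting intervals is not misread as an
uncovered region.

## Benchmarks and efficiency

The random design assigns items irrespective of ability (`h_i = s·g/n`);
the symmetric design samples mass s/m in an interval symmetric around each
of the m = 2n unrestricted points and is undefined when those intervals
overlap (returned as a structured failure value, not an exception).
Relative D-efficiency uses the 2n-th root of the determinant ratio; since
both designs share the same s, the standardization cancels and no second
scaling is applied.  The extra-sample-size reading `(1/RE_D - 1)·100 %`
relies on information scaling linearly in sample size.  For item banks
split into blocks (each examinee calibrates one item per block), the
overall efficiency of a benchmark against the blocked optimum is the
geometric mean of the per-block efficiencies — an identity under the
determinant-product form of the criterion, verified numerically in the
tests.

## Numerical choices

- Ability density truncated to [-10, 10] for the standard normal
  (mass beyond < 1e-10); boundaries within 1e-6 mass of the support edge
  are reported as ±∞.
- Fixed-order Gauss–Legendre quadrature per interval: 61 nodes inside the
  optimizer loop, 201 for final reporting and verification.  The integrands
  are smooth, so the quadrature is exact to machine precision at these
  orders; a dense midpoint-rule oracle agrees entrywise to 1e-6 in the
  tests.
- The unrestricted two-point offset (≈1.5434) is recomputed at import by
  maximizing `ν(c)·c` at a = 1, b = 0 to 1e-10 and reused through the
  `b ± c/a` invariance.
- Intervals with mass below 1e-4 are pruned from reports; coinciding
  boundaries of the same item are merged.
- `s = 0` is accepted as a limiting request and returns the unrestricted
  two-point design.
- Ties: if several items share the smallest discrimination at s = 1, the
  first in the list receives the tails (a warning is emitted); ordering
  ties in the enumeration are broken by enumeration order.

## Reference scenarios and what they show

The bundled scenarios (`irtcalib.scenarios`) fix three benchmark items —
(1, 0.5), (1.5, −1.2), (1.6, 2) — under a standard normal population and
compare computed designs against reference interval endpoints, masses and
efficiencies with explicit tolerances (±0.02 abilities, ±0.15–0.25
percentage points, ±0.5 pp on sample-size gains).  Far-tail endpoints
(e.g. an upper boundary near 5.4, beyond which the population mass is
~1e-8) are not compared: the criterion is numerically flat there and the
endpoint is unidentifiable; the interval mass is compared instead.

Two reference values deserve a note.  In the three-item whole-population
scenario the reported interval masses total 100.3 %, which is impossible at
s = 1; the fixture asserts the mass implied by the reported boundary 1.513
(6.51 %) instead of the printed 6.82 %.  And the reported collapse of the
central item's design to a single interval at s = 0.96 is inconsistent
with the reference efficiency table: the two-interval design with a small
interior gap that this package finds at s ≥ 0.9 reproduces the table's
RE_D values to four decimals, beats the best single interval by 6 % in
det M, and passes the equivalence check (which rejects the single
interval).  The package keeps the verified two-interval answer; for the
hard item the collapse to one interval is detected between s = 0.58 and
0.60.

These scenarios exercise deterministic numerical reproduction, not
statistical behaviour: passing them shows the optimizer and verifier
recover known optima, not that locally optimal designs are robust to
misspecified item parameters on real data.

## Known limitations

- D-optimality only (the criterion interface is internal; A-, E-, L-
  criteria are not implemented).
- 2PL only: no guessing parameter, no multidimensional ability.
- Abilities are treated as known when the design is applied; estimation
  error in operational ability estimates is outside the model.
- For n ≥ 3 the ordering enumeration grows as a multinomial coefficient;
  the cap (500) covers n = 3, K = 2 (90 orderings) comfortably but a large
  bank must be handled by blocking, not by joint optimization.
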