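# Methods

## Model

Each agent carries two emotional parameters, both dimensionless and
confined to [0, 1]: an intensity λ, measured as a fraction of the unit
pot, and an arousal threshold τ on the deviation |2x − 1| of a share x
from the even split.  Utility is the material share plus a signed
emotion term, u(x) = x + v(x)·a(x), with valence v(x) = sign(x − 1/2)
and arousal a(x) = λ once |2x − 1| > τ (the threshold case is
inclusive: a deviation exactly equal to τ leaves the agent calm, and
the valence at x = 1/2 is exactly zero, compared without an epsilon
band since shares are user-specified values).  Below the even split
this makes utility x − λ on [0, (1 − τ)/2) and x on [(1 − τ)/2, 1/2),
so the minimum acceptable offer (MAO) — the smallest share with
non-negative utility — is min((1 − τ)/2, λ).  An offer exactly equal to
the MAO is accepted.  Proposers use the self-projection heuristic:
assume the responder's parameters equal your own and offer your own
MAO; a proposer whose MAO is zero therefore offers exactly zero.  The
MAO is strictly below 1/2 except in the closure case λ ≥ 1/2, τ = 0,
where an offer of exactly 1/2 is allowed.

All quantities are fractions of a unit pot.  Multiplying by a monetary
pot size is presentation only and never enters the model: the model has
no mechanism for pot-size effects on behaviour.

## From parameter distribution to offers

With offers equal to MAOs, the population offer is the transformed
random variable S = min((1 − T)/2, Λ).  The engine never represents the
Dirac components of this min() transformation numerically; it uses the
analytically reduced forms.  For independent marginals with densities,

    p(s) = f_Λ(s) F_T(1 − 2s) + 2 f_T(1 − 2s) (1 − F_Λ(s)),

and for any independent joint — including marginals with atoms — the
acceptance curve comes from the survival identity (rejection means both
Λ > s and (1 − T)/2 > s):

    P(s) = 1 − (1 − F_Λ(s)) F_T(1 − 2s),

which reduces to P(s) = F(1 − 2s)(F(s) − 1) + 1 when both marginals
share one cdf F.  Correlated joints are rejected with an explicit
not-implemented error; the `independent` flag exists so an extension
cannot be silently mishandled.  The proposer's expected payoff is
g(s) = (1 − s)P(s).

## Distribution families

* `uniform` on [0, 1] — the maximally heterogeneous population.
* `normal`, default N(1/2, 1/6) — σ is stored as the full-precision
  float of 1/6, not 0.17; with this σ the interval [0, 1] carries
  99.73% of the mass.  The analytic engine uses the **untruncated**
  normal pdf/cdf with no renormalisation, deliberately neglecting the
  0.27% of mass outside the parameter range; the simulator instead
  clips sampled values into [0, 1] (clipping rather than re-sampling
  keeps the sample size exact).  The two conventions disagree by at
  most a few tenths of a percentage point, inside every reporting
  tolerance used here; one visible trace is that the analytic P(1/2)
  is 0.9993 rather than exactly 1.
* `table` — an empirical marginal from observed values: ECDF for the
  cdf, a fixed 100-bin histogram for the density, bootstrap resampling
  for draws.  Intended for plugging measured emotion parameters into
  the model.
* `point` — a degenerate point mass for limiting cases; it has no
  density, and everything involving it goes through the cdf.

## Numerical choices

* Median offer: smallest s with P(s) ≥ 1/2, by bisection on [0, 1/2] to
  1e-9.  The ≥ convention is what makes the definition well-posed for
  step-shaped acceptance curves from degenerate populations.
* Mean offer: adaptive quadrature of s·p(s) (relative tolerance 1e-8)
  when densities exist; otherwise the equivalent survival integral of
  1 − P(s), by midpoint sum at step 1e-5.
* Mode: argmax of p on a step-1e-4 grid with local bounded refinement,
  ties toward the smaller s; for atomic populations, the centre of the
  1-percentage-point bin carrying the most mass.
* Optimal offer s*: grid argmax of g followed by bounded scalar
  maximisation in the winning cell (xatol 1e-8), ties toward the
  smaller s; a flat payoff curve returns the smallest maximiser with a
  warning.
* Percent reporting: nearest percent, half-up, applied only at report
  time; raw floats are always carried alongside.  Values are snapped to
  9 decimals before rounding so that a mathematically exact half-way
  case (e.g. the uniform population's 5.5% rejection rate at the 45%
  threshold) cannot be flipped by binary representation noise.
* Statistic conventions: "offers in range 1–10%" is the cumulative
  P(0.10) — the interval convention P(0.10) − P(0.01) would give 25%
  rather than the 28% the cumulative one yields for the uniform
  population; "rejection in range 1–20%" is the survival 1 − P(0.20);
  "rejection in range 40–50%" is evaluated at the 45% midpoint,
  1 − P(0.45), i.e. the proportion of responders who only accept offers
  above 45%.  "Offers in range 50–100%" is structurally zero (every MAO
  is ≤ 1/2); its raw value reports the analytic leakage of the
  untruncated normal above 1/2, at most a few hundredths of a percent.

## Randomness

One root seed per run.  The joint sampler splits it into one child
stream per marginal via `SeedSequence.spawn`, so λ draws are unaffected
by the τ family and vice versa.  The simulator's pairing stream is
separate from the population seed.  Same spec + seed is bit-identical
across runs.

## Simulator conventions

The underlying analysis is one-shot and never specifies a matching, so
the simulator's conventions are package decisions: agents are paired by
a uniform random perfect matching each round, roles within a pair are
assigned by a fair coin from the pairing stream, and an odd population
leaves the last agent of the shuffled order out of the round.  The
empirical summary uses 1-percentage-point histogram bins for the mode
(matching report granularity) and maximises (1 − s)·ECDF(s) on a 0.1%
grid for the empirical optimal offer.

The simulator is the designated brute-force oracle: it shares no code
with the analytic transforms (it only samples agents and counts), so
agreement — empirical MAO cdf within Kolmogorov–Smirnov distance 3/√n
of P(s) at n = 1e5, empirical summary within one percentage point of
the analytic one — is a genuine cross-validation.  What the synthetic
populations do *not* emulate is real behavioural data: offers here are
deterministic functions of (λ, τ), there is no decision noise, no
learning, no history, and no correlation between the two parameters.
Passing tests therefore validate the mathematics of the model, not its
fit to human play.

## Known limitations and open points

* The payoff-maximising offer for the N(1/2, 1/6) population computes
  to s* ≈ 0.369 (37%), noticeably above the population's central
  offers; the engine reports the computed maximiser.  (For the uniform
  population s* = (10 − √28)/12 ≈ 39.2% exactly.)
* The N(1/2, 1/6) modal offer falls at 24.46%, essentially on the 24/25
  rounding boundary; the raw value is reported alongside the rounded
  one, and boundary statistics (the mode, the rejection rate at 45%)
  should be read with ±1 percentage point in mind.
* Proposer and responder roles draw from one population with one
  parameter distribution; separate role-specific distributions are not
  modelled.
* No evolutionary dynamics over (λ, τ), no fitting of the parameter
  distribution to experimental UG data, no repeated play or
  reputation — all deliberately out of scope.
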