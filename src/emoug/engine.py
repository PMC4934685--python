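"""Analytic engine: from a parameter distribution to offers and payoffs.

With proposers offering their own MAO, the population offer ``S`` is the
transformed random variable ``min((1 - T)/2, L)`` of the emotional
parameters ``(L, T)``.  For independent marginals with densities
``f_L, f_T`` and cdfs ``F_L, F_T`` the offer density on [0, 1/2] is

    p(s) = f_L(s) F_T(1 - 2s) + 2 f_T(1 - 2s) (1 - F_L(s))

and the acceptance curve — the probability that a random responder's
MAO is at most ``s``, which is also the offer cdf — is

    P(s) = 1 - (1 - F_L(s)) F_T(1 - 2s)

the survival form of the MAO definition: an offer is rejected only when
both ``L > s`` and ``(1 - T)/2 > s``.  When both parameters share one
cdf ``F`` this reduces to the closed form

    P(s) = F(1 - 2s) (F(s) - 1) + 1

Point masses in the parameter distribution are never represented as
numerical Dirac deltas: everything with atoms goes through the cdf.

The proposer's expected payoff is ``g(s) = (1 - s) P(s)``; its argmax
over [0, 1/2] is the optimal offer ``s*``.  ``summary_table`` collects
the statistics conventionally reported for Ultimatum Game populations:
modal/median/mean offer, the share of offers at or below 10% of the
pot, the share above 50% (structurally zero here, since MAO <= 1/2),
the rejection rate of offers up to 20%, the rejection rate for the
40-50% band (evaluated at the 45% midpoint: the proportion of
responders who would only accept offers greater than 45%), and ``s*``.
All percentages are computed at full precision and rounded to the
nearest percent (half-up) only at report time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy import integrate, optimize

from emoug.distributions import JointParameterDistribution

__all__ = [
    "OfferCurves",
    "SummaryTable",
    "offer_density",
    "acceptance_curve",
    "expected_payoff",
    "compute_curves",
    "optimal_offer",
    "median_offer",
    "mean_offer",
    "modal_offer",
    "summary_table",
    "round_half_up",
]

#: Row labels used in tabular reports, in conventional order.
SUMMARY_LABELS = {
    "modal_offer": "Modal offer",
    "median_offer": "Median offer",
    "mean_offer": "Mean offer",
    "offers_1_10": "Offers in range 1-10%",
    "offers_50_100": "Offers in range 50-100%",
    "rejection_40_50": "Rejection of offers in range 40-50%",
    "rejection_1_20": "Rejection of offers in range 1-20%",
    "optimal_offer": "Optimal offer",
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves rounding upward.

    The value is first snapped to 9 decimal places so that binary
    representation noise (e.g. a mathematically exact 5.5 arriving as
    5.4999999999999999) cannot flip a half-way case.
    """
    return int(math.floor(round(x, 9) + 0.5))


def _require_independent(joint: JointParameterDistribution) -> None:
    if not joint.independent:
        raise NotImplementedError(
            "only independent (lam, tau) joints are supported"
        )


def _require_densities(joint: JointParameterDistribution) -> None:
    if not (joint.lam_marginal.has_density and joint.tau_marginal.has_density):
        raise ValueError(
            "offer density requires marginals with densities; "
            "distributions with atoms only define the acceptance curve"
        )


def offer_density(joint: JointParameterDistribution, s) -> np.ndarray:
    """Density p(s) of equilibrium offers, on s in [0, 1/2].

    Uses the closed form for independent marginals; the two Dirac
    contributions of the raw min() transformation are already integrated
    out analytically.
    """
    _require_independent(joint)
    _require_densities(joint)
    s = np.asarray(s, dtype=float)
    f_lam = joint.lam_marginal.pdf
    F_lam = joint.lam_marginal.cdf
    f_tau = joint.tau_marginal.pdf
    F_tau = joint.tau_marginal.cdf
    return f_lam(s) * F_tau(1.0 - 2.0 * s) + 2.0 * f_tau(1.0 - 2.0 * s) * (
        1.0 - F_lam(s)
    )


def acceptance_curve(joint: JointParameterDistribution, s) -> np.ndarray:
    """Probability P(s) that a random responder accepts offer s.

    Identical to the offer cdf, since offers equal MAOs under the
    self-projection heuristic.  Valid for any independent joint,
    including marginals with atoms.
    """
    _require_independent(joint)
    s = np.asarray(s, dtype=float)
    F_lam = joint.lam_marginal.cdf
    F_tau = joint.tau_marginal.cdf
    return 1.0 - (1.0 - F_lam(s)) * F_tau(1.0 - 2.0 * s)


@dataclass(frozen=True)
class OfferCurves:
    """Tabulated offer density, acceptance curve and expected payoff.

    ``p`` is None when a marginal carries atoms (no density exists); the
    acceptance curve and payoff are always defined.
    """

    grid: np.ndarray
    p: np.ndarray | None
    P: np.ndarray
    g: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        p = np.full_like(self.grid, np.nan) if self.p is None else self.p
        return pd.DataFrame({"s": self.grid, "p": p, "P": self.P, "g": self.g})


def compute_curves(
    joint: JointParameterDistribution, grid_step: float = 0.001
) -> OfferCurves:
    """Tabulate p, P and g on a uniform offer grid over [0, 1/2]."""
    if not (0.0 < grid_step <= 0.01):
        raise ValueError(f"grid_step must be in (0, 0.01], got {grid_step}")
    n = int(round(0.5 / grid_step))
    grid = np.linspace(0.0, 0.5, n + 1)
    P = acceptance_curve(joint, grid)
    has_density = (
        joint.lam_marginal.has_density and joint.tau_marginal.has_density
    )
    p = offer_density(joint, grid) if has_density else None
    return OfferCurves(grid=grid, p=p, P=P, g=(1.0 - grid) * P)


def expected_payoff(curves: OfferCurves) -> OfferCurves:
    """Recompute the proposer payoff g(s) = (1 - s) P(s) pointwise."""
    return OfferCurves(
        grid=curves.grid,
        p=curves.p,
        P=curves.P,
        g=(1.0 - curves.grid) * curves.P,
    )


CurvesOrJoint = Union[OfferCurves, JointParameterDistribution]


def optimal_offer(source: CurvesOrJoint) -> float:
    """Offer s* maximising the proposer's expected payoff over [0, 1/2].

    Grid argmax (ties broken toward the smallest s) followed, when the
    continuous acceptance curve is available, by bracketed scalar
    maximisation in the winning cell to absolute tolerance 1e-8.  A flat
    payoff curve (degenerate population rejecting everything below 1/2
    or accepting everything) returns the smallest maximiser with a
    warning.
    """
    if isinstance(source, JointParameterDistribution):
        refine: Callable[[float], float] | None = lambda s: -(
            1.0 - s
        ) * float(acceptance_curve(source, s))
        curves = compute_curves(source, grid_step=0.001)
    else:
        refine = None
        curves = source

    g = curves.g
    if np.ptp(g) < 1e-12:
        warnings.warn(
            "expected payoff is flat; returning the smallest maximiser",
            stacklevel=2,
        )
        return float(curves.grid[0])
    k = int(np.argmax(g))
    s0 = float(curves.grid[k])
    if refine is None:
        return s0
    lo = max(0.0, s0 - float(curves.grid[1] - curves.grid[0]))
    hi = min(0.5, s0 + float(curves.grid[1] - curves.grid[0]))
    res = optimize.minimize_scalar(
        refine, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    # keep the grid point if refinement failed to improve (step P etc.)
    return float(res.x) if -res.fun >= g[k] - 1e-12 else s0


def median_offer(joint: JointParameterDistribution) -> float:
    """Smallest s with P(s) >= 1/2.

    For continuous acceptance curves this is the root of P(s) = 1/2,
    found by bisection; the >= convention extends the definition to
    step-shaped P from populations with atoms.
    """
    _require_independent(joint)
    P = lambda s: float(acceptance_curve(joint, s))
    if P(0.0) >= 0.5:
        return 0.0
    lo, hi = 0.0, 0.5
    while hi - lo > 1e-9:
        mid = 0.5 * (lo + hi)
        if P(mid) >= 0.5:
            hi = mid
        else:
            lo = mid
    return hi


def mean_offer(joint: JointParameterDistribution) -> float:
    """First moment of the offer distribution over [0, 1/2].

    Computed as the integral of s p(s) by adaptive quadrature when the
    density exists; populations with atoms use the equivalent
    survival-function integral of 1 - P(s) instead.
    """
    _require_independent(joint)
    if joint.lam_marginal.has_density and joint.tau_marginal.has_density:
        val, _ = integrate.quad(
            lambda s: s * float(offer_density(joint, s)),
            0.0,
            0.5,
            epsrel=1e-8,
            limit=200,
        )
        return val
    # midpoint Riemann sum of the survival function; exact to the grid
    # step for step-shaped P
    step = 1e-5
    mids = np.arange(step / 2.0, 0.5, step)
    return float(np.sum(1.0 - acceptance_curve(joint, mids)) * step)


def modal_offer(joint: JointParameterDistribution) -> float:
    """Mode of the offer distribution on [0, 1/2].

    With densities: argmax of p on a step-1e-4 grid, locally refined;
    ties go to the smallest s.  With atoms: the centre of the 1-percent
    bin carrying the most probability mass.
    """
    _require_independent(joint)
    if joint.lam_marginal.has_density and joint.tau_marginal.has_density:
        grid = np.arange(0.0, 0.5 + 1e-12, 1e-4)
        dens = offer_density(joint, grid)
        k = int(np.argmax(dens))
        lo = max(0.0, grid[k] - 1e-4)
        hi = min(0.5, grid[k] + 1e-4)
        res = optimize.minimize_scalar(
            lambda s: -float(offer_density(joint, s)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x) if -res.fun >= dens[k] else float(grid[k])
    edges = np.arange(-0.005, 0.5051, 0.01)  # bins centred on whole percents
    mass = np.diff(acceptance_curve(joint, edges))
    k = int(np.argmax(mass))
    return float(0.01 * k)


@dataclass(frozen=True)
class SummaryTable:
    """Population summary statistics, on the percent scale (raw floats).

    ``rounded()`` applies nearest-percent half-up rounding; raw values
    keep full precision.  ``offers_50_100`` is the analytic leakage of
    the acceptance curve above the even split — structurally zero for
    parameters confined to [0, 1], and at most a few hundredths of a
    percent for the untruncated normal family.
    """

    modal_offer: float
    median_offer: float
    mean_offer: float
    offers_1_10: float
    offers_50_100: float
    rejection_40_50: float
    rejection_1_20: float
    optimal_offer: float

    _FIELDS = tuple(SUMMARY_LABELS)

    def raw(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self._FIELDS}

    def rounded(self) -> dict[str, int]:
        return {
            name: round_half_up(getattr(self, name)) for name in self._FIELDS
        }

    def to_json_dict(self, spec: dict | None = None) -> dict:
        out = {"raw_percent": self.raw(), "rounded_percent": self.rounded()}
        if spec is not None:
            out["distribution"] = spec
        return out

    def to_markdown(self) -> str:
        rounded = self.rounded()
        lines = ["| Statistic | Value |", "| --- | --- |"]
        for name, label in SUMMARY_LABELS.items():
            lines.append(f"| {label} | {rounded[name]}% |")
        return "\n".join(lines)


def summary_table(joint: JointParameterDistribution) -> SummaryTable:
    """Compute the eight summary statistics for a parameter distribution.

    Conventions: 'offers in range 1-10%' is the cumulative P(0.10);
    'rejection of offers in range 1-20%' is the survival 1 - P(0.20);
    'rejection of offers in range 40-50%' is evaluated at the 45%
    midpoint, 1 - P(0.45).
    """
    _require_independent(joint)
    P = lambda s: float(acceptance_curve(joint, s))
    return SummaryTable(
        modal_offer=100.0 * modal_offer(joint),
        median_offer=100.0 * median_offer(joint),
        mean_offer=100.0 * mean_offer(joint),
        offers_1_10=100.0 * P(0.10),
        offers_50_100=100.0 * max(0.0, 1.0 - P(0.5)),
        rejection_40_50=100.0 * (1.0 - P(0.45)),
        rejection_1_20=100.0 * (1.0 - P(0.20)),
        optimal_offer=100.0 * optimal_offer(joint),
    )
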