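"""Marginal distributions of the emotional parameters and their joint.

Each marginal lives nominally on [0, 1] and exposes a vectorised pdf,
cdf, and seeded sampler.  Four families are provided:

``uniform``
    Flat on [0, 1]; the maximally heterogeneous population.
``normal``
    An *untruncated* normal, by default N(1/2, 1/6).  With sigma = 1/6
    the interval [0, 1] carries 99.73% of the mass, so leakage outside
    the parameter range is negligible and the analytic formulas use the
    plain normal cdf with no renormalisation.  The simulator clips
    sampled values into [0, 1] so that agents remain valid.
``table``
    An empirical distribution built from observed values (ECDF for the
    cdf, a fixed 100-bin histogram for the pdf), for plugging measured
    emotion parameters into the model.
``point``
    A degenerate point mass, mostly useful for limiting cases and tests.

The joint distribution of (lam, tau) is the independent product of two
marginals; sampling splits the root seed into one child stream per
marginal via `numpy.random.SeedSequence.spawn`, so the lam draws are
unaffected by how many tau draws are taken and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "ParameterDistribution",
    "UniformDistribution",
    "NormalDistribution",
    "EmpiricalDistribution",
    "DegenerateDistribution",
    "JointParameterDistribution",
    "make_distribution",
    "make_joint",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]


class ParameterDistribution:
    """Abstract marginal distribution of one emotional parameter.

    Subclasses implement ``pdf``, ``cdf`` and ``sample``; ``has_density``
    is False for families with atoms (point masses), which the analytic
    engine must treat through the cdf only.
    """

    family: str = "abstract"
    has_density: bool = True

    def pdf(self, x: ArrayLike) -> np.ndarray:
        raise NotImplementedError

    def cdf(self, x: ArrayLike) -> np.ndarray:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> dict:
        """JSON-serialisable description of the family and parameters."""
        return {"family": self.family}


class UniformDistribution(ParameterDistribution):
    """Uniform marginal on [0, 1]."""

    family = "uniform"

    def pdf(self, x: ArrayLike) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where((x >= 0.0) & (x <= 1.0), 1.0, 0.0)

    def cdf(self, x: ArrayLike) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(0.0, 1.0, size=n)

    def __repr__(self) -> str:
        return "UniformDistribution()"


class NormalDistribution(ParameterDistribution):
    """Untruncated normal marginal, default N(1/2, 1/6).

    No renormalisation is applied for mass outside [0, 1]; with the
    default sigma that mass is 0.27%.  Samples are returned as drawn
    (possibly outside [0, 1]); clipping to the valid parameter range is
    the caller's decision (the population simulator clips).
    """

    family = "normal"

    def __init__(self, mu: float = 0.5, sigma: float = 1.0 / 6.0) -> None:
        if sigma <= 0.0:
            raise ValueError(f"sigma must be positive, got {sigma}")
        self.mu = float(mu)
        self.sigma = float(sigma)
        self._dist = stats.norm(self.mu, self.sigma)

    def pdf(self, x: ArrayLike) -> np.ndarray:
        return self._dist.pdf(np.asarray(x, dtype=float))

    def cdf(self, x: ArrayLike) -> np.ndarray:
        return self._dist.cdf(np.asarray(x, dtype=float))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size=n)

    def spec(self) -> dict:
        return {"family": self.family, "mu": self.mu, "sigma": self.sigma}

    def __repr__(self) -> str:
        return f"NormalDistribution(mu={self.mu}, sigma={self.sigma})"


class EmpiricalDistribution(ParameterDistribution):
    """Empirical marginal fitted to observed parameter values.

    The cdf is the ECDF of the supplied values; the pdf is a histogram
    density on a fixed 100-bin grid over [0, 1].  Sampling resamples the
    observed values with replacement.
    """

    family = "table"
    _N_BINS = 100

    def __init__(self, values: Sequence[float]) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if np.any((values < 0.0) | (values > 1.0)):
            raise ValueError("observed parameter values must lie in [0, 1]")
        self.values = np.sort(values)
        edges = np.linspace(0.0, 1.0, self._N_BINS + 1)
        counts, _ = np.histogram(self.values, bins=edges)
        self._edges = edges
        self._density = counts / (counts.sum() * (edges[1] - edges[0]))

    def pdf(self, x: ArrayLike) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        idx = np.clip(
            np.searchsorted(self._edges, x, side="right") - 1,
            0,
            self._N_BINS - 1,
        )
        return np.where((x >= 0.0) & (x <= 1.0), self._density[idx], 0.0)

    def cdf(self, x: ArrayLike) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.searchsorted(self.values, x, side="right") / self.values.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.values, size=n, replace=True)

    def spec(self) -> dict:
        return {"family": self.family, "n_values": int(self.values.size)}

    def __repr__(self) -> str:
        return f"EmpiricalDistribution(n={self.values.size})"


class DegenerateDistribution(ParameterDistribution):
    """Point mass at a single parameter value."""

    family = "point"
    has_density = False

    def __init__(self, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"point mass must lie in [0, 1], got {value}")
        self.value = float(value)

    def pdf(self, x: ArrayLike) -> np.ndarray:
        raise NotImplementedError(
            "a point mass has no density; use the cdf"
        )

    def cdf(self, x: ArrayLike) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(x >= self.value, 1.0, 0.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.value)

    def spec(self) -> dict:
        return {"family": self.family, "value": self.value}

    def __repr__(self) -> str:
        return f"DegenerateDistribution(value={self.value})"


_FAMILIES = {
    "uniform": UniformDistribution,
    "normal": NormalDistribution,
    "table": EmpiricalDistribution,
    "point": DegenerateDistribution,
}


def make_distribution(family: str, **params) -> ParameterDistribution:
    """Build a marginal from a family name and family-specific parameters.

    Raises
    ------
    ValueError
        If the family name is unknown (no silent defaults) or the
        parameters are invalid for the family.
    """
    try:
        cls = _FAMILIES[family]
    except KeyError:
        known = ", ".join(sorted(_FAMILIES))
        raise ValueError(f"unknown family {family!r}; expected one of {known}")
    return cls(**params)


@dataclass(frozen=True)
class JointParameterDistribution:
    """Independent joint distribution of (lam, tau).

    The joint density factorises, f(lam, tau) = f_L(lam) f_T(tau).  The
    ``independent`` flag is carried explicitly so that a correlated
    extension would be detected (and rejected) by the analytic engine
    rather than silently mishandled.
    """

    lam_marginal: ParameterDistribution
    tau_marginal: ParameterDistribution
    independent: bool = field(default=True)

    def sample(self, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` iid (lam, tau) pairs, reproducibly.

        The root seed is split into two independent child streams, one
        per marginal.  Values are returned exactly as drawn — normal
        draws may fall outside [0, 1]; clip before constructing agents.
        """
        if n < 1:
            raise ValueError(f"need n >= 1 samples, got {n}")
        lam_ss, tau_ss = np.random.SeedSequence(seed).spawn(2)
        lam = self.lam_marginal.sample(n, np.random.default_rng(lam_ss))
        tau = self.tau_marginal.sample(n, np.random.default_rng(tau_ss))
        return lam, tau

    @property
    def same_marginal(self) -> bool:
        """True when lam and tau share one distribution object or spec."""
        return (
            self.lam_marginal is self.tau_marginal
            or self.lam_marginal.spec() == self.tau_marginal.spec()
        )

    def spec(self) -> dict:
        return {
            "lam": self.lam_marginal.spec(),
            "tau": self.tau_marginal.spec(),
            "independent": self.independent,
        }


def make_joint(
    family: str = "uniform",
    *,
    tau_family: str | None = None,
    lam_params: dict | None = None,
    tau_params: dict | None = None,
    **shared_params,
) -> JointParameterDistribution:
    """Convenience constructor for an independent (lam, tau) joint.

    By default both marginals share one family and parameter set, which
    is the configuration the closed-form same-marginal results apply to.
    """
    lam_kwargs = dict(shared_params)
    lam_kwargs.update(lam_params or {})
    tau_kwargs = dict(shared_params)
    tau_kwargs.update(tau_params or {})
    lam = make_distribution(family, **lam_kwargs)
    tau = make_distribution(tau_family or family, **tau_kwargs)
    return JointParameterDistribution(lam, tau)
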