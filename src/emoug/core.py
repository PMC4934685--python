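"""Pointwise model functions for a single emotional agent.

An agent is a pair ``(lam, tau)`` with both parameters in [0, 1]:
``lam`` is the emotional intensity, measured as a fraction of the unit
pot, and ``tau`` is the arousal threshold, the minimum deviation of
``|2x - 1|`` from the even split required before the emotion fires.

The utility of receiving a share ``x`` of the unit pot is

    u(x) = x + v(x) * a(x; lam, tau)

where the valence ``v(x) = sign(x - 1/2)`` and the arousal
``a(x) = lam`` if ``|2x - 1| > tau`` else ``0`` (the threshold case is
inclusive: a deviation exactly equal to ``tau`` does not arouse).

Shares below the even split with utility still non-negative are
acceptable, which gives the minimum acceptable offer (MAO)

    mao = min((1 - tau) / 2, lam)

A responder accepts any offer at or above her MAO.  A proposer using the
self-projection heuristic assumes the responder's parameters equal her
own and offers exactly her own MAO.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EmotionParams",
    "Allocation",
    "valence",
    "arousal",
    "emotion_term",
    "utility",
    "mao",
    "accepts",
    "self_projection_offer",
]

_ALLOC_TOL = 1e-9


@dataclass(frozen=True)
class EmotionParams:
    """One agent's emotional profile.

    Parameters
    ----------
    lam
        Emotional intensity, a fraction of the unit pot, in [0, 1].
    tau
        Arousal threshold on the deviation ``|2x - 1|``, in [0, 1].
    """

    lam: float
    tau: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")


@dataclass(frozen=True)
class Allocation:
    """A split ``(x_i, x_j)`` of the unit pot, ``x_i + x_j = 1``."""

    x_i: float
    x_j: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_i <= 1.0):
            raise ValueError(f"x_i must lie in [0, 1], got {self.x_i}")
        if abs(self.x_i + self.x_j - 1.0) > _ALLOC_TOL:
            raise ValueError(
                f"shares must sum to 1, got {self.x_i} + {self.x_j}"
            )

    @classmethod
    def from_share(cls, x_i: float) -> "Allocation":
        return cls(x_i, 1.0 - x_i)


def _check_share(x_i: float) -> None:
    if not (0.0 <= x_i <= 1.0):
        raise ValueError(f"share must lie in [0, 1], got {x_i}")


def valence(x_i: float) -> int:
    """Sign of the emotion triggered by receiving share ``x_i``.

    Negative below the even split, zero exactly at it, positive above.
    The comparison with 1/2 is exact: shares are user-specified values,
    not results of floating-point accumulation.
    """
    _check_share(x_i)
    if x_i < 0.5:
        return -1
    if x_i > 0.5:
        return 1
    return 0


def arousal(x_i: float, params: EmotionParams) -> float:
    """Emotional intensity triggered by share ``x_i``.

    Zero while the deviation ``|2 x_i - 1|`` stays at or below the
    threshold ``tau`` (inclusive), otherwise the full intensity ``lam``.
    """
    _check_share(x_i)
    if abs(2.0 * x_i - 1.0) <= params.tau:
        return 0.0
    return params.lam


def emotion_term(x_i: float, params: EmotionParams) -> float:
    """Signed emotional contribution ``v(x) * a(x)`` to utility."""
    return valence(x_i) * arousal(x_i, params)


def utility(x_i: float, params: EmotionParams) -> float:
    """Perceived utility ``x_i + emotion_term`` of receiving ``x_i``."""
    return x_i + emotion_term(x_i, params)


def mao(params: EmotionParams) -> float:
    """Minimum acceptable offer ``min((1 - tau) / 2, lam)``.

    The smallest share with non-negative utility: below ``(1 - tau) / 2``
    the emotion fires and utility drops to ``x - lam``, which is
    non-negative only from ``x = lam`` on; at or above ``(1 - tau) / 2``
    utility is the share itself and any share qualifies.
    """
    return min((1.0 - params.tau) / 2.0, params.lam)


def accepts(offer: float, params: EmotionParams) -> bool:
    """Whether a responder with ``params`` accepts ``offer``.

    Accepting anything at or above the MAO (equality accepts) is the
    dominant responder strategy.
    """
    _check_share(offer)
    return offer >= mao(params)


def self_projection_offer(params: EmotionParams) -> float:
    """Offer made by a proposer projecting her own preferences.

    Lacking information about the responder, the proposer assumes the
    responder's ``(lam, tau)`` equal her own and offers her own MAO.
    May equal 1/2 exactly when ``lam >= 1/2`` and ``tau = 0``; strictly
    below 1/2 whenever ``tau > 0`` or ``lam < 1/2``.
    """
    return mao(params)
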