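"""Generalized-normal mixture with online competitive updates.

The model maintains a one-dimensional mixture of generalized normal
(exponential-power) classes with shared width ``sigma`` and shape ``beta``.
Each incoming feature value is classified to a class and the mixture is
updated by two competing rules:

* the centroid of the selected class moves toward the input by an amount
  proportional to the *a-posteriori* probability of that class
  (``mu_k <- mu_k + gamma * p(c=k|x) * (x - mu_k)``), and
* every mixing probability is nudged by the *conditional likelihood*
  (``pi_k <- pi_k * (1 + eta * (p(x|c=k) - p(x)))``), so the class most
  likely to have generated the input gains mass at the expense of the rest.

A new class is created around inputs whose total mixture density falls
below a threshold ``theta``.  The tension between the posterior-driven
centroid update and the likelihood-driven mixing update is what produces
evidence accumulation and, downstream, bistable switching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GNShape",
    "MixtureState",
    "ModelConfig",
    "DegenerateDensityError",
    "gnorm_pdf",
    "mixture_density",
    "posterior",
    "classify",
    "update_centroid",
    "update_mixing",
    "maybe_create_class",
]

logger = logging.getLogger(__name__)

# Floor for the multiplicative factor in the mixing update; keeps every
# pi_k strictly positive under extreme eta / heavy-tailed density peaks.
FACTOR_FLOOR = 1e-12

# Total mixture density below this is treated as numerically degenerate.
DENSITY_FLOOR = 1e-300


class DegenerateDensityError(ValueError):
    """Raised when the mixture density underflows and no posterior exists."""


@dataclass(frozen=True)
class GNShape:
    """Shape of the (shared) class-conditional generalized normal density.

    Parameters
    ----------
    beta:
        Shape exponent (> 0).  ``beta = 2`` is the normal density,
        ``beta < 2`` gives heavier-than-normal tails.
    sigma:
        Standard deviation of each class, in feature units (> 0).

    The scale ``alpha`` is derived so that the distribution's variance is
    exactly ``sigma**2``: ``alpha = sigma * sqrt(Gamma(1/beta)/Gamma(3/beta))``.
    """

    beta: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def alpha(self) -> float:
        """Scale parameter giving variance ``sigma**2``."""
        b = self.beta
        return self.sigma * math.exp(0.5 * (gammaln(1.0 / b) - gammaln(3.0 / b)))

    @property
    def norm_const(self) -> float:
        """Normalizing constant ``beta / (2 * alpha * Gamma(1/beta))``."""
        b = self.beta
        return b / (2.0 * self.alpha) * math.exp(-gammaln(1.0 / b))


@dataclass
class MixtureState:
    """Belief state: class centroids, mixing probabilities, shared shape."""

    centroids: np.ndarray
    mixing: np.ndarray
    shape: GNShape

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).copy()
        self.mixing = np.asarray(self.mixing, dtype=float).copy()
        if self.centroids.shape != self.mixing.shape or self.centroids.ndim != 1:
            raise ValueError("centroids and mixing must be 1-d arrays of equal length")
        if np.any(self.mixing <= 0):
            raise ValueError("all mixing probabilities must be > 0")
        if abs(self.mixing.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixing probabilities must sum to 1, got {self.mixing.sum()}")

    @property
    def n_classes(self) -> int:
        return len(self.centroids)

    def copy(self) -> "MixtureState":
        return MixtureState(self.centroids.copy(), self.mixing.copy(), self.shape)

    def to_dict(self) -> dict:
        return {
            "centroids": self.centroids.tolist(),
            "mixing": self.mixing.tolist(),
            "beta": self.shape.beta,
            "sigma": self.shape.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureState":
        return cls(
            np.asarray(d["centroids"], dtype=float),
            np.asarray(d["mixing"], dtype=float),
            GNShape(beta=d["beta"], sigma=d["sigma"]),
        )


@dataclass(frozen=True)
class ModelConfig:
    """Dynamics parameters of the online classification process.

    gamma:
        Centroid update rate (dimensionless, >= 0).
    eta:
        Mixing-probability update rate.  Multiplies a density, so it carries
        feature units; the normalized rate ``eta/sigma`` is the scale-free
        quantity (see :attr:`eta_tilde`).
    theta:
        New-class likelihood threshold (density units, >= 0).  With the
        default 0 class creation never triggers; the two-tone simulations
        initialize the mixture with both classes instead.
    p_init:
        Initial mixing probability of a newly created class.
    classification_mode:
        ``"deterministic"`` (argmax of the posterior) or ``"stochastic"``
        (class drawn from the posterior).
    K:
        Switch count for the stochastic percept rule (>= 1): the percept
        flips after K B-elements are classified opposite to the current
        percept within the current phase.
    update_source:
        Which class assignment drives the parameter updates in stochastic
        mode.  ``"percept"`` (default) attributes each element to the stream
        implied by the current percept (integration: everything to class 1;
        segregation: B to class 2), so the mixture tracks the active scene
        interpretation and the evidence variable P(c=2|B) rises during
        integration and falls during segregation; the stochastic draws feed
        only the switch counter.  ``"drawn"`` updates with the drawn class
        itself.
    mixing_update_uses_new_mu:
        Whether the mixing update recomputes the likelihoods with the
        centroid already moved (default) or uses the pre-update centroid.
    counter_mode:
        ``"cumulative"``: opposite-percept classifications accumulate within
        the phase and reset only at a switch.  ``"consecutive"``: a B
        classified consistently with the current percept resets the counter.
    seed:
        Seed for the classification RNG in stochastic mode.
    """

    gamma: float = 0.1
    eta: float = 0.5
    theta: float = 0.0
    p_init: float = 0.001
    classification_mode: Literal["deterministic", "stochastic"] = "deterministic"
    K: int = 1
    update_source: Literal["percept", "drawn"] = "percept"
    mixing_update_uses_new_mu: bool = True
    counter_mode: Literal["cumulative", "consecutive"] = "cumulative"
    prune_floor: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.eta < 0 or self.theta < 0:
            raise ValueError("gamma, eta and theta must be >= 0")
        if not (0 < self.p_init < 1):
            raise ValueError("p_init must be in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.classification_mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown classification_mode {self.classification_mode!r}")
        if self.update_source not in ("percept", "drawn"):
            raise ValueError(f"unknown update_source {self.update_source!r}")

    def delta_tilde(self, delta: float, sigma: float) -> float:
        """Normalized feature separation Δ/σ (scale-free)."""
        return delta / sigma

    def eta_tilde(self, sigma: float) -> float:
        """Normalized mixing update rate η/σ (scale-free)."""
        return self.eta / sigma


def gnorm_pdf(x, mu, shape: GNShape):
    """Generalized normal density ``beta/(2 alpha Gamma(1/beta)) * exp(-|(x-mu)/alpha|^beta)``.

    Vectorized over ``x`` and/or ``mu``.
    """
    z = np.abs((np.asarray(x, dtype=float) - mu) / shape.alpha)
    out = shape.norm_const * np.exp(-(z ** shape.beta))
    if np.ndim(out) == 0:
        return float(out)
    return out


def mixture_density(state: MixtureState, x: float) -> float:
    """Total mixture density ``p(x) = sum_k pi_k p(x|c=k)``."""
    return float(np.dot(state.mixing, gnorm_pdf(x, state.centroids, state.shape)))


def posterior(state: MixtureState, x: float) -> np.ndarray:
    """A-posteriori class probabilities ``p(c=k|x)``; sums to 1.

    Raises
    ------
    DegenerateDensityError
        If the total density underflows (input absurdly far from every
        class), rather than returning NaN posteriors.
    """
    joint = state.mixing * gnorm_pdf(x, state.centroids, state.shape)
    total = joint.sum()
    if not (total > DENSITY_FLOOR):
        raise DegenerateDensityError(
            f"mixture density underflow at x={x}: p(x)={total}"
        )
    return joint / total


def classify(
    state: MixtureState,
    x: float,
    mode: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> int:
    """Classify ``x`` to a class index.

    Deterministic mode returns the argmax of the posterior (lowest index on
    exact ties); stochastic mode draws from the posterior.
    """
    post = posterior(state, x)
    if mode == "deterministic":
        return int(np.argmax(post))
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic classification requires an rng")
        # Inverse-CDF draw from one uniform: keeps the scalar path and the
        # vectorized engine on identical random streams.
        u = rng.random()
        return int(np.searchsorted(np.cumsum(post), u, side="right").clip(0, len(post) - 1))
    raise ValueError(f"unknown classification mode {mode!r}")


def update_centroid(state: MixtureState, k_star: int, x: float, gamma: float) -> MixtureState:
    """Move the selected centroid toward ``x`` by ``gamma * p(c=k*|x) * (x - mu)``."""
    if not (0 <= k_star < state.n_classes):
        raise IndexError(f"class index {k_star} out of range")
    post = posterior(state, x)
    new = state.copy()
    new.centroids[k_star] += gamma * post[k_star] * (x - new.centroids[k_star])
    return new


def update_mixing(state: MixtureState, x: float, eta: float) -> MixtureState:
    """Competitive mixing update ``pi_k <- pi_k [1 + eta (p(x|c=k) - p(x))]``.

    Applied to all classes; conserves ``sum(pi) = 1`` algebraically.  Factors
    are floored at a tiny positive value (with renormalization and a logged
    warning) if an extreme ``eta`` would drive a mixing probability negative.
    """
    lik = gnorm_pdf(x, state.centroids, state.shape)
    px = float(np.dot(state.mixing, lik))
    factors = 1.0 + eta * (lik - px)
    if np.any(factors <= 0):
        logger.warning(
            "mixing-update factor clamped at x=%s (min factor %.3g); "
            "eta may be too large for this density scale", x, factors.min()
        )
        factors = np.maximum(factors, FACTOR_FLOOR)
        new_pi = state.mixing * factors
        new_pi /= new_pi.sum()
    else:
        new_pi = state.mixing * factors
    new = state.copy()
    new.mixing = new_pi
    return new


def maybe_create_class(
    state: MixtureState, x: float, theta: float, p_init: float
) -> MixtureState:
    """Create a new class at ``x`` if the mixture density ``p(x) < theta``.

    The new class gets mixing probability ``p_init``; existing mixing
    probabilities are rescaled by ``1 - p_init``.  No-op when the density
    already covers ``x``.
    """
    if theta <= 0 or mixture_density(state, x) >= theta:
        return state
    new = MixtureState(
        np.append(state.centroids, x),
        np.append(state.mixing * (1.0 - p_init), p_init),
        state.shape,
    )
    return new


def prune_classes(state: MixtureState, floor: float) -> MixtureState:
    """Drop classes with mixing probability below ``floor`` (off by default).

    Keeps at least one class; renormalizes the survivors.
    """
    keep = state.mixing >= floor
    if keep.all():
        return state
    if not keep.any():
        keep[int(np.argmax(state.mixing))] = True
    pi = state.mixing[keep]
    return MixtureState(state.centroids[keep], pi / pi.sum(), state.shape)
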