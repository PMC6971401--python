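"""Shifted- and negative-gamma densities on the bounded confidence scale.

Confidence ratings live on a 10-point scale (1 = certainly face, 10 =
certainly car) and are made continuous by jittering, so the modelled
support is [1, L) with L = 11.  Two mirrored gamma variants cover the two
ends of the scale:

* the *shifted gamma*  ``g(x) = beta^alpha / Gamma(alpha) (x-1)^(alpha-1)
  exp(-beta (x-1))`` with support ``x >= 1`` models face-leaning rating
  components;
* the *negative gamma* ``ng(x) = beta^alpha / Gamma(alpha) (L-x)^(alpha-1)
  exp(-beta (L-x))`` with support ``x <= L`` is its mirror image and
  models car-leaning components.

``beta`` acts as a rate parameter.  The shape parameter is restricted to
``alpha >= 1`` so that every component has a well-defined mode, at
``1 + (alpha-1)/beta`` (shifted) or ``L - (alpha-1)/beta`` (negative).

Which two-component combination applies to a cell of ratings is decided by
the subject's individual decision ``k1`` (the no-cue rating, 1-10) and the
numeric cue code ``k2`` (FF -> 1, neutral FC/CF -> 5, CC -> 10):

====================  ============  ==========================
k1                    k2            family
====================  ============  ==========================
1..5 (face side)      1 or 5        SS, two shifted gammas
6..10 (car side)      10            NN, two negative gammas
1..5                  10            SN, shifted + negative
6..10                 1 or 5        SN, shifted + negative
====================  ============  ==========================
"""

from __future__ import annotations

import numbers

import numpy as np
from scipy import stats

#: Upper end of the jittered confidence scale (known constant).
L = 11.0

#: Mixture family tags: two shifted gammas, two negative gammas, one of each.
FAMILIES = ("SS", "NN", "SN")

#: Component kinds per family ('s' = shifted gamma, 'n' = negative gamma).
FAMILY_KINDS = {"SS": ("s", "s"), "NN": ("n", "n"), "SN": ("s", "n")}

#: Numeric cue codes: the cue variable k2 recodes the displayed cue pair.
CUE_CODES = {"FF": 1, "FC/CF": 5, "CC": 10}


def _check_shape_rate(alpha: float, beta: float) -> None:
    if not alpha >= 1.0:
        raise ValueError(f"shape parameter alpha must be >= 1, got {alpha!r}")
    if not beta > 0.0:
        raise ValueError(f"rate parameter beta must be > 0, got {beta!r}")


def shifted_gamma_pdf(x, alpha: float, beta: float):
    """Density of the gamma distribution translated to support [1, inf).

    Parameters
    ----------
    x : array_like
        Evaluation points; the density is 0 for ``x < 1``.
    alpha : float
        Shape, restricted to ``alpha >= 1`` so the mode exists.
    beta : float
        Rate (> 0).
    """
    _check_shape_rate(alpha, beta)
    return stats.gamma.pdf(x, alpha, loc=1.0, scale=1.0 / beta)


def shifted_gamma_cdf(x, alpha: float, beta: float):
    """CDF companion of :func:`shifted_gamma_pdf`."""
    _check_shape_rate(alpha, beta)
    return stats.gamma.cdf(x, alpha, loc=1.0, scale=1.0 / beta)


def negative_gamma_pdf(x, alpha: float, beta: float, big_l: float = L):
    """Density of the mirror-reflected gamma with support (-inf, L].

    Satisfies ``negative_gamma_pdf(x) == shifted_gamma_pdf(L + 1 - x)``.
    """
    _check_shape_rate(alpha, beta)
    x = np.asarray(x, dtype=float)
    return stats.gamma.pdf(big_l - x, alpha, scale=1.0 / beta)


def negative_gamma_cdf(x, alpha: float, beta: float, big_l: float = L):
    """CDF of the negative gamma: ``P(X <= x) = P(Y >= L - x)`` for gamma Y."""
    _check_shape_rate(alpha, beta)
    x = np.asarray(x, dtype=float)
    return stats.gamma.sf(big_l - x, alpha, scale=1.0 / beta)


def component_pdf(x, kind: str, alpha: float, beta: float, big_l: float = L):
    """Dispatch on the component kind ('s' shifted, 'n' negative)."""
    if kind == "s":
        return shifted_gamma_pdf(x, alpha, beta)
    if kind == "n":
        return negative_gamma_pdf(x, alpha, beta, big_l)
    raise ValueError(f"unknown component kind {kind!r}")


def component_cdf(x, kind: str, alpha: float, beta: float, big_l: float = L):
    if kind == "s":
        return shifted_gamma_cdf(x, alpha, beta)
    if kind == "n":
        return negative_gamma_cdf(x, alpha, beta, big_l)
    raise ValueError(f"unknown component kind {kind!r}")


def component_mode(kind: str, alpha: float, beta: float, big_l: float = L) -> float:
    """Closed-form mode: ``1 + (alpha-1)/beta`` or ``L - (alpha-1)/beta``."""
    _check_shape_rate(alpha, beta)
    if kind == "s":
        return 1.0 + (alpha - 1.0) / beta
    if kind == "n":
        return big_l - (alpha - 1.0) / beta
    raise ValueError(f"unknown component kind {kind!r}")


def select_family(k1: int, k2: int) -> str:
    """Mixture family implied by the individual decision and the cue code.

    ``k1`` in 1..5 is a face-side individual decision, 6..10 car-side;
    ``k2`` is 1 (FF), 5 (neutral) or 10 (CC).  Returns 'SS', 'NN' or 'SN'.
    """
    if not (isinstance(k1, numbers.Integral) and 1 <= k1 <= 10):
        raise ValueError(f"k1 must be an integer in 1..10, got {k1!r}")
    if k2 not in (1, 5, 10):
        raise ValueError(f"k2 must be one of 1, 5, 10, got {k2!r}")
    if k1 <= 5 and k2 in (1, 5):
        return "SS"
    if k1 >= 6 and k2 == 10:
        return "NN"
    return "SN"


def jitter_ratings(ratings, seed=None):
    """Make integer ratings continuous by adding Uniform(0, 1) noise.

    Each rating ``r`` in 1..10 becomes ``r + u`` with ``u ~ U(0, 1)`` i.i.d.,
    so jittered values lie in ``[1, 11) = [1, L)`` and flooring recovers the
    original integers exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ratings = np.asarray(ratings)
    if ratings.size and (
        not np.issubdtype(ratings.dtype, np.integer)
        and not np.allclose(ratings, np.round(ratings))
    ):
        raise ValueError("ratings must be integers")
    r = np.round(ratings).astype(float)
    if r.size and (r.min() < 1 or r.max() > 10):
        raise ValueError("ratings must lie in [1, 10]")
    return r + rng.uniform(0.0, 1.0, size=r.shape)
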