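"""Social-influence metrics derived from fitted rating mixtures.

Given per-cell mixture fits, these functions quantify how far decisions
shifted toward the cue and how strongly each subject conformed:

* a Mahalanobis-type distance between the individual decision k1 and the
  two fitted modes, D = x' Sigma^-1 x with x = (k1 - m1, k1 - m2)' and
  Sigma the across-subject covariance of the mode estimates for that
  (k1, k2) cell (plain squared Euclidean distance when k1 = k2);
* the proportion of decisions between k1 and k2, obtained by integrating
  the fitted density over that interval;
* the confidence gain under a concurring cue: extra mass in the
  own-decision region ([1, 6] for faces, [7, 11] for cars) relative to a
  neutral cue;
* crossover detection: a fitted mode strictly on the opposite side of the
  face/car boundary (6.0 on the jittered scale) from k1, the behavioral
  signature of opinion reversal;
* bootstrap percentile confidence intervals and achieved significance
  levels (ASL: the fraction of bootstrap statistics on the null side of
  zero) for the mean shift and the crossover proportion;
* the social-bias score W_i = (p_i - 0.5) / (sigma / sqrt(n)), a
  one-sample z-type statistic on each subject's average
  proportion-toward-cue p_i, thresholded at 1.96 to select the strongly
  influenced subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Face/car decision boundary on the jittered confidence scale.
DECISION_BOUNDARY = 6.0

#: Own-decision regions used in the concurring-cue comparison.
FACE_REGION = (1.0, 6.0)
CAR_REGION = (7.0, 11.0)


def mode_covariance(m1, m2):
    """2x2 covariance of the mode estimates across subjects of one cell."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.size != m2.size or m1.size < 2:
        raise ValueError("need >= 2 subjects with both modes")
    return np.cov(np.vstack([m1, m2]))


def shift_distance(k1, k2, m1_i, m2_i, sigma=None):
    """Quadratic-form distance of the fitted modes from the individual decision.

    With x = (k1 - m1_i, k1 - m2_i)': returns x'x when k1 = k2 and
    x' Sigma^-1 x otherwise.  A singular Sigma is ridge-regularized with a
    warning.
    """
    x = np.array([k1 - m1_i, k1 - m2_i], dtype=float)
    if k1 == k2:
        return float(x @ x)
    if sigma is None:
        raise ValueError("Sigma is required when k1 != k2")
    sigma = np.asarray(sigma, dtype=float)
    try:
        inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular mode covariance; using ridge-regularized inverse")
        inv = np.linalg.inv(sigma + 1e-8 * np.trace(sigma) * np.eye(2) + 1e-12 * np.eye(2))
    return float(x @ inv @ x)


@dataclass
class BootstrapResult:
    statistic: float
    ci_low: float
    ci_high: float
    asl: float
    n_boot: int


def bootstrap_mean_shift(values, n_boot: int = 10000, seed=None,
                         ci: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap CI and ASL for 'mean shift > 0'.

    The ASL is the fraction of bootstrap means on the null side
    (<= 0), per the percentile achieved-significance-level convention.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(int(n_boot), v.size))
    means = v[idx].mean(axis=1)
    a = (1.0 - ci) / 2.0
    lo, hi = np.quantile(means, [a, 1.0 - a])
    return BootstrapResult(float(v.mean()), float(lo), float(hi),
                           float(np.mean(means <= 0.0)), int(n_boot))


def proportion_toward_cue(fit, k1, k2):
    """Fitted-density mass on the interval between k1 and k2.

    Returns NaN when k1 == k2 (no interval to integrate over).
    """
    if k1 == k2:
        return float("nan")
    lo, hi = sorted((float(k1), float(k2)))
    return float(fit.cdf(hi) - fit.cdf(lo))


def _region_mass(fit, region):
    lo, hi = region
    return float(fit.cdf(hi) - fit.cdf(lo))


def concurrence_gain(fit_concurring, fit_neutral, decision_side: str):
    """Extra own-region mass under a concurring vs a neutral cue.

    ``decision_side`` 'face' uses region [1, 6]; 'car' uses [7, 11].
    Positive values mean the concurring cue increased decision confidence.
    """
    if decision_side == "face":
        region = FACE_REGION
    elif decision_side == "car":
        region = CAR_REGION
    else:
        raise ValueError("decision_side must be 'face' or 'car'")
    return _region_mass(fit_concurring, region) - _region_mass(fit_neutral, region)


def detect_crossover(fit, k1, boundary: float = DECISION_BOUNDARY):
    """Whether a fitted mode lies on the opposite side of the boundary from k1.

    Returns ``(crossover, crossover_mass)`` where the mass is the weight
    of the crossing component times its own mass beyond the boundary.
    """
    own_face_side = k1 <= 5
    crossover = False
    mass = 0.0
    for j, m in enumerate(fit.component_modes()):
        opposite = (m > boundary) if own_face_side else (m < boundary)
        if opposite:
            crossover = True
            w = fit.weights[j]
            if own_face_side:
                beyond = 1.0 - float(fit.component_cdf(j, boundary))
            else:
                beyond = float(fit.component_cdf(j, boundary))
            mass += w * beyond
    return crossover, mass


def crossover_asl(indicators, n_boot: int = 10000, seed=None) -> BootstrapResult:
    """Bootstrap ASL for 'crossover proportion > 0' across a cohort.

    All-false indicators give ASL 1 (every resampled proportion sits on
    the null); all-true give ASL 0.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ind = np.asarray(indicators, dtype=float)
    if ind.size < 2:
        raise ValueError("need >= 2 indicators")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ind.size, size=(int(n_boot), ind.size))
    props = ind[idx].mean(axis=1)
    lo, hi = np.quantile(props, [0.025, 0.975])
    return BootstrapResult(float(ind.mean()), float(lo), float(hi),
                           float(np.mean(props <= 0.0)), int(n_boot))


@dataclass
class SocialBiasRanking:
    """Cohort-level social-bias scores and the selected subject set."""

    scores: np.ndarray  # W_i per subject
    ranking: np.ndarray  # subject indices, most influenced first
    selected: np.ndarray  # boolean, W_i > threshold
    threshold: float
    degenerate: bool  # sigma == 0 across the cohort


def social_bias_scores(p_values, threshold: float = 1.96) -> SocialBiasRanking:
    """Standardize average proportions-toward-cue into social-bias scores.

    W_i = (p_i - 0.5) / (sigma / sqrt(n)) with sigma the sample SD of the
    p_i and n the number of subjects with a valid p_i.  Subjects with
    W_i > 1.96 shifted toward the cue significantly more than chance.
    """
    p = np.asarray(p_values, dtype=float)
    valid = np.isfinite(p)
    n = int(valid.sum())
    if n < 2:
        raise ValueError("need >= 2 subjects with valid proportions")
    sigma = float(np.std(p[valid], ddof=1))
    if sigma == 0.0:
        w = np.full(p.shape, np.nan)
        w[valid] = 0.0
        ranking = np.flatnonzero(valid)
        return SocialBiasRanking(w, ranking, np.zeros(p.shape, bool), threshold, True)
    w = np.full(p.shape, np.nan)
    w[valid] = (p[valid] - 0.5) / (sigma / np.sqrt(n))
    ranking = np.argsort(np.where(valid, w, -np.inf))[::-1][:n]
    selected = np.zeros(p.shape, dtype=bool)
    selected[valid] = w[valid] > threshold
    return SocialBiasRanking(w, ranking, selected, threshold, False)
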