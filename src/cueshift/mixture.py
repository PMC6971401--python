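"""Two-component gamma-variant mixtures fit by EM with Newton-Raphson M-steps.

The model for a cell of jittered confidence ratings is a convex mixture

    f(x) = p f1(x) + (1 - p) f2(x)

whose components are shifted and/or negative gammas depending on the
family ('SS', 'NN', 'SN'; see :func:`cueshift.distributions.select_family`).
Maximum-likelihood estimation uses EM: the E-step computes standard
responsibilities, and each M-step performs a weighted gamma MLE on the
transformed values ``y = x - 1`` (shifted component) or ``y = L - x``
(negative component), solving

    ln(alpha) - psi(alpha) = ln(mean_w y) - mean_w(ln y)

for the shape by a safeguarded Newton-Raphson iteration (bisection
fallback), then setting the rate ``beta = alpha / mean_w(y)``.  Shapes are
projected onto [1, 1e6] so component modes stay defined; given a projected
shape, the rate update above remains the conditional MLE.

A two-component Gaussian mixture on the same data serves as the baseline
model for likelihood-ratio comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.mixture import GaussianMixture as _SkGaussianMixture

from .distributions import (
    FAMILY_KINDS,
    L,
    component_cdf,
    component_mode,
    component_pdf,
    select_family,
)

#: Cells with at most this many observations are not fit.
MIN_CELL_SIZE = 10

_ALPHA_MAX = 1e6
_Y_FLOOR = 1e-12  # clamp for transformed values that hit the boundary exactly


# ---------------------------------------------------------------------------
# containers


@dataclass
class RatingCell:
    """All jittered confidence responses of one subject for one (k1, k2).

    ``k1`` is the individual (no-cue) decision 1..10, ``k2`` the cue code
    (1, 5 or 10), ``x`` the jittered ratings in [1, L).  This is the unit
    the mixture model is fit to; cells need more than
    :data:`MIN_CELL_SIZE` observations.
    """

    subject_id: str
    k1: int
    k2: int
    x: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.size and (self.x.min() < 1.0 or self.x.max() > L):
            raise ValueError("cell values must lie in [1, L]")

    @property
    def family(self) -> str:
        return select_family(self.k1, self.k2)

    @property
    def fittable(self) -> bool:
        return self.x.size > MIN_CELL_SIZE


@dataclass
class MixtureFit:
    """Fitted two-component gamma-variant mixture.

    Components are ordered so that ``mode1 <= mode2`` for SS/NN; for SN the
    shifted component always comes first (its mode is the smaller one by
    construction of the family rules).  ``p`` is the weight of component 1.
    """

    family: str
    p: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    loglik: float
    n_obs: int
    converged: bool = True
    n_iter: int = 0
    big_l: float = L
    loglik_trace: np.ndarray = field(default=None, repr=False)

    @property
    def kinds(self):
        return FAMILY_KINDS[self.family]

    @property
    def params(self):
        return ((self.alpha1, self.beta1), (self.alpha2, self.beta2))

    @property
    def weights(self):
        return (self.p, 1.0 - self.p)

    def component_modes(self):
        """Modes in component order (not sorted)."""
        return tuple(
            component_mode(k, a, b, self.big_l)
            for k, (a, b) in zip(self.kinds, self.params)
        )

    @property
    def modes(self):
        """Component modes sorted ascending, ``(m1, m2)``."""
        return tuple(sorted(self.component_modes()))

    @property
    def m1(self) -> float:
        return self.modes[0]

    @property
    def m2(self) -> float:
        return self.modes[1]

    def component_pdf(self, j: int, x):
        a, b = self.params[j]
        return component_pdf(x, self.kinds[j], a, b, self.big_l)

    def component_cdf(self, j: int, x):
        a, b = self.params[j]
        return component_cdf(x, self.kinds[j], a, b, self.big_l)

    def pdf(self, x):
        return self.p * self.component_pdf(0, x) + (1.0 - self.p) * self.component_pdf(1, x)

    def cdf(self, x):
        return self.p * self.component_cdf(0, x) + (1.0 - self.p) * self.component_cdf(1, x)

    def ppf(self, q):
        """Numerical quantile function on [1, L] (scalar or vector q)."""
        scalar = np.isscalar(q)
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        out = np.empty_like(qs)
        lo, hi = 1.0, self.big_l
        c_lo, c_hi = self.cdf(lo), self.cdf(hi)
        for i, qi in enumerate(qs):
            if qi <= c_lo:
                out[i] = lo
            elif qi >= c_hi:
                out[i] = hi
            else:
                out[i] = optimize.brentq(lambda t: self.cdf(t) - qi, lo, hi, xtol=1e-10)
        return float(out[0]) if scalar else out

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw n values, rejection-sampled into [1, L]."""
        from .simulate import simulate_cell  # local import to avoid a cycle

        return simulate_cell(
            self.family, self.p, self.alpha1, self.beta1, self.alpha2, self.beta2,
            n, seed=seed, big_l=self.big_l,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("loglik_trace")
        d["m1"], d["m2"] = self.modes
        return d


@dataclass
class GaussianFit:
    """Two-component Gaussian mixture baseline (components sorted by mean)."""

    p: float
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    n_obs: int
    converged: bool = True

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        z1 = np.exp(-0.5 * ((x - self.mu1) / self.sigma1) ** 2) / (
            self.sigma1 * np.sqrt(2 * np.pi)
        )
        z2 = np.exp(-0.5 * ((x - self.mu2) / self.sigma2) ** 2) / (
            self.sigma2 * np.sqrt(2 * np.pi)
        )
        return self.p * z1 + (1.0 - self.p) * z2


# ---------------------------------------------------------------------------
# EM internals


def _comp_logpdf(x, kind, alpha, beta, big_l=L):
    """Fast log-density used inside the EM loop (no scipy dispatch)."""
    y = x - 1.0 if kind == "s" else big_l - x
    out = np.full(y.shape, -np.inf)
    pos = y > 0
    if alpha == 1.0:
        valid = y >= 0
        out[valid] = np.log(beta) - beta * y[valid]
        return out
    out[pos] = (
        alpha * np.log(beta)
        - special.gammaln(alpha)
        + (alpha - 1.0) * np.log(y[pos])
        - beta * y[pos]
    )
    return out


def _weighted_gamma_mle(y, w):
    """Weighted gamma MLE with the shape projected onto [1, 1e6].

    Solves ``ln(alpha) - psi(alpha) = s`` with
    ``s = ln(mean_w y) - mean_w(ln y)`` by Newton-Raphson from the standard
    closed-form starting point, with a bisection fallback; then
    ``beta = alpha / mean_w(y)``.
    """
    w_sum = w.sum()
    if w_sum <= 1e-12:
        return None  # collapsed component: caller keeps previous params
    y = np.maximum(y, _Y_FLOOR)
    ybar = float(np.dot(w, y) / w_sum)
    logbar = float(np.dot(w, np.log(y)) / w_sum)
    s = np.log(ybar) - logbar
    if s <= 1e-12:
        alpha = _ALPHA_MAX
    else:
        alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
        ok = False
        for _ in range(60):
            h = np.log(alpha) - special.digamma(alpha) - s
            if abs(h) < 1e-12:
                ok = True
                break
            hp = 1.0 / alpha - special.polygamma(1, alpha)
            step = h / hp
            new = alpha - step
            if not np.isfinite(new) or new <= 0:
                new = alpha / 2.0 if h < 0 else alpha * 2.0
            alpha = min(max(new, 1e-8), _ALPHA_MAX)
        else:
            ok = abs(np.log(alpha) - special.digamma(alpha) - s) < 1e-8
        if not ok:
            # h is strictly decreasing in alpha: bisection always works
            f = lambda a: np.log(a) - special.digamma(a) - s
            try:
                alpha = optimize.brentq(f, 1e-8, _ALPHA_MAX)
            except ValueError:
                alpha = _ALPHA_MAX if f(_ALPHA_MAX) > 0 else 1e-8
    alpha = min(max(alpha, 1.0), _ALPHA_MAX)
    beta = alpha / ybar
    return alpha, beta


def _em_run(x, kinds, init, max_iter, tol, big_l=L):
    """One EM run from a given initialization; returns params + trace."""
    p, (a1, b1), (a2, b2) = init
    trace = []
    converged = False
    ll = -np.inf
    for it in range(max_iter):
        l1 = _comp_logpdf(x, kinds[0], a1, b1, big_l)
        l2 = _comp_logpdf(x, kinds[1], a2, b2, big_l)
        m = np.maximum(l1, l2)
        m = np.where(np.isfinite(m), m, 0.0)
        f1 = p * np.exp(l1 - m)
        f2 = (1.0 - p) * np.exp(l2 - m)
        den = f1 + f2
        ll_new = float(np.sum(np.log(np.maximum(den, 1e-300)) + m))
        trace.append(ll_new)
        if it > 0 and abs(ll_new - ll) <= tol * max(1.0, abs(ll_new)):
            converged = True
            ll = ll_new
            break
        ll = ll_new
        r = f1 / np.maximum(den, 1e-300)
        p = float(np.clip(r.mean(), 1e-6, 1.0 - 1e-6))
        y1 = x - 1.0 if kinds[0] == "s" else big_l - x
        y2 = x - 1.0 if kinds[1] == "s" else big_l - x
        upd1 = _weighted_gamma_mle(y1, r)
        upd2 = _weighted_gamma_mle(y2, 1.0 - r)
        if upd1 is not None:
            a1, b1 = upd1
        if upd2 is not None:
            a2, b2 = upd2
    return p, a1, b1, a2, b2, ll, converged, len(trace), np.asarray(trace)


def _moment_init(y):
    """Method-of-moments gamma parameters on transformed values."""
    y = np.maximum(y, _Y_FLOOR)
    m = float(y.mean())
    v = float(y.var()) + 1e-6
    a = float(np.clip(m * m / v, 1.0, 1e4))
    b = float(np.clip(m / v, 1e-4, 1e4))
    return a, b


def _initializations(x, kinds, rng, n_restarts, big_l=L):
    """Bimodal-aware base init plus seeded random perturbations.

    The base split point is the midpoint between the two largest histogram
    peaks (unit bins on [1, L]); fallback is the median.  Each side is
    summarized by method-of-moments on the component's own transform, and
    the initial mixing weight is the left-mass fraction.
    """
    counts, edges = np.histogram(x, bins=np.linspace(1.0, big_l, 11))
    centers = 0.5 * (edges[:-1] + edges[1:])
    order = np.argsort(counts)[::-1]
    i, j = sorted(order[:2])
    if counts[j] == 0 or j - i < 2:
        split = float(np.median(x))
    else:
        split = float(0.5 * (centers[i] + centers[j]))
    left = x[x < split]
    right = x[x >= split]
    if left.size < 2 or right.size < 2:
        split = float(np.median(x))
        left, right = x[x < split], x[x >= split]
    if left.size < 2 or right.size < 2:
        left = right = x
    sides = (left, right)
    base = []
    for k, side in zip(kinds, sides):
        y = side - 1.0 if k == "s" else big_l - side
        base.append(_moment_init(y))
    p0 = float(np.clip(left.size / x.size, 0.05, 0.95))
    inits = [(p0, base[0], base[1])]
    for _ in range(n_restarts):
        pert = []
        for a, b in base:
            fa, fb = rng.lognormal(0.0, 0.35, size=2)
            pert.append(
                (float(np.clip(a * fa, 1.0, 1e4)), float(np.clip(b * fb, 1e-4, 1e4)))
            )
        pp = float(np.clip(p0 + rng.uniform(-0.25, 0.25), 0.05, 0.95))
        inits.append((pp, pert[0], pert[1]))
    return inits


def _order_components(family, p, a1, b1, a2, b2, big_l=L):
    """Sort same-kind components by mode; SN keeps (shifted, negative)."""
    kinds = FAMILY_KINDS[family]
    if kinds[0] == kinds[1]:
        m1 = component_mode(kinds[0], a1, b1, big_l)
        m2 = component_mode(kinds[1], a2, b2, big_l)
        if m1 > m2:
            return 1.0 - p, a2, b2, a1, b1
    return p, a1, b1, a2, b2


# ---------------------------------------------------------------------------
# estimators


class GammaVariantMixture(DensityMixin, BaseEstimator):
    """Two-component shifted/negative-gamma mixture density estimator.

    Parameters
    ----------
    family : {'SS', 'NN', 'SN'}
        Component combination (see :func:`select_family`).
    n_restarts : int
        Number of seeded random perturbations of the bimodal-aware
        initializer; the best final likelihood across the base init and
        all restarts is kept.
    max_iter : int
        EM iteration cap per restart.
    tol : float
        Relative log-likelihood change declaring convergence.
    random_state : int or Generator, optional
        Seeds restart perturbations only; EM itself is deterministic
        given data and initialization.

    Attributes
    ----------
    weights_ : ndarray of shape (2,)
        Mixing weights ``(p, 1-p)``.
    alphas_, betas_ : ndarray of shape (2,)
        Component shapes and rates.
    modes_ : ndarray of shape (2,)
        Component modes (ascending).
    loglik_ : float
        Log-likelihood at the returned optimum.
    converged_ : bool
    fit_ : MixtureFit
        Full fit record (also returned by :func:`fit_em`).
    """

    def __init__(self, family="SS", n_restarts=5, max_iter=500, tol=1e-8,
                 random_state=None):
        self.family = family
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size <= MIN_CELL_SIZE:
            raise ValueError(
                f"mixture fitting requires more than {MIN_CELL_SIZE} observations, "
                f"got {x.size}"
            )
        if self.family not in FAMILY_KINDS:
            raise ValueError(f"unknown family {self.family!r}")
        if not np.all(np.isfinite(x)):
            raise ValueError("data must be finite")
        kinds = FAMILY_KINDS[self.family]
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        best = None
        for init in _initializations(x, kinds, rng, self.n_restarts):
            out = _em_run(x, kinds, init, self.max_iter, self.tol)
            if np.isfinite(out[5]) and (best is None or out[5] > best[5]):
                best = out
        if best is None:  # every restart diverged: report a flagged failure
            self.fit_ = MixtureFit(
                self.family, np.nan, np.nan, np.nan, np.nan, np.nan,
                -np.inf, x.size, converged=False,
            )
            self.converged_ = False
            return self
        p, a1, b1, a2, b2, ll, conv, n_iter, trace = best
        p, a1, b1, a2, b2 = _order_components(self.family, p, a1, b1, a2, b2)
        self.fit_ = MixtureFit(
            self.family, p, a1, b1, a2, b2, ll, x.size,
            converged=conv, n_iter=n_iter, loglik_trace=trace,
        )
        self.weights_ = np.array([p, 1.0 - p])
        self.alphas_ = np.array([a1, a2])
        self.betas_ = np.array([b1, b2])
        self.modes_ = np.array(self.fit_.modes)
        self.loglik_ = ll
        self.converged_ = conv
        self.n_iter_ = n_iter
        return self

    def pdf(self, x):
        return self.fit_.pdf(x)

    def cdf(self, x):
        return self.fit_.cdf(x)

    def score_samples(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return np.log(np.maximum(self.pdf(x), 1e-300))

    def score(self, X, y=None):
        return float(np.sum(self.score_samples(X)))

    def sample(self, n, seed=None):
        return self.fit_.sample(n, seed=seed)


class GaussianRatingMixture(DensityMixin, BaseEstimator):
    """Two-component Gaussian mixture baseline for model comparison.

    Thin estimator around a 1-D two-component Gaussian mixture fit
    (unconstrained means, positive variances); exposes the same
    pdf/score surface as :class:`GammaVariantMixture`.
    """

    def __init__(self, n_init=5, max_iter=500, tol=1e-8, random_state=None):
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size <= MIN_CELL_SIZE:
            raise ValueError(
                f"mixture fitting requires more than {MIN_CELL_SIZE} observations"
            )
        seed = self.random_state
        if isinstance(seed, np.random.Generator):
            seed = int(seed.integers(2**31 - 1))
        gm = _SkGaussianMixture(
            n_components=2, n_init=self.n_init, max_iter=self.max_iter,
            tol=self.tol, reg_covar=1e-6, random_state=seed,
        ).fit(x[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        w = gm.weights_.ravel()
        order = np.argsort(means)
        means, sds, w = means[order], sds[order], w[order]
        ll = float(gm.score(x[:, None]) * x.size)
        self.fit_ = GaussianFit(
            float(w[0]), float(means[0]), float(sds[0]),
            float(means[1]), float(sds[1]), ll, x.size,
            converged=bool(gm.converged_),
        )
        self.means_ = means
        self.sds_ = sds
        self.weights_ = w
        self.loglik_ = ll
        self.converged_ = bool(gm.converged_)
        return self

    def pdf(self, x):
        return self.fit_.pdf(x)

    def score_samples(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return np.log(np.maximum(self.pdf(x), 1e-300))

    def score(self, X, y=None):
        return float(np.sum(self.score_samples(X)))


# ---------------------------------------------------------------------------
# functional surface


def fit_em(cell, family=None, n_restarts=5, max_iter=500, tol=1e-8, seed=None) -> MixtureFit:
    """Fit the gamma-variant mixture to a cell of jittered ratings.

    ``cell`` may be a :class:`RatingCell` (family inferred from (k1, k2)
    unless given) or a plain array with ``family`` supplied.
    """
    if isinstance(cell, RatingCell):
        x = cell.x
        family = family or cell.family
    else:
        x = np.asarray(cell, dtype=float).ravel()
        if family is None:
            raise ValueError("family must be given when fitting a raw array")
    est = GammaVariantMixture(
        family=family, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
        random_state=seed,
    ).fit(x)
    return est.fit_


def fit_gaussian_mixture(cell, n_init=5, max_iter=500, tol=1e-8, seed=None) -> GaussianFit:
    """Fit the two-component Gaussian baseline to a cell of ratings."""
    x = cell.x if isinstance(cell, RatingCell) else np.asarray(cell, dtype=float).ravel()
    est = GaussianRatingMixture(
        n_init=n_init, max_iter=max_iter, tol=tol, random_state=seed,
    ).fit(x)
    return est.fit_


def modes(fit: MixtureFit):
    """Component modes of a fit, sorted ascending."""
    return fit.modes
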