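"""Goodness of fit, HPDR predictive validation and model comparison.

Three layers of validation for the gamma-variant mixture:

* a Kolmogorov-Smirnov test of each fitted CDF against the empirical CDF,
  with Holm-Bonferroni control of the family-wise error rate across the
  cells tested per subject (the KS p-value uses the standard asymptotic
  null, uncorrected for estimated parameters, which makes acceptance
  conservative);
* 10-fold cross-validated coverage of the 95% highest-probability-density
  region (HPDR): the model is fit on the training folds, the HPDR
  computed, and the fraction of held-out points falling outside it is the
  prediction error;
* a cross-validated likelihood-ratio comparison against a two-component
  Gaussian mixture: per fold, the ratio of held-out likelihoods
  (proposed / Gaussian) of models fit on the training folds; the median
  over folds summarizes the cell.

The HPDR of a density f at level 1 - a is R(f_a) = {x : f(x) >= f_a} with
f_a the largest threshold whose region still holds mass >= 1 - a; for a
bimodal fit it is generally a union of disjoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .distributions import L
from .mixture import MIN_CELL_SIZE, GammaVariantMixture, GaussianRatingMixture, RatingCell


def _cell_data(cell):
    return cell.x if isinstance(cell, RatingCell) else np.asarray(cell, dtype=float).ravel()


def ks_gof(cell, fit):
    """KS statistic and p-value of a fitted mixture against the data.

    D is the supremum distance between the empirical CDF and the fitted
    mixture CDF; the p-value comes from the standard KS null distribution.
    """
    x = _cell_data(cell)
    if x.size == 0:
        raise ValueError("cannot test an empty cell")
    res = stats.kstest(x, fit.cdf)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(pvalues, fwer: float = 0.05):
    """Step-down Holm rejection flags at the given family-wise error rate."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fwer, method="holm")
    return reject


@dataclass
class Hpdr:
    """Highest-probability-density region of a fitted mixture.

    ``intervals`` are disjoint ordered ``(lo, hi)`` pairs within [1, L];
    ``mass`` is the exact probability the fitted CDF assigns to them
    (>= level by construction); ``f_alpha`` the density threshold.
    """

    level: float
    f_alpha: float
    intervals: tuple
    mass: float
    grid_step: float

    def contains(self, x):
        """Membership in the region, inclusive up to half a grid step."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        tol = 0.5 * self.grid_step
        inside = np.zeros(x.shape, dtype=bool)
        for lo, hi in self.intervals:
            inside |= (x >= lo - tol) & (x <= hi + tol)
        return inside if inside.size > 1 else bool(inside[0])


def _intervals_from_mask(grid, mask, step, lo_bound, hi_bound):
    """Contiguous runs of above-threshold grid points, as intervals.

    The true level-set boundary lies between the last included and first
    excluded grid point, so run endpoints are extended by half a step
    (clipped to the domain) rather than truncated at the grid point.
    """
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2] - 1
    return tuple(
        (max(lo_bound, float(grid[i]) - 0.5 * step),
         min(hi_bound, float(grid[j]) + 0.5 * step))
        for i, j in zip(starts, stops)
    )


def hpdr(fit, level: float = 0.95, n_grid: int = 10001) -> Hpdr:
    """Compute the HPDR of a fitted mixture on a regular grid over [1, L].

    The density threshold is located by bisection over the sorted grid
    densities, using the fitted CDF for exact interval masses, so the
    returned region is the smallest grid-resolved level set with mass at
    least ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    big_l = getattr(fit, "big_l", L)
    grid = np.linspace(1.0, big_l, n_grid)
    step = grid[1] - grid[0]
    dens = np.asarray(fit.pdf(grid), dtype=float)
    order = np.argsort(dens)[::-1]
    sorted_dens = dens[order]

    def region(k):
        mask = dens >= sorted_dens[k]
        ivs = _intervals_from_mask(grid, mask, step, 1.0, big_l)
        mass = float(sum(fit.cdf(hi) - fit.cdf(lo) for lo, hi in ivs))
        return ivs, mass

    lo_k, hi_k = 0, n_grid - 1
    ivs_hi, mass_hi = region(hi_k)
    _, mass_lo = region(lo_k)
    if mass_lo >= level:
        hi_k = lo_k
        ivs_hi, mass_hi = region(lo_k)
    while hi_k - lo_k > 1:
        mid = (lo_k + hi_k) // 2
        ivs_m, mass_m = region(mid)
        if mass_m >= level:
            hi_k, ivs_hi, mass_hi = mid, ivs_m, mass_m
        else:
            lo_k = mid
    return Hpdr(level, float(sorted_dens[hi_k]), ivs_hi, mass_hi, float(step))


def cv_hpdr_error(cell, family: str, folds: int = 10, level: float = 0.95,
                  seed=None, n_grid: int = 10001, **fit_kw):
    """Per-fold HPDR prediction error under seeded K-fold cross-validation.

    Each fold fits the mixture on the training part, computes the
    ``level`` HPDR and scores the fraction of held-out points outside it.
    Returns an array of ``folds`` error rates.
    """
    x = _cell_data(cell)
    fam = family or (cell.family if isinstance(cell, RatingCell) else None)
    if x.size * (folds - 1) // folds <= MIN_CELL_SIZE:
        raise ValueError("cell too small for cross-validated fitting")
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    errors = np.empty(folds)
    for f, (tr, te) in enumerate(kf.split(x)):
        fit = GammaVariantMixture(
            family=fam, random_state=int(rng.integers(2**31 - 1)), **fit_kw
        ).fit(x[tr]).fit_
        region = hpdr(fit, level=level, n_grid=n_grid)
        errors[f] = float(np.mean(~region.contains(x[te])))
    return errors


@dataclass
class ModelComparison:
    """Cross-validated likelihood comparison vs the Gaussian baseline."""

    median_ratio: float
    fold_ratios: np.ndarray
    fold_log_ratios: np.ndarray
    n_folds_used: int


def compare_vs_gaussian(cell, family: str, folds: int = 10, seed=None,
                        **fit_kw) -> ModelComparison:
    """Held-out likelihood ratios (gamma-variant / Gaussian) across folds.

    Both models are fit on each training part; the ratio is the product of
    held-out densities.  Folds on which either model fails to produce a
    finite fit are excluded and counted out of ``n_folds_used``.
    """
    x = _cell_data(cell)
    fam = family or (cell.family if isinstance(cell, RatingCell) else None)
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
    log_ratios = []
    for tr, te in kf.split(x):
        s1 = int(rng.integers(2**31 - 1))
        s2 = int(rng.integers(2**31 - 1))
        try:
            gam = GammaVariantMixture(family=fam, random_state=s1, **fit_kw).fit(x[tr])
            gau = GaussianRatingMixture(random_state=s2).fit(x[tr])
        except ValueError:
            continue
        if not np.isfinite(gam.loglik_):
            continue
        log_ratios.append(gam.score(x[te]) - gau.score(x[te]))
    log_ratios = np.asarray(log_ratios)
    ratios = np.exp(np.clip(log_ratios, -700, 700))
    median = float(np.median(ratios)) if ratios.size else np.nan
    return ModelComparison(median, ratios, log_ratios, int(ratios.size))


def assess_cells(cells, fits, fwer: float = 0.05):
    """Per-subject KS + Holm acceptance over a collection of fitted cells.

    ``cells`` and ``fits`` are parallel sequences; cells are grouped by
    ``subject_id`` so the Holm correction spans the N_i models tested
    simultaneously for each subject.  Returns a list of dicts (one per
    cell) with the KS statistic, p-value and the Holm accept flag.
    """
    rows = []
    for cell, fit in zip(cells, fits):
        d, p = ks_gof(cell, fit)
        rows.append({
            "subject_id": cell.subject_id, "k1": cell.k1, "k2": cell.k2,
            "family": fit.family, "n_obs": int(cell.x.size),
            "ks_stat": d, "ks_pvalue": p,
        })
    subjects = sorted({r["subject_id"] for r in rows})
    for sid in subjects:
        idx = [i for i, r in enumerate(rows) if r["subject_id"] == sid]
        reject = holm_bonferroni([rows[i]["ks_pvalue"] for i in idx], fwer=fwer)
        for i, rej in zip(idx, reject):
            rows[i]["accepted"] = bool(~rej)
    return rows
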