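"""Study-condition validation runs for the mixture model.

These functions reproduce, on synthetic cohorts, the validation analyses
used to certify the gamma-variant mixture: goodness-of-fit acceptance
under Holm-Bonferroni, cross-validated HPDR prediction error, the
likelihood-ratio comparison with the Gaussian mixture, and the HPDR mass
guarantee.  They are called both by the acceptance script and by the
test suite, and are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .assessment import compare_vs_gaussian, cv_hpdr_error, holm_bonferroni, hpdr, ks_gof
from .distributions import FAMILY_KINDS, component_pdf, select_family
from .mixture import MixtureFit, fit_em
from .simulate import SubjectGroundTruth, simulate_cell

ALL_CELLS = [(k1, k2) for k1 in range(1, 11) for k2 in (1, 5, 10)]


def _cohort_truths(rng, n_subjects):
    """Heterogeneous ground truths: susceptibility varies across subjects."""
    return [
        SubjectGroundTruth(float(rng.uniform(0.15, 0.65)),
                           float(rng.uniform(1.5, 3.0)))
        for _ in range(n_subjects)
    ]


def run_gof_acceptance(seed: int, n_subjects: int = 15, n_per_cell: int = 150,
                       fwer: float = 0.05) -> dict:
    """KS + Holm acceptance rate over synthetic model-family cohorts.

    Each of ``n_subjects`` subjects contributes all 30 (k1, k2) cells with
    ``n_per_cell`` draws from that subject's ground-truth mixture; every
    cell is fit by EM, KS-tested against its own fit, and Holm-corrected
    per subject at the given FWER.  Returns the acceptance percentage.
    """
    rng = np.random.default_rng(seed)
    truths = _cohort_truths(rng, n_subjects)
    accepted = 0
    total = 0
    for truth in truths:
        pvals = []
        for k1, k2 in ALL_CELLS:
            fam, p, a1, b1, a2, b2 = truth.cell_params(k1, k2)
            x = simulate_cell(fam, p, a1, b1, a2, b2, n_per_cell, seed=rng)
            fit = fit_em(x, fam, seed=int(rng.integers(2**31 - 1)))
            _, pv = ks_gof(x, fit)
            pvals.append(pv)
        reject = holm_bonferroni(pvals, fwer=fwer)
        accepted += int(np.sum(~reject))
        total += len(pvals)
    return {"acceptance_pct": 100.0 * accepted / total, "n_cells": total}


def _random_bimodal_cell(rng):
    """A bimodal ground-truth cell drawn from the generator's parameter map."""
    k1 = int(rng.integers(1, 11))
    k2 = int(rng.choice([1, 5, 10]))
    while abs(k1 - k2) < 3:  # keep the two modes clearly separated
        k1 = int(rng.integers(1, 11))
        k2 = int(rng.choice([1, 5, 10]))
    truth = SubjectGroundTruth(float(rng.uniform(0.3, 0.6)),
                               float(rng.uniform(1.5, 3.0)))
    return truth.cell_params(k1, k2)


def run_hpdr_cv(seed: int, n_cells: int = 50, n_per_cell: int = 200,
                folds: int = 10, level: float = 0.95) -> dict:
    """Cross-validated HPDR prediction error over bimodal synthetic cells.

    Returns the per-fold error averaged across cells and its maximum over
    folds, both in percent.
    """
    rng = np.random.default_rng(seed)
    errors = np.empty((n_cells, folds))
    for i in range(n_cells):
        fam, p, a1, b1, a2, b2 = _random_bimodal_cell(rng)
        x = simulate_cell(fam, p, a1, b1, a2, b2, n_per_cell, seed=rng)
        errors[i] = cv_hpdr_error(x, fam, folds=folds, level=level,
                                  seed=int(rng.integers(2**31 - 1)))
    fold_means = errors.mean(axis=0)
    return {
        "max_fold_error_pct": 100.0 * float(fold_means.max()),
        "fold_error_pct": (100.0 * fold_means).tolist(),
        "n_cells": n_cells,
    }


def run_model_comparison(seed: int, n_cells: int = 30, n_per_cell: int = 200,
                         folds: int = 10) -> dict:
    """Gamma-variant vs Gaussian mixture on skewed bimodal cells.

    ``n_cells`` synthetic cells from skewed bimodal gamma-variant
    mixtures; per cell, the median cross-validated held-out likelihood
    ratio (proposed / Gaussian).  Returns the number of cells the
    Gaussian mixture wins (median ratio < 1).
    """
    rng = np.random.default_rng(seed)
    gaussian_wins = 0
    ratios = []
    for _ in range(n_cells):
        fam, p, a1, b1, a2, b2 = _random_bimodal_cell(rng)
        x = simulate_cell(fam, p, a1, b1, a2, b2, n_per_cell, seed=rng)
        res = compare_vs_gaussian(x, fam, folds=folds,
                                  seed=int(rng.integers(2**31 - 1)))
        ratios.append(res.median_ratio)
        if res.median_ratio < 1.0:
            gaussian_wins += 1
    return {"gaussian_wins": gaussian_wins, "n_cells": n_cells,
            "median_ratios": ratios}


def random_valid_fit(rng, min_scale_mass: float = 0.999) -> MixtureFit:
    """A random parameter set inside the model's parameter space.

    Modes are drawn on the rating scale (the fit invariant for data on
    [1, L]) and parameter sets whose components leak appreciable mass
    past the opposite end of the scale are redrawn, so the density lives
    where rating fits do.
    """
    from .distributions import L

    while True:
        fam = str(rng.choice(["SS", "NN", "SN"]))
        kinds = FAMILY_KINDS[fam]
        p = float(rng.uniform(0.0, 1.0))
        params = []
        for kind in kinds:
            beta = float(rng.uniform(1.0, 3.0))
            mode = float(rng.uniform(1.0, 10.0)) if kind == "s" else float(
                rng.uniform(2.0, 11.0))
            alpha = 1.0 + (mode - 1.0) * beta if kind == "s" else 1.0 + (L - mode) * beta
            params.append((alpha, beta))
        fit = MixtureFit(fam, p, params[0][0], params[0][1],
                         params[1][0], params[1][1], loglik=np.nan, n_obs=0)
        if fit.cdf(L) - fit.cdf(1.0) >= min_scale_mass:
            return fit


def run_hpdr_mass(seed: int, n_fits: int = 100, level: float = 0.95,
                  n_grid: int = 10001) -> dict:
    """Minimum quadrature-checked HPDR mass over random valid fits.

    The contained mass is integrated numerically (adaptive quadrature per
    interval), independently of the CDF used to build the region.
    """
    from scipy.integrate import quad

    rng = np.random.default_rng(seed)
    masses = []
    for _ in range(n_fits):
        fit = random_valid_fit(rng)
        region = hpdr(fit, level=level, n_grid=n_grid)
        mass = 0.0
        for lo, hi in region.intervals:
            if hi <= lo:
                continue
            mass += quad(lambda t: float(fit.pdf(t)), lo, hi,
                         epsabs=1e-10, limit=200)[0]
        masses.append(mass)
    masses = np.asarray(masses)
    return {"min_mass_pct": 100.0 * float(masses.min()),
            "mean_mass_pct": 100.0 * float(masses.mean()), "n_fits": n_fits}
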