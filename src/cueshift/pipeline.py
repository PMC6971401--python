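"""End-to-end behavioral pipeline: trial tables -> cells -> fits -> profiles.

Cells are formed per subject by grouping cued trials by (k1, k2), where
k1 is the subject's rating of the same image with no cue and k2 recodes
the cue (FF -> 1, FC/CF -> 5, CC -> 10).  Integer ratings are jittered
with Uniform(0, 1) noise before fitting.  Cells with 10 or fewer
observations are skipped, mirroring the estimation rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import CUE_CODES, jitter_ratings
from .mixture import MixtureFit, RatingCell, fit_em
from .social import proportion_toward_cue, social_bias_scores


def build_cells(trials: pd.DataFrame, seed=None) -> list[RatingCell]:
    """Group a trial table into jittered (subject, k1, k2) rating cells.

    Requires every image to have a no-cue presentation (its rating
    defines k1).  Returns all cells, including ones too small to fit
    (check ``cell.fittable``).
    """
    rng = np.random.default_rng(seed)
    cells = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        nocue = sub[sub["cue"] == "none"].set_index("image_id")["rating"]
        cued = sub[sub["cue"] != "none"]
        k1 = cued["image_id"].map(nocue)
        if k1.isna().any():
            raise ValueError(f"subject {sid!r}: images missing a no-cue rating")
        k2 = cued["cue"].map(CUE_CODES)
        grouped = cued.assign(k1=k1.astype(int), k2=k2.astype(int)).groupby(["k1", "k2"])
        for (kk1, kk2), grp in grouped:
            x = jitter_ratings(grp["rating"].to_numpy(), seed=rng)
            cells.append(RatingCell(str(sid), int(kk1), int(kk2), x))
    return cells


def fit_cells(cells, seed=None, **fit_kw):
    """Fit every fittable cell; returns parallel (cells, fits) lists."""
    rng = np.random.default_rng(seed)
    kept, fits = [], []
    for cell in cells:
        if not cell.fittable:
            continue
        fit = fit_em(cell, seed=int(rng.integers(2**31 - 1)), **fit_kw)
        kept.append(cell)
        fits.append(fit)
    return kept, fits


@dataclass
class SubjectProfile:
    """Per-subject summary of cue influence.

    ``proportions`` maps (k1, k2) to the fitted proportion of decisions
    between k1 and k2; ``p_mean`` is their average (the subject's p_i),
    later standardized into the social-bias score W_i.
    """

    subject_id: str
    proportions: dict
    p_mean: float
    w_score: float = float("nan")
    selected: bool = False


def subject_profiles(cells, fits, threshold: float = 1.96):
    """Aggregate fitted cells into ranked subject profiles.

    Computes each subject's average proportion-toward-cue across cells
    with k1 != k2, standardizes across the cohort into W_i scores and
    flags subjects above ``threshold``.  Returns profiles sorted most
    influenced first, plus the cohort-level ranking object.
    """
    per_subject: dict[str, dict] = {}
    for cell, fit in zip(cells, fits):
        if cell.k1 == cell.k2:
            continue
        prop = proportion_toward_cue(fit, cell.k1, cell.k2)
        per_subject.setdefault(cell.subject_id, {})[(cell.k1, cell.k2)] = prop
    sids = sorted(per_subject)
    p_means = np.array([np.mean(list(per_subject[s].values())) for s in sids])
    ranking = social_bias_scores(p_means, threshold=threshold)
    profiles = []
    for i, sid in enumerate(sids):
        profiles.append(SubjectProfile(
            sid, per_subject[sid], float(p_means[i]),
            float(ranking.scores[i]), bool(ranking.selected[i]),
        ))
    profiles.sort(key=lambda pr: -pr.w_score)
    return profiles, ranking


def fits_by_cell(cells, fits) -> dict:
    """Index fits by (subject_id, k1, k2)."""
    return {(c.subject_id, c.k1, c.k2): f for c, f in zip(cells, fits)}
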