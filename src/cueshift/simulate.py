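"""Synthetic behavioral experiments and ERP-like EEG epochs.

The behavioral generator emulates a face/car identification task in which
every image is shown four times — once preceded by each cue condition
(FF, neutral FC/CF, CC) and once with no cue — and the subject answers on
a 10-point confidence scale (1 = certainly face, 10 = certainly car).
With the default design of 250 images this yields 1,000 trials per
subject, 250 per cue condition.

Each image carries a latent percept mode (an integer 1..5 for faces,
6..10 for cars).  A subject's rating is a floored draw from a
two-component gamma-variant mixture whose own-side component peaks at the
latent percept and whose cue-side component peaks at the cue code k2; the
cue-side mixing weight is the subject's *susceptibility*.  The no-cue
rating is a draw from the own-side component alone, and its realized
value defines k1 for that image — exactly the grouping convention of the
downstream analysis.  At susceptibility 0 cued and no-cue ratings are
therefore exchangeable draws from the same distribution.

The EEG generator produces trials x channels x samples epochs with a
class-dependent spatiotemporal signal (a smooth temporal bump centred
between 200 and 300 ms post-stimulus times a fixed topography, opposite
sign for the two classes) scaled per condition by an SNR knob, on top of
spatially correlated 1/f-spectrum noise.  The baseline window carries no
signal and epochs are baseline-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import CUE_CODES, FAMILY_KINDS, L, select_family

CUE_CONDITIONS = ("FF", "FC/CF", "CC", "none")


# ---------------------------------------------------------------------------
# behavioral generator


@dataclass
class ExperimentDesign:
    """Trial schedule: each image appears once per cue condition."""

    n_images: int = 250
    n_trials: int = 1000
    rating_min: int = 1
    rating_max: int = 10
    sessions: int = 40

    def __post_init__(self):
        if self.n_images < 2 or self.n_images % 2:
            raise ValueError("n_images must be even (equal face/car split)")
        if self.n_trials != 4 * self.n_images:
            raise ValueError(
                "n_trials must equal n_images x 4 (one presentation per cue condition)"
            )
        if (self.rating_min, self.rating_max) != (1, 10):
            raise ValueError("the confidence scale is fixed at 1..10")


@dataclass
class SubjectGroundTruth:
    """Latent behavioral parameters of one synthetic subject.

    susceptibility : float in [0, 1]
        True mixing weight of the cue-side mixture component; 0 means the
        cue is ignored, 1 means ratings follow the cue entirely.
    confidence_sharpness : float > 0
        Rate parameter of every component; larger values concentrate the
        rating components around their modes.
    """

    susceptibility: float = 0.35
    confidence_sharpness: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.susceptibility <= 1.0:
            raise ValueError("susceptibility must lie in [0, 1]")
        if not self.confidence_sharpness > 0:
            raise ValueError("confidence_sharpness must be positive")

    def cell_params(self, k1: int, k2: int):
        """Ground-truth mixture for a (k1, k2) cell.

        Returns ``(family, p, alpha1, beta1, alpha2, beta2)`` with the
        own-side component mode at ``k1`` and the cue-side mode at ``k2``
        (mode solved as ``1 + (alpha-1)/beta`` or ``L - (alpha-1)/beta``
        with ``beta = confidence_sharpness``), components ordered by mode
        so that ``p`` is the weight of the lower-mode component.
        """
        family = select_family(k1, k2)
        beta = self.confidence_sharpness
        s = self.susceptibility
        comps = []  # (mode, weight)
        comps.append((float(k1), 1.0 - s))  # own side
        comps.append((float(k2), s))  # cue side
        kinds = FAMILY_KINDS[family]
        comps.sort(key=lambda t: t[0])
        params = []
        for kind, (mode, _) in zip(kinds, comps):
            if kind == "s":
                alpha = 1.0 + (mode - 1.0) * beta
            else:
                alpha = 1.0 + (L - mode) * beta
            params.append((alpha, beta))
        p = comps[0][1]
        if comps[0][0] == comps[1][0]:  # degenerate cell (k1 == k2)
            p = 1.0 - s
        (a1, b1), (a2, b2) = params
        return family, p, a1, b1, a2, b2


def _draw_component(kind, alpha, beta, n, rng, big_l=L):
    """Component draws rejection-sampled into [1, L]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        y = rng.gamma(alpha, 1.0 / beta, size=m)
        v = 1.0 + y if kind == "s" else big_l - y
        v = v[(v >= 1.0) & (v <= big_l)]
        out[filled : filled + v.size] = v
        filled += v.size
    return out


def simulate_cell(family, p, alpha1, beta1, alpha2, beta2, n, seed=None, big_l=L,
                  truncate: bool = True):
    """I.i.d. draws from a gamma-variant mixture.

    With ``truncate=True`` (default) draws falling outside [1, L] —
    possible only in the gamma tail pointing away from the reflected end —
    are redrawn, so all returned values lie in the jittered-rating support.
    For the rating-scale parameter ranges produced by the experiment
    generator the redrawn mass is negligible (< 1%); for components whose
    mean sits near the opposite end of the scale it is not, and
    ``truncate=False`` then returns draws from the exact untruncated
    mixture (matching the density the EM fits).
    """
    if family not in FAMILY_KINDS:
        raise ValueError(f"unknown family {family!r}")
    if not (0.0 <= p <= 1.0):
        raise ValueError("mixing weight p must lie in [0, 1]")
    for a, b in ((alpha1, beta1), (alpha2, beta2)):
        if not a >= 1.0:
            raise ValueError("shape parameters must be >= 1")
        if not b > 0.0:
            raise ValueError("rate parameters must be > 0")
    if not n >= 1:
        raise ValueError("n must be a positive count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kinds = FAMILY_KINDS[family]
    pick1 = rng.random(int(n)) < p
    out = np.empty(int(n))
    n1 = int(pick1.sum())
    if truncate:
        if n1:
            out[pick1] = _draw_component(kinds[0], alpha1, beta1, n1, rng, big_l)
        if int(n) - n1:
            out[~pick1] = _draw_component(kinds[1], alpha2, beta2, int(n) - n1, rng, big_l)
    else:
        for mask, kind, a, b in ((pick1, kinds[0], alpha1, beta1),
                                 (~pick1, kinds[1], alpha2, beta2)):
            m = int(mask.sum())
            if not m:
                continue
            y = rng.gamma(a, 1.0 / b, size=m)
            out[mask] = 1.0 + y if kind == "s" else big_l - y
    return out


def _rating_from_continuous(values):
    """Floor continuous draws in [1, 11] onto the integer 1..10 scale."""
    return np.clip(np.floor(values).astype(int), 1, 10)


def simulate_experiment(design: ExperimentDesign, truth: SubjectGroundTruth,
                        seed: int, subject_id: str = "S01") -> pd.DataFrame:
    """Simulate one subject's full trial table.

    Returns a DataFrame with columns ``subject_id, image_id,
    stimulus_class, cue, rating`` in randomized trial order; each
    (image, cue condition) pair occurs exactly once.  The no-cue rating of
    an image defines that image's k1 in downstream cell grouping.
    """
    rng = np.random.default_rng(seed)
    n_img = design.n_images
    half = n_img // 2
    stim_class = np.array(["face"] * half + ["car"] * half)
    # latent percept mode per image: face-side 1..5, car-side 6..10
    latent = np.where(
        stim_class == "face",
        rng.integers(1, 6, size=n_img),
        rng.integers(6, 11, size=n_img),
    )
    records = []
    for cond in CUE_CONDITIONS:
        if cond == "none":
            # own-side component alone (susceptibility plays no role)
            for mu in np.unique(latent):
                idx = np.where(latent == mu)[0]
                kind = "s" if mu <= 5 else "n"
                beta = truth.confidence_sharpness
                alpha = 1.0 + (mu - 1.0) * beta if kind == "s" else 1.0 + (L - mu) * beta
                draws = _draw_component(kind, alpha, beta, idx.size, rng)
                for i, v in zip(idx, draws):
                    records.append((subject_id, int(i), stim_class[i], cond,
                                    int(_rating_from_continuous(np.array([v]))[0])))
        else:
            k2 = CUE_CODES[cond]
            for mu in np.unique(latent):
                idx = np.where(latent == mu)[0]
                fam, p, a1, b1, a2, b2 = truth.cell_params(int(mu), k2)
                draws = simulate_cell(fam, p, a1, b1, a2, b2, idx.size, seed=rng)
                ratings = _rating_from_continuous(draws)
                for i, r in zip(idx, ratings):
                    records.append((subject_id, int(i), stim_class[i], cond, int(r)))
    df = pd.DataFrame(
        records, columns=["subject_id", "image_id", "stimulus_class", "cue", "rating"]
    )
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    assert len(df) == design.n_trials
    return df


def simulate_cohort(n_subjects, susceptibilities=None, sharpness=2.0, seed=0,
                    design: ExperimentDesign | None = None) -> pd.DataFrame:
    """Trial tables for a cohort of subjects with heterogeneous susceptibility."""
    design = design or ExperimentDesign()
    rng = np.random.default_rng(seed)
    if susceptibilities is None:
        susceptibilities = rng.uniform(0.1, 0.7, size=n_subjects)
    frames = []
    for i, s in enumerate(susceptibilities):
        truth = SubjectGroundTruth(float(s), sharpness)
        sub_seed = int(rng.integers(2**31 - 1))
        frames.append(
            simulate_experiment(design, truth, sub_seed, subject_id=f"S{i + 1:02d}")
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EEG generator


@dataclass
class EegEpochs:
    """Trials x channels x samples epoch container.

    data is in microvolt-like units; ``window_ms`` gives the epoch extent
    relative to the event, ``baseline_ms`` the pre-event interval used for
    baseline correction.
    """

    data: np.ndarray
    labels: np.ndarray  # 'face' / 'car' per trial
    condition: np.ndarray  # condition tag per trial
    sfreq: float
    window_ms: tuple = (-200.0, 500.0)
    baseline_ms: tuple = (-200.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must match trial count")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def times(self):
        """Sample times in ms relative to the event."""
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.sfreq

    def select(self, mask):
        return EegEpochs(self.data[mask], self.labels[mask], self.condition[mask],
                         self.sfreq, self.window_ms, self.baseline_ms)


def _pink_noise(rng, n_channels, n_samples, mixing):
    """Spatially correlated noise with a 1/f-like temporal spectrum."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz].min())
    noise = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    noise = mixing @ noise
    rms = noise.std()
    return noise / max(rms, 1e-12)


def simulate_eeg(n_trials_per_class: int, conditions: dict, n_channels: int = 64,
                 sfreq: float = 512.0, window_ms=(-200.0, 500.0),
                 baseline_ms=(-200.0, 0.0), seed=0) -> EegEpochs:
    """Generate ERP-like epochs with condition-dependent class signal.

    Parameters
    ----------
    n_trials_per_class : int
        Trials per class *per condition*.
    conditions : dict
        Maps condition name (e.g. 'concurring', 'neutral', 'conflicting')
        to a non-negative SNR multiplier for the class-discriminative
        signal.
    """
    for cond, snr in conditions.items():
        if snr < 0:
            raise ValueError(f"snr must be >= 0 (condition {cond!r})")
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    n_samples = int(round((window_ms[1] - window_ms[0]) * sfreq / 1000.0))
    times = window_ms[0] + np.arange(n_samples) * 1000.0 / sfreq
    # class-discriminative pattern: smooth bump centred at 250 ms times a
    # fixed topography; strictly zero before stimulus onset
    bump = np.exp(-0.5 * ((times - 250.0) / 40.0) ** 2) * (times >= 0.0)
    topo = np.cos(np.linspace(0.0, 3.0 * np.pi, n_channels))
    topo /= np.linalg.norm(topo) / np.sqrt(n_channels)
    signal = topo[:, None] * bump[None, :]
    # fixed spatial correlation structure for the noise
    idx = np.arange(n_channels)
    mixing = np.linalg.cholesky(
        np.exp(-np.abs(idx[:, None] - idx[None, :]) / 5.0) + 1e-9 * np.eye(n_channels)
    )
    data, labels, cond_tags = [], [], []
    for cond, snr in conditions.items():
        for label, sign in (("face", 1.0), ("car", -1.0)):
            for _ in range(int(n_trials_per_class)):
                noise = _pink_noise(rng, n_channels, n_samples, mixing)
                data.append(noise + sign * snr * signal)
                labels.append(label)
                cond_tags.append(cond)
    data = np.array(data)
    # baseline correction: subtract the per-channel pre-event mean
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    epochs = EegEpochs(data, np.array(labels), np.array(cond_tags), sfreq,
                       tuple(window_ms), tuple(baseline_ms))
    order = rng.permutation(epochs.n_trials)
    return epochs.select(order)
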