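"""Synthetic study generator: behavior, EEG, PANAS, and symptom scores.

Emulates the design of the affect-primed gambling study: 38 patients (SZ)
and 26 controls (CTRL), each completing three sessions (neutral, angry,
happy facial-prime conditions) of 480 experimental trials.  Per group x
condition, subject-level (alpha, beta) are drawn from truncated group
normals; choices come from the delta-rule/softmax agent on a freshly drawn
block schedule; continuous EEG carries Gaussian-shaped N170/P200 components
locked to prime onsets and an FRN effect (injected on unexpected-loss
feedback only, so the loss-minus-win difference wave recovers it) on top of
white channel noise; PANAS pre/post ratings shift by condition; and five
PANSS symptom factors are generated for SZ subjects with *plantable*
correlations to subject-level measures, realized through a Gaussian copula
on the subject latents.

Component templates are scaled so that the configured amplitude equals the
component's mean over its analysis window (not the Gaussian peak), making
injection-recovery semantics exact at zero noise.

Everything is deterministic per seed; continuous EEG is regenerated lazily
and byte-identically on demand rather than stored (a full cohort's raw EEG
would be tens of gigabytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import erp as erp_mod
from .agent import SubjectParams, simulate_subject
from .behavior import PanasDiff, panas_diff
from .errors import ConfigurationError, DataError
from .hbayes import GroupHyperParams
from .task import TaskConfig, TrialRecord, make_block_schedule

GROUPS = ("SZ", "CTRL")
CONDITIONS = ("neutral", "angry", "happy")
MEASURES = ("alpha", "beta", "frn", "p200")
FACTORS = ("positive", "negative", "cognitive", "excitement", "depressive")

#: PANSS five-factor composites: (mean, SD, number of items)
DEFAULT_FACTOR_STATS = {
    "positive": (8.39, 3.53, 4),  # P1 + P3 + P5 + G9
    "negative": (12.68, 4.03, 6),  # N1 + N2 + N3 + N4 + N6 + G7
    "cognitive": (6.68, 2.52, 3),  # P2 + N5 + G11
    "excitement": (5.45, 2.37, 4),  # P4 + P7 + G8 + G14
    "depressive": (4.95, 1.89, 3),  # G2 + G3 + G6
}

DEFAULT_GROUP_PARAMS = {
    ("CTRL", "neutral"): GroupHyperParams(0.25, 0.10, 6.0, 1.0),
    ("CTRL", "angry"): GroupHyperParams(0.35, 0.10, 4.5, 1.0),
    ("CTRL", "happy"): GroupHyperParams(0.35, 0.10, 4.5, 1.0),
    ("SZ", "neutral"): GroupHyperParams(0.45, 0.12, 2.0, 0.8),
    ("SZ", "angry"): GroupHyperParams(0.45, 0.12, 2.0, 0.8),
    ("SZ", "happy"): GroupHyperParams(0.55, 0.12, 1.5, 0.8),
}


@dataclass(frozen=True)
class ErpTemplates:
    """Per-condition component amplitudes in µV (window means, see module doc)."""

    n170_uv: float
    p200_uv: float
    frn_effect_uv: float


DEFAULT_ERP_TEMPLATES = {
    ("CTRL", "neutral"): ErpTemplates(-5.01, 4.0, -3.0),
    ("CTRL", "angry"): ErpTemplates(-5.01, 6.0, -4.3),
    ("CTRL", "happy"): ErpTemplates(-5.01, 6.0, -4.3),
    ("SZ", "neutral"): ErpTemplates(-3.51, 4.0, -2.8),
    ("SZ", "angry"): ErpTemplates(-3.51, 4.2, -2.0),
    ("SZ", "happy"): ErpTemplates(-3.51, 5.5, -2.6),
}

#: Planted measure x factor correlations (SZ, correlation condition)
DEFAULT_PLANTED_CORRELATIONS = {
    ("frn", "positive"): -0.436,
    ("frn", "cognitive"): -0.447,
    ("beta", "positive"): -0.334,
    ("p200", "negative"): -0.362,
    ("p200", "cognitive"): -0.344,
}

DEFAULT_PANAS_SHIFTS = {
    ("CTRL", "neutral"): (0.0, 0.0),
    ("CTRL", "angry"): (0.0, 0.8),
    ("CTRL", "happy"): (1.0, 0.0),
    ("SZ", "neutral"): (0.0, 0.0),
    ("SZ", "angry"): (0.0, 0.0),
    ("SZ", "happy"): (1.0, 0.0),
}


@dataclass(frozen=True)
class EEGNoiseModel:
    """Additive channel noise: white Gaussian, optionally 1/f-shaped, with
    optional high-amplitude frontal blink transients (to exercise rejection)."""

    white_sd_uv: float = 10.0
    pink_exponent: float | None = None
    blink_rate_per_trial: float = 0.0
    blink_amplitude_uv: float = 120.0


@dataclass(frozen=True)
class CohortConfig:
    n_sz: int = 38
    n_ctrl: int = 26
    conditions: tuple[str, ...] = CONDITIONS
    task: TaskConfig = field(default_factory=TaskConfig)
    group_params: Mapping[tuple[str, str], GroupHyperParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    erp_templates: Mapping[tuple[str, str], ErpTemplates] = field(
        default_factory=lambda: dict(DEFAULT_ERP_TEMPLATES)
    )
    n170_subject_sd: float = 0.8
    p200_subject_sd: float = 1.2
    frn_subject_sd: float = 0.8
    noise: EEGNoiseModel = field(default_factory=EEGNoiseModel)
    panas_shifts: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PANAS_SHIFTS)
    )
    panas_items_per_subscale: int = 10
    factor_stats: Mapping[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(DEFAULT_FACTOR_STATS)
    )
    planted_correlations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_CORRELATIONS)
    )
    correlation_condition: str = "angry"
    sfreq: float = 1000.0
    segment_ms: float = 2000.0  # inter-trial interval of the epoch-aligned record
    prime_at_ms: float = 200.0
    feedback_at_ms: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sz < 1 or self.n_ctrl < 1:
            raise ConfigurationError("group sizes must be >= 1")
        for group in GROUPS:
            for cond in self.conditions:
                if (group, cond) not in self.group_params:
                    raise ConfigurationError(f"missing group_params for {(group, cond)}")
                if (group, cond) not in self.erp_templates:
                    raise ConfigurationError(f"missing erp_templates for {(group, cond)}")
        for (measure, factor), r in self.planted_correlations.items():
            if measure not in MEASURES or factor not in FACTORS:
                raise ConfigurationError(f"unknown correlation cell {(measure, factor)}")
            if not (-1.0 < r < 1.0):
                raise ConfigurationError(f"planted r must lie in (-1, 1), got {r}")
        # fail early if the joint copula correlation is infeasible
        _copula_cholesky(self.planted_correlations)
        wins = (self.prime_at_ms - 100.0, self.prime_at_ms + 500.0,
                self.feedback_at_ms - 100.0, self.feedback_at_ms + 900.0)
        if wins[0] < 0 or wins[3] > self.segment_ms or wins[1] > wins[2]:
            raise ConfigurationError(
                "prime/feedback epochs must fit inside a trial segment without overlap"
            )


def _copula_matrix(planted: Mapping[tuple[str, str], float]) -> np.ndarray:
    """Joint correlation of (4 measures, 5 factors): identity blocks with the
    planted cross-block."""
    k = len(MEASURES) + len(FACTORS)
    sigma = np.eye(k)
    for (measure, factor), r in planted.items():
        i = MEASURES.index(measure)
        j = len(MEASURES) + FACTORS.index(factor)
        sigma[i, j] = sigma[j, i] = r
    return sigma


def _copula_cholesky(planted: Mapping[tuple[str, str], float]) -> np.ndarray:
    sigma = _copula_matrix(planted)
    eigenvalues = np.linalg.eigvalsh(sigma)
    if eigenvalues.min() < -1e-10:
        raise ConfigurationError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigenvalues.min():.3g})"
        )
    return np.linalg.cholesky(sigma + 1e-10 * np.eye(len(sigma)))


def _truncnorm_ppf(u: np.ndarray | float, mu: float, sigma: float,
                   lo: float, hi: float) -> np.ndarray:
    from scipy.stats import truncnorm

    if sigma <= 0:
        return np.clip(np.full_like(np.asarray(u, dtype=float), mu), lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _draw_truncnorm(rng: np.random.Generator, mu: float, sigma: float,
                    lo: float, hi: float, size=None):
    return _truncnorm_ppf(rng.random(size), mu, sigma, lo, hi)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic, independent substream keyed by integers."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


# --------------------------------------------------------------------------
# symptom scores


def symptom_scores(
    latents: np.ndarray,
    config: CohortConfig,
    subject_ids: Sequence[str],
) -> pd.DataFrame:
    """PANSS five-factor scores from standard-normal latents.

    ``latents`` is (n_subjects, 5) in the order of :data:`FACTORS`.  Each
    factor is mean + SD * z, clipped at its theoretical minimum (one point
    per item).
    """
    latents = np.asarray(latents, dtype=float)
    if latents.shape != (len(subject_ids), len(FACTORS)):
        raise DataError(f"latents must be (n_subjects, {len(FACTORS)})")
    out = {}
    for j, factor in enumerate(FACTORS):
        mean, sd, n_items = config.factor_stats[factor]
        out[factor] = np.clip(mean + sd * latents[:, j], float(n_items), None)
    return pd.DataFrame(out, index=list(subject_ids))


# --------------------------------------------------------------------------
# synthetic EEG


def _window_scaled_bump(
    t_rel_ms: np.ndarray,
    center_ms: float,
    sd_ms: float,
    window_ms: tuple[float, float],
    amplitude_uv: float,
    sfreq: float,
) -> np.ndarray:
    """Gaussian bump scaled so its mean over the (half-open) analysis window
    equals ``amplitude_uv`` on the sample grid."""
    g = np.exp(-0.5 * ((t_rel_ms - center_ms) / sd_ms) ** 2)
    in_window = (t_rel_ms >= window_ms[0]) & (t_rel_ms < window_ms[1])
    window_mean = g[in_window].mean()
    return (amplitude_uv / window_mean) * g


def synth_eeg(
    trials: Sequence[TrialRecord],
    templates: ErpTemplates,
    noise: EEGNoiseModel,
    rng: np.random.Generator,
    sfreq: float = 1000.0,
    segment_ms: float = 2000.0,
    prime_at_ms: float = 200.0,
    feedback_at_ms: float = 1000.0,
    windows: erp_mod.ComponentWindows = erp_mod.DEFAULT_WINDOWS,
    dtype=np.float32,
) -> erp_mod.ContinuousEEG:
    """Continuous record of epoch-aligned trial segments with injected
    components.

    Each trial occupies one ``segment_ms`` stretch holding a prime event and
    a feedback event; the feedback event's code encodes the trial's
    expectancy class.  N170 goes to P7/P8 (right-lateralized: P8 carries
    1.1x, P7 0.9x the template), P200 to Fz/Cz/Pz(+FCz), and the FRN effect
    to Fz/FCz/Cz on unexpected-loss trials only.
    """
    channels = erp_mod.ANALYSIS_CHANNELS
    seg = int(round(segment_ms * sfreq / 1000.0))
    n_samples = seg * len(trials)
    data = rng.standard_normal((len(channels), n_samples), dtype=np.float64).astype(dtype)
    data *= dtype(noise.white_sd_uv)
    if noise.pink_exponent:
        data = _pinkify(data, noise.pink_exponent, rng)

    t_seg_ms = np.arange(seg) / sfreq * 1000.0
    prime_rel = t_seg_ms - prime_at_ms
    fb_rel = t_seg_ms - feedback_at_ms

    n170 = _window_scaled_bump(prime_rel, 180.0, 20.0, windows.n170_window,
                               templates.n170_uv, sfreq)
    p200 = _window_scaled_bump(prime_rel, 200.0, 20.0, windows.p200_window,
                               templates.p200_uv, sfreq)
    frn = _window_scaled_bump(fb_rel, 450.0, 80.0, windows.frn_window,
                              templates.frn_effect_uv, sfreq)

    lateral = {"P7": 0.9, "P8": 1.1}
    p200_channels = ("Fz", "FCz", "Cz", "Pz")

    events = []
    prime_offset = int(round(prime_at_ms * sfreq / 1000.0))
    fb_offset = int(round(feedback_at_ms * sfreq / 1000.0))
    for k, trial in enumerate(trials):
        start = k * seg
        sl = slice(start, start + seg)
        for ch in ("P7", "P8"):
            data[channels.index(ch), sl] += lateral[ch] * n170
        for ch in p200_channels:
            data[channels.index(ch), sl] += p200
        expectancy = erp_mod.classify_feedback(trial)
        if expectancy == erp_mod.UNEXPECTED_LOSS:
            for ch in windows.frn_channels:
                data[channels.index(ch), sl] += frn
        events.append((start + prime_offset, erp_mod.EVENT_CODES["prime"]))
        events.append((start + fb_offset, erp_mod.EVENT_CODES[expectancy]))
        if noise.blink_rate_per_trial > 0 and rng.random() < noise.blink_rate_per_trial:
            blink_at = start + int(rng.integers(0, seg - 200))
            blink = noise.blink_amplitude_uv * np.hanning(200)
            for ch in ("Fz", "FCz"):
                data[channels.index(ch), blink_at : blink_at + 200] += blink

    return erp_mod.ContinuousEEG(
        data=data, channels=channels, sfreq=sfreq,
        events=np.array(events, dtype=np.int64),
    )


def _pinkify(data: np.ndarray, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Reshape white noise to a 1/f^exponent amplitude spectrum, preserving
    total variance."""
    n = data.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = np.fft.rfft(data, axis=1) * shaping
    shaped = np.fft.irfft(spectrum, n=n, axis=1)
    shaped *= data.std(axis=1, keepdims=True) / shaped.std(axis=1, keepdims=True)
    return shaped.astype(data.dtype)


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class SyntheticStudy:
    """Full synthetic cohort with ground truth for every recovery test.

    Continuous EEG is not stored; :meth:`eeg` regenerates any subject x
    condition record deterministically from the study seed.
    """

    config: CohortConfig
    roster: pd.DataFrame  # subject_id, group
    params: dict[tuple[str, str], SubjectParams]
    trials: dict[tuple[str, str], list[TrialRecord]]
    erp_truth: dict[tuple[str, str], ErpTemplates]
    panas_pre: dict[tuple[str, str], dict[str, float]]
    panas_post: dict[tuple[str, str], dict[str, float]]
    panas_item_subscale: dict[str, str]
    symptoms: pd.DataFrame  # SZ subjects x five factors

    @property
    def subject_ids(self) -> list[str]:
        return list(self.roster["subject_id"])

    def group_of(self, subject_id: str) -> str:
        return self.roster.set_index("subject_id")["group"][subject_id]

    def trials_frame(self) -> pd.DataFrame:
        from .task import trials_to_frame

        frames = [trials_to_frame(recs) for recs in self.trials.values()]
        return pd.concat(frames, ignore_index=True)

    def panas_difference(self, subject_id: str, condition: str) -> PanasDiff:
        key = (subject_id, condition)
        return panas_diff(self.panas_pre[key], self.panas_post[key], self.panas_item_subscale)

    def _subject_index(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)

    def eeg(self, subject_id: str, condition: str) -> erp_mod.ContinuousEEG:
        """Regenerate this subject-session's continuous EEG (deterministic)."""
        cfg = self.config
        si = self._subject_index(subject_id)
        ci = cfg.conditions.index(condition)
        rng = _stream(cfg.seed, 7, si, ci)
        return synth_eeg(
            self.trials[(subject_id, condition)],
            self.erp_truth[(subject_id, condition)],
            cfg.noise, rng, sfreq=cfg.sfreq, segment_ms=cfg.segment_ms,
            prime_at_ms=cfg.prime_at_ms, feedback_at_ms=cfg.feedback_at_ms,
        )


def generate_cohort(config: CohortConfig) -> SyntheticStudy:
    """Generate the full synthetic study (see module docstring)."""
    seed = config.seed
    subject_ids = [f"sz{i + 1:02d}" for i in range(config.n_sz)] + [
        f"ct{i + 1:02d}" for i in range(config.n_ctrl)
    ]
    groups = ["SZ"] * config.n_sz + ["CTRL"] * config.n_ctrl
    roster = pd.DataFrame({"subject_id": subject_ids, "group": groups})

    # copula latents for SZ: (alpha, beta, frn, p200, five factors)
    chol = _copula_cholesky(config.planted_correlations)
    z = _stream(seed, 1).standard_normal((config.n_sz, chol.shape[0])) @ chol.T
    from scipy.special import ndtr

    params: dict[tuple[str, str], SubjectParams] = {}
    trials: dict[tuple[str, str], list[TrialRecord]] = {}
    erp_truth: dict[tuple[str, str], ErpTemplates] = {}
    panas_pre: dict[tuple[str, str], dict[str, float]] = {}
    panas_post: dict[tuple[str, str], dict[str, float]] = {}

    n_items = config.panas_items_per_subscale
    item_subscale = {f"pos{i + 1:02d}": "positive" for i in range(n_items)}
    item_subscale.update({f"neg{i + 1:02d}": "negative" for i in range(n_items)})

    for si, (sid, group) in enumerate(zip(subject_ids, groups)):
        for ci, condition in enumerate(config.conditions):
            hp = config.group_params[(group, condition)]
            template = config.erp_templates[(group, condition)]
            planted = group == "SZ" and condition == config.correlation_condition
            rng_param = _stream(seed, 2, si, ci)
            if planted:
                u_alpha, u_beta = ndtr(z[si, 0]), ndtr(z[si, 1])
                alpha = float(_truncnorm_ppf(u_alpha, hp.mu_alpha, hp.sigma_alpha, 0.0, 1.0))
                beta = float(_truncnorm_ppf(u_beta, hp.mu_beta, hp.sigma_beta, 0.0, 10.0))
                frn_i = template.frn_effect_uv + config.frn_subject_sd * z[si, 2]
                p200_i = template.p200_uv + config.p200_subject_sd * z[si, 3]
            else:
                alpha = float(_draw_truncnorm(rng_param, hp.mu_alpha, hp.sigma_alpha, 0.0, 1.0))
                beta = float(_draw_truncnorm(rng_param, hp.mu_beta, hp.sigma_beta, 0.0, 10.0))
                frn_i = template.frn_effect_uv + config.frn_subject_sd * rng_param.standard_normal()
                p200_i = template.p200_uv + config.p200_subject_sd * rng_param.standard_normal()
            n170_i = template.n170_uv + config.n170_subject_sd * rng_param.standard_normal()
            key = (sid, condition)
            params[key] = SubjectParams(
                alpha=alpha, beta=beta, subject_id=sid, group=group, condition=condition
            )
            erp_truth[key] = ErpTemplates(
                n170_uv=float(n170_i), p200_uv=float(p200_i), frn_effect_uv=float(frn_i)
            )
            schedule = make_block_schedule(config.task, _stream(seed, 3, si, ci))
            records, _ = simulate_subject(params[key], schedule, _stream(seed, 4, si, ci))
            trials[key] = records

            rng_panas = _stream(seed, 5, si, ci)
            pos_shift, neg_shift = config.panas_shifts[(group, condition)]
            pre, post = {}, {}
            for item, subscale in item_subscale.items():
                base = 2.8 if subscale == "positive" else 1.8
                shift = pos_shift if subscale == "positive" else neg_shift
                pre[item] = float(np.clip(base + 0.5 * rng_panas.standard_normal(), 1.0, 5.0))
                post[item] = float(
                    np.clip(pre[item] + shift + 0.3 * rng_panas.standard_normal(), 1.0, 5.0)
                )
            panas_pre[key], panas_post[key] = pre, post

    symptoms = symptom_scores(z[:, len(MEASURES):], config, subject_ids[: config.n_sz])

    return SyntheticStudy(
        config=config, roster=roster, params=params, trials=trials,
        erp_truth=erp_truth, panas_pre=panas_pre, panas_post=panas_post,
        panas_item_subscale=item_subscale, symptoms=symptoms,
    )
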