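"""Hierarchical Bayesian estimation of learning rate and choice consistency.

Subject-level parameters (alpha_i, beta_i) are modelled as draws from group
normal distributions with means (mu_alpha, mu_beta) and standard deviations
(sigma_alpha, sigma_beta), truncated to the parameter supports ([0, 1] for
alpha, [0, 10] for beta) so the delta-rule/softmax likelihood stays
well-defined.  Hyperpriors are uniform: mu_alpha, sigma_alpha ~ U(0, 1),
mu_beta ~ U(0, 10), sigma_beta ~ U(0, 5).

Sampling uses Metropolis-within-Gibbs: per-iteration random-walk proposals
for every subject's alpha and beta (accepted independently per subject,
since the likelihood factorizes over subjects) followed by scalar
random-walk updates of the four hyperparameters, whose full conditionals
involve only the truncated-normal group densities.  Proposal scales adapt
during burn-in only, so the retained chain is Markovian.  The iteration /
burn-in / thinning accounting is honored literally: the default protocol of
3 chains x 16,000 iterations with 6,000 burn-in and thinning interval 5
retains exactly 2,000 draws per chain, 6,000 in total.

The trial likelihood is evaluated by a numba-compiled kernel when numba is
importable, with a bit-equivalent pure-numpy fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .agent import DEFAULT_Q0
from .errors import ConfigurationError, DataError, DomainError
from .task import TrialRecord

ALPHA_SUPPORT = (0.0, 1.0)
BETA_SUPPORT = (0.0, 10.0)

HYPER_NAMES = ("mu_alpha", "sigma_alpha", "mu_beta", "sigma_beta")


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the configured threshold."""


# --------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class GroupHyperParams:
    """Group-level means and SDs of the subject-level normals."""

    mu_alpha: float
    sigma_alpha: float
    mu_beta: float
    sigma_beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_alpha <= 1.0):
            raise ConfigurationError(f"mu_alpha must lie in [0, 1], got {self.mu_alpha}")
        if not (0.0 <= self.sigma_alpha <= 1.0):
            raise ConfigurationError(f"sigma_alpha must lie in [0, 1], got {self.sigma_alpha}")
        if not (0.0 <= self.mu_beta <= 10.0):
            raise ConfigurationError(f"mu_beta must lie in [0, 10], got {self.mu_beta}")
        if not (0.0 <= self.sigma_beta <= 5.0):
            raise ConfigurationError(f"sigma_beta must lie in [0, 5], got {self.sigma_beta}")


@dataclass(frozen=True)
class HierarchicalPriors:
    """Support bounds of the uniform hyperpriors."""

    mu_alpha_bounds: tuple[float, float] = (0.0, 1.0)
    sigma_alpha_bounds: tuple[float, float] = (0.0, 1.0)
    mu_beta_bounds: tuple[float, float] = (0.0, 10.0)
    sigma_beta_bounds: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        for name in ("mu_alpha_bounds", "sigma_alpha_bounds", "mu_beta_bounds", "sigma_beta_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigurationError(f"{name}: lower bound must be < upper, got ({lo}, {hi})")

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return (self.mu_alpha_bounds, self.sigma_alpha_bounds,
                self.mu_beta_bounds, self.sigma_beta_bounds)


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iterations: int = 16_000
    burn_in: int = 6_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return len(range(self.burn_in, self.n_iterations, self.thin))

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


def paper_mcmc_config(seed: int = 0) -> McmcConfig:
    """The published estimation protocol: 3 x 16,000 / 6,000 burn-in / thin 5."""
    return McmcConfig(n_chains=3, n_iterations=16_000, burn_in=6_000, thin=5, seed=seed)


def fast_mcmc_config(seed: int = 0) -> McmcConfig:
    """Reduced protocol for tests and quick exploration: 3 x 4,000 / 1,000 / thin 2."""
    return McmcConfig(n_chains=3, n_iterations=4_000, burn_in=1_000, thin=2, seed=seed)


@dataclass(frozen=True)
class SubjectDataset:
    """Padded per-subject choice/reward arrays for likelihood evaluation."""

    choices: np.ndarray  # (n_subjects, max_trials) int, padded with 0
    rewards: np.ndarray  # (n_subjects, max_trials) float, padded with 0
    lengths: np.ndarray  # (n_subjects,) int
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.choices.shape[0] == 0:
            raise DataError("dataset must contain at least one subject")
        if np.any(self.lengths < 1):
            raise DataError("every subject must have at least one trial")

    @property
    def n_subjects(self) -> int:
        return self.choices.shape[0]

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    ) -> "SubjectDataset":
        """Build from ``{subject_id: (choices, rewards)}`` sequences."""
        if not sequences:
            raise DataError("dataset must contain at least one subject")
        ids = tuple(sequences)
        lengths = np.array([len(sequences[s][0]) for s in ids], dtype=np.int64)
        t_max = int(lengths.max())
        choices = np.zeros((len(ids), t_max), dtype=np.int64)
        rewards = np.zeros((len(ids), t_max), dtype=np.float64)
        for i, s in enumerate(ids):
            c, r = sequences[s]
            if len(c) != len(r):
                raise DataError(f"subject {s}: choices and rewards differ in length")
            choices[i, : len(c)] = c
            rewards[i, : len(r)] = r
        return cls(choices=choices, rewards=rewards, lengths=lengths, subject_ids=ids)

    @classmethod
    def from_records(cls, records: Sequence[TrialRecord]) -> "SubjectDataset":
        by_subject: dict[str, tuple[list[int], list[int]]] = {}
        for rec in records:
            c, r = by_subject.setdefault(rec.subject_id, ([], []))
            c.append(rec.chosen_deck)
            r.append(rec.reward)
        return cls.from_sequences(by_subject)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SubjectDataset":
        """Build from the tidy trial table (``chosen_deck`` as 'A'/'B' or 0/1)."""
        seqs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sid, sub in frame.groupby("subject_id", sort=False):
            sub = sub.sort_values("trial")
            seqs[str(sid)] = (
                sub["chosen_deck"].map({"A": 0, "B": 1, 0: 0, 1: 1}).to_numpy(),
                sub["reward"].to_numpy(),
            )
        return cls.from_sequences(seqs)


# --------------------------------------------------------------------------
# likelihood kernel (numba-compiled when available, numpy fallback otherwise)


def _loglik_numpy(choices, rewards, lengths, alpha, beta, q0):
    n, t_max = choices.shape
    qa = np.full(n, q0)
    qb = np.full(n, q0)
    out = np.zeros(n)
    rows = np.arange(n)
    for t in range(t_max):
        active = t < lengths
        c = choices[:, t]
        d = beta * (qa - qb)
        z = np.where(c == 0, d, -d)
        out += np.where(active, -np.logaddexp(0.0, -z), 0.0)
        r = rewards[:, t]
        q_chosen = np.where(c == 0, qa, qb)
        q_new = q_chosen + alpha * (r - q_chosen)
        upd = active
        qa = np.where(upd & (c == 0), q_new, qa)
        qb = np.where(upd & (c == 1), q_new, qb)
    return out


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True)
    def _loglik_numba(choices, rewards, lengths, alpha, beta, q0):  # pragma: no cover
        n = choices.shape[0]
        out = np.zeros(n)
        for i in range(n):
            qa = q0
            qb = q0
            a = alpha[i]
            b = beta[i]
            acc = 0.0
            for t in range(lengths[i]):
                d = b * (qa - qb)
                c = choices[i, t]
                z = d if c == 0 else -d
                if z < -30.0:
                    acc += z
                else:
                    acc += -np.log1p(np.exp(-z))
                r = rewards[i, t]
                if c == 0:
                    qa += a * (r - qa)
                else:
                    qb += a * (r - qb)
            out[i] = acc
        return out

    _loglik_kernel = _loglik_numba
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _loglik_kernel = _loglik_numpy
    HAVE_NUMBA = False


def per_subject_log_likelihood(
    dataset: SubjectDataset,
    alphas: np.ndarray,
    betas: np.ndarray,
    q0: float = DEFAULT_Q0,
) -> np.ndarray:
    """Vector of per-subject log-likelihoods of the observed choices."""
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if alphas.shape != (dataset.n_subjects,) or betas.shape != (dataset.n_subjects,):
        raise DataError("need exactly one (alpha, beta) per subject")
    if np.any((alphas < 0) | (alphas > 1)):
        raise DomainError("alpha values must lie in [0, 1]")
    if np.any(betas < 0):
        raise DomainError("beta values must be >= 0")
    return _loglik_kernel(dataset.choices, dataset.rewards, dataset.lengths,
                          alphas, betas, float(q0))


def log_likelihood(
    dataset: SubjectDataset,
    alphas: np.ndarray,
    betas: np.ndarray,
    q0: float = DEFAULT_Q0,
) -> float:
    """Total log-probability of all subjects' choices under the model."""
    return float(per_subject_log_likelihood(dataset, alphas, betas, q0).sum())


# --------------------------------------------------------------------------
# truncated-normal group density


def _truncnorm_logpdf(x, mu, sigma, lo, hi):
    """Log density of N(mu, sigma) truncated to [lo, hi]; -inf outside."""
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    mass = ndtr(b) - ndtr(a)
    if mass <= 0:
        return np.full_like(x, -np.inf)
    out = -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi) - np.log(mass)
    return np.where((x < lo) | (x > hi), -np.inf, out)


# --------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with sampler-provenance attached.

    Arrays are indexed (chain, draw[, subject]); the hyperparameter order is
    ``mu_alpha, sigma_alpha, mu_beta, sigma_beta``.
    """

    alpha: np.ndarray  # (chain, draw, subject)
    beta: np.ndarray  # (chain, draw, subject)
    hypers: np.ndarray  # (chain, draw, 4)
    subject_ids: tuple[str, ...]
    config: McmcConfig
    priors: HierarchicalPriors

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def retained_per_chain(self) -> int:
        return self.alpha.shape[1]

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain

    def get(self, name: str) -> np.ndarray:
        """Draws for one named parameter, shape (chain, draw)."""
        if name in HYPER_NAMES:
            return self.hypers[:, :, HYPER_NAMES.index(name)]
        for prefix, arr in (("alpha", self.alpha), ("beta", self.beta)):
            if name.startswith(prefix + "["):
                sid = name[len(prefix) + 1 : -1]
                return arr[:, :, self.subject_ids.index(sid)]
        raise KeyError(name)

    def parameter_names(self) -> list[str]:
        names = list(HYPER_NAMES)
        names += [f"alpha[{s}]" for s in self.subject_ids]
        names += [f"beta[{s}]" for s in self.subject_ids]
        return names

    def to_inferencedata(self):
        """View as an :mod:`arviz` InferenceData for diagnostics/plotting."""
        import arviz as az

        posterior = {name: self.get(name)[..., None][:, :, 0] for name in HYPER_NAMES}
        posterior["alpha"] = self.alpha
        posterior["beta"] = self.beta
        return az.from_dict(
            posterior=posterior,
            dims={"alpha": ["subject"], "beta": ["subject"]},
            coords={"subject": list(self.subject_ids)},
        )


# --------------------------------------------------------------------------
# sampler


def _init_state(n: int, priors: HierarchicalPriors, rng: np.random.Generator):
    b = priors.bounds
    hypers = np.array([
        rng.uniform(b[0][0] + 0.2 * (b[0][1] - b[0][0]), b[0][1] - 0.2 * (b[0][1] - b[0][0])),
        rng.uniform(0.1 * (b[1][1] - b[1][0]) + b[1][0], 0.5 * (b[1][1] + b[1][0])),
        rng.uniform(b[2][0] + 0.2 * (b[2][1] - b[2][0]), b[2][1] - 0.2 * (b[2][1] - b[2][0])),
        rng.uniform(0.1 * (b[3][1] - b[3][0]) + b[3][0], 0.5 * (b[3][1] + b[3][0])),
    ])
    alpha = np.clip(rng.normal(hypers[0], max(hypers[1], 0.05), size=n), 0.02, 0.98)
    beta = np.clip(rng.normal(hypers[2], max(hypers[3], 0.1), size=n), 0.1, 9.9)
    return alpha, beta, hypers


def _run_chain(
    dataset: SubjectDataset,
    priors: HierarchicalPriors,
    config: McmcConfig,
    rng: np.random.Generator,
    q0: float,
    prior_only: bool,
):
    n = dataset.n_subjects
    alpha, beta, hypers = _init_state(n, priors, rng)

    def loglik(a, b):
        if prior_only:
            return np.zeros(n)
        return _loglik_kernel(dataset.choices, dataset.rewards, dataset.lengths, a, b, q0)

    ll = loglik(alpha, beta)
    scale_a = np.full(n, 0.1)
    scale_b = np.full(n, 0.5)
    scale_h = np.array([0.05, 0.05, 0.4, 0.3])
    acc_a = np.zeros(n)
    acc_b = np.zeros(n)
    acc_h = np.zeros(4)
    batch = 50

    kept = (config.n_iterations - config.burn_in + config.thin - 1) // config.thin
    out_alpha = np.empty((kept, n))
    out_beta = np.empty((kept, n))
    out_hypers = np.empty((kept, 4))
    k = 0

    prior_bounds = priors.bounds

    for it in range(config.n_iterations):
        # ---- subject-level alpha block (independent MH per subject)
        prop = alpha + scale_a * rng.standard_normal(n)
        ok = (prop >= ALPHA_SUPPORT[0]) & (prop <= ALPHA_SUPPORT[1])
        prop_eval = np.where(ok, prop, alpha)
        ll_prop = loglik(prop_eval, beta)
        logr = (
            ll_prop - ll
            + _truncnorm_logpdf(prop_eval, hypers[0], hypers[1], *ALPHA_SUPPORT)
            - _truncnorm_logpdf(alpha, hypers[0], hypers[1], *ALPHA_SUPPORT)
        )
        accept = ok & (np.log(rng.random(n)) < logr)
        alpha = np.where(accept, prop_eval, alpha)
        ll = np.where(accept, ll_prop, ll)
        acc_a += accept

        # ---- subject-level beta block
        prop = beta + scale_b * rng.standard_normal(n)
        ok = (prop >= BETA_SUPPORT[0]) & (prop <= BETA_SUPPORT[1])
        prop_eval = np.where(ok, prop, beta)
        ll_prop = loglik(alpha, prop_eval)
        logr = (
            ll_prop - ll
            + _truncnorm_logpdf(prop_eval, hypers[2], hypers[3], *BETA_SUPPORT)
            - _truncnorm_logpdf(beta, hypers[2], hypers[3], *BETA_SUPPORT)
        )
        accept = ok & (np.log(rng.random(n)) < logr)
        beta = np.where(accept, prop_eval, beta)
        ll = np.where(accept, ll_prop, ll)
        acc_b += accept

        # ---- hyperparameter scalar updates
        for j in range(4):
            lo, hi = prior_bounds[j]
            prop_h = hypers[j] + scale_h[j] * rng.standard_normal()
            if not (lo < prop_h < hi):
                continue
            values, support = (alpha, ALPHA_SUPPORT) if j < 2 else (beta, BETA_SUPPORT)
            mu_cur, sig_cur = hypers[2 * (j // 2)], hypers[2 * (j // 2) + 1]
            if j % 2 == 0:
                mu_new, sig_new = prop_h, sig_cur
            else:
                mu_new, sig_new = mu_cur, prop_h
            if sig_new <= 0:
                continue
            logr = (
                _truncnorm_logpdf(values, mu_new, sig_new, *support).sum()
                - _truncnorm_logpdf(values, mu_cur, sig_cur, *support).sum()
            )
            if np.log(rng.random()) < logr:
                hypers[j] = prop_h
                acc_h[j] += 1

        # ---- burn-in-only proposal adaptation
        if it < config.burn_in and (it + 1) % batch == 0:
            for scales, accs, lo_s, hi_s in (
                (scale_a, acc_a, 1e-3, 1.0),
                (scale_b, acc_b, 1e-3, 5.0),
                (scale_h, acc_h, 1e-3, 3.0),
            ):
                rates = accs / batch
                scales *= np.where(rates > 0.5, 1.4, np.where(rates < 0.2, 0.7, 1.0))
                np.clip(scales, lo_s, hi_s, out=scales)
                accs[:] = 0.0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_alpha[k] = alpha
            out_beta[k] = beta
            out_hypers[k] = hypers
            k += 1

    assert k == kept
    return out_alpha, out_beta, out_hypers


def fit_hierarchical(
    dataset: SubjectDataset,
    priors: HierarchicalPriors | None = None,
    config: McmcConfig | None = None,
    q0: float = DEFAULT_Q0,
    prior_only: bool = False,
    rhat_threshold: float = 1.1,
) -> PosteriorSamples:
    """Sample the hierarchical posterior over subject and group parameters.

    ``prior_only`` disables the likelihood (sampling the prior), which is
    used by prior-recovery checks.  A warning carrying the offending values
    is emitted when any hyperparameter's split R-hat exceeds
    ``rhat_threshold``; the samples are still returned.
    """
    priors = priors or HierarchicalPriors()
    config = config or fast_mcmc_config()
    seed_seq = np.random.SeedSequence(config.seed)
    chains = []
    for child in seed_seq.spawn(config.n_chains):
        rng = np.random.default_rng(child)
        chains.append(_run_chain(dataset, priors, config, rng, q0, prior_only))
    samples = PosteriorSamples(
        alpha=np.stack([c[0] for c in chains]),
        beta=np.stack([c[1] for c in chains]),
        hypers=np.stack([c[2] for c in chains]),
        subject_ids=dataset.subject_ids,
        config=config,
        priors=priors,
    )
    if config.n_chains >= 2:
        diagnostics = rhat(samples)
        worst = {k: v for k, v in diagnostics.items() if np.isfinite(v) and v > rhat_threshold}
        if worst:
            warnings.warn(
                f"R-hat exceeds {rhat_threshold} for {worst}; treat estimates with care",
                ConvergenceWarning,
                stacklevel=2,
            )
    return samples


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, median, and central 95% interval per parameter
    (chains pooled)."""
    rows = []
    for name in samples.parameter_names():
        draws = samples.get(name).ravel()
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {"parameter": name, "mean": draws.mean(), "median": np.median(draws),
             "ci_2.5": lo, "ci_97.5": hi}
        )
    return pd.DataFrame(rows).set_index("parameter")


def rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Rank-normalized split R-hat per parameter (via arviz).

    With a single chain the diagnostic is unavailable and every entry is
    NaN.
    """
    names = samples.parameter_names()
    if samples.n_chains < 2:
        return {name: float("nan") for name in names}
    import arviz as az

    result = az.rhat(samples.to_inferencedata())
    out = {}
    for name in HYPER_NAMES:
        out[name] = float(result[name].values)
    for i, sid in enumerate(samples.subject_ids):
        out[f"alpha[{sid}]"] = float(result["alpha"].values[i])
        out[f"beta[{sid}]"] = float(result["beta"].values[i])
    return out
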