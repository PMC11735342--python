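"""Bayesian inference for zero-inflated, left-censored lognormal residues.

The measurement model: each sample truly contains no analyte with
probability ``p0`` ("zero inflation"); otherwise the concentration C is
lognormal, ln C ~ N(mu, sigma^2).  A sample is reported as a non-detect
when it is a true zero *or* its concentration falls below the limit of
detection, so with alpha = (ln LOD - mu)/sigma the number of non-detects
among N samples is Binomial(N, p0 + (1 - p0) * Phi(alpha)).

Priors (defaults): p0 ~ Beta(1, 1); mu ~ Normal(0, precision 0.01), i.e.
variance 100 — the precision parameterization is the default because that
is the convention of the BUGS-family samplers this prior originates from;
sigma^-2 ~ Gamma(0.1, 0.1).

Posterior sampling is data-augmentation Gibbs: each non-detect gets a
latent label (true zero vs. censored positive) and, when censored, a
latent log-concentration drawn from the normal truncated above at ln LOD.
Given the augmented data every conditional is conjugate (Beta, Normal,
Gamma), so the sampler needs no tuning and mixes quickly.

The population mean concentration of the mixture is
``E[C] = (1 - p0) * exp(mu + sigma^2 / 2)``; its posterior is summarized
by averaging that expression over the retained draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .errors import InsufficientDataError, ValidationError
from .residues import ResidueDataset

__all__ = [
    "CensoredCount",
    "PriorSpec",
    "McmcSettings",
    "PosteriorDraws",
    "ResidueDistribution",
    "censoring_probability",
    "expected_concentration",
    "log_posterior",
    "fit_mcmc",
    "posterior_mean_concentration",
    "sample_concentration",
    "split_rhat",
]


@dataclass(frozen=True)
class CensoredCount:
    """Sufficient statistics of a censored residue sample.

    ``observed_log_values`` are ln(concentration) for the detected samples;
    ``lods`` holds one LOD per *non-detect* (ng/g).  With a shared LOD pass
    a length-1 array or let :meth:`from_values` broadcast it.
    """

    n_total: int
    observed_log_values: np.ndarray
    lods: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_log_values", np.atleast_1d(np.asarray(self.observed_log_values, dtype=float)))
        lods = np.atleast_1d(np.asarray(self.lods, dtype=float))
        n_detected = self.observed_log_values.size
        n_below = self.n_total - n_detected
        if n_below < 0:
            raise ValidationError("more detected values than total samples")
        if lods.size == 1 and n_below > 1:
            lods = np.full(n_below, lods[0])
        if lods.size != n_below and not (n_below == 0 and lods.size <= 1):
            raise ValidationError(f"need one LOD per non-detect ({n_below}), got {lods.size}")
        if np.any(lods <= 0):
            raise ValidationError("all LODs must be positive")
        object.__setattr__(self, "lods", lods[: n_below] if n_below else np.empty(0))

    @property
    def n_detected(self) -> int:
        return self.observed_log_values.size

    @property
    def n_below_lod(self) -> int:
        return self.n_total - self.n_detected

    @classmethod
    def from_values(cls, detected_values: Sequence[float], n_below_lod: int, lod: float | Sequence[float]) -> "CensoredCount":
        vals = np.asarray(detected_values, dtype=float)
        if np.any(vals <= 0):
            raise ValidationError("detected concentrations must be positive")
        lods = np.atleast_1d(np.asarray(lod, dtype=float))
        if lods.size == 1:
            lods = np.full(n_below_lod, lods[0])
        return cls(n_total=vals.size + n_below_lod, observed_log_values=np.log(vals), lods=lods)

    @classmethod
    def from_dataset(cls, dataset: ResidueDataset, analyte: str, food_category: str | None = None) -> "CensoredCount":
        sub = dataset.subset(analyte=analyte, food_category=food_category)
        if len(sub) == 0:
            raise InsufficientDataError(f"no records for {analyte!r} / {food_category!r}")
        detected = [r.value for r in sub.records if r.detected]
        lods = [r.lod for r in sub.records if not r.detected]
        return cls(
            n_total=len(sub),
            observed_log_values=np.log(np.asarray(detected, dtype=float)) if detected else np.empty(0),
            lods=np.asarray(lods, dtype=float) if lods else np.empty(0),
        )


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters for (p0, mu, sigma^-2).

    ``mu_normal`` is (location, scale2) where ``scale2`` is a *precision*
    by default (``mu_parameterization="precision"``) or a variance when
    ``mu_parameterization="variance"``.
    """

    p0_beta: tuple[float, float] = (1.0, 1.0)
    mu_normal: tuple[float, float] = (0.0, 0.01)
    sigma2_inv_gamma: tuple[float, float] = (0.1, 0.1)
    mu_parameterization: str = "precision"

    def __post_init__(self) -> None:
        for name, pair in (("p0_beta", self.p0_beta), ("mu_normal", (1.0, self.mu_normal[1])), ("sigma2_inv_gamma", self.sigma2_inv_gamma)):
            if any(not np.isfinite(v) or v <= 0 for v in pair):
                raise ValidationError(f"{name} hyperparameters must be positive and finite")
        if self.mu_parameterization not in ("precision", "variance"):
            raise ValidationError("mu_parameterization must be 'precision' or 'variance'")

    @property
    def mu_mean(self) -> float:
        return self.mu_normal[0]

    @property
    def mu_precision(self) -> float:
        loc, scale2 = self.mu_normal
        return scale2 if self.mu_parameterization == "precision" else 1.0 / scale2


@dataclass(frozen=True)
class McmcSettings:
    n_iterations: int = 14_000
    n_burn_in: int = 4_000
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_burn_in < self.n_iterations):
            raise ValidationError("need 0 <= n_burn_in < n_iterations")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws of (p0, mu, sigma), flattened across chains."""

    p0: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    chain: np.ndarray
    iteration: np.ndarray

    def __post_init__(self) -> None:
        n = self.p0.size
        if not (self.mu.size == self.sigma.size == self.chain.size == self.iteration.size == n):
            raise ValidationError("draw vectors must have equal length")
        if n and (np.any(self.p0 < 0) or np.any(self.p0 > 1) or np.any(self.sigma <= 0)):
            raise ValidationError("draws out of domain (p0 in [0,1], sigma > 0)")

    def __len__(self) -> int:
        return self.p0.size

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if len(self) else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain": self.chain, "iteration": self.iteration, "p0": self.p0, "mu": self.mu, "sigma": self.sigma}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        f = pd.read_csv(path)
        return cls(
            p0=f["p0"].to_numpy(float),
            mu=f["mu"].to_numpy(float),
            sigma=f["sigma"].to_numpy(float),
            chain=f["chain"].to_numpy(int),
            iteration=f["iteration"].to_numpy(int),
        )


@dataclass(frozen=True)
class ResidueDistribution:
    """Posterior summary of the mixture-mean concentration E[C] (ng/g).

    ``mean_c1``/``sd_c1`` average (1-p0)exp(mu+sigma^2/2) over draws;
    ``plug_in`` evaluates the same expression once at the posterior means.
    With posterior uncertainty in sigma the draw-averaged mean exceeds the
    plug-in (Jensen), so both are reported and not forced to agree.
    """

    mean_c1: float
    sd_c1: float
    plug_in: float
    p0_mean: float
    p0_sd: float
    mu_mean: float
    mu_sd: float
    sigma_mean: float
    sigma_sd: float

    @property
    def p0_percent(self) -> tuple[float, float]:
        """(mean, SD) of p0 expressed in percent, the survey-report convention."""
        return 100.0 * self.p0_mean, 100.0 * self.p0_sd


def censoring_probability(p0: float, mu: float, sigma: float, lod: float) -> float:
    """Probability a sample is reported as a non-detect.

    ``p0 + (1 - p0) * Phi((ln lod - mu) / sigma)``: either a true zero or a
    positive concentration below the detection limit.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    if lod <= 0:
        raise ValidationError(f"lod must be positive, got {lod}")
    alpha = (np.log(lod) - mu) / sigma
    return float(p0 + (1.0 - p0) * ndtr(alpha))


def expected_concentration(p0: float, mu: float, sigma: float) -> float:
    """Mixture mean E[C] = (1 - p0) * exp(mu + sigma^2 / 2), in ng/g."""
    return float((1.0 - p0) * np.exp(mu + sigma**2 / 2.0))


def log_posterior(params: tuple[float, float, float], data: CensoredCount, priors: PriorSpec = PriorSpec()) -> float:
    """Unnormalized log posterior density of (p0, mu, sigma).

    Detected values contribute ``log(1-p0) + log N(y | mu, sigma^2)``;
    each non-detect contributes ``log censoring_probability`` at its own
    LOD (the binomial form is recovered when all LODs coincide); priors on
    p0, mu and sigma^-2 are added.  Boundary p0 in {0, 1} that is
    incompatible with the data yields ``-inf`` rather than an exception.
    """
    p0, mu, sigma = params
    if sigma <= 0 or not (0.0 <= p0 <= 1.0):
        return -np.inf
    y = data.observed_log_values
    lp = 0.0
    if data.n_detected:
        if p0 >= 1.0:
            return -np.inf
        lp += data.n_detected * np.log1p(-p0)
        lp += float(np.sum(stats.norm.logpdf(y, loc=mu, scale=sigma)))
    if data.n_below_lod:
        alpha = (np.log(data.lods) - mu) / sigma
        probs = p0 + (1.0 - p0) * ndtr(alpha)
        if np.any(probs <= 0):
            return -np.inf
        lp += float(np.sum(np.log(probs)))
    a, b = priors.p0_beta
    lp += float(stats.beta.logpdf(p0, a, b))
    tau0 = priors.mu_precision
    lp += float(stats.norm.logpdf(mu, loc=priors.mu_mean, scale=tau0**-0.5))
    ga, gb = priors.sigma2_inv_gamma
    # prior is on the precision sigma^-2; evaluate its gamma density there
    lp += float(stats.gamma.logpdf(sigma**-2, ga, scale=1.0 / gb))
    return lp


def _truncated_normal_below(rng: np.random.Generator, mean: np.ndarray, sd: float, upper: np.ndarray) -> np.ndarray:
    """Draws from N(mean, sd^2) truncated above at ``upper`` (inverse CDF)."""
    z = (upper - mean) / sd
    cap = ndtr(z)
    u = rng.uniform(0.0, 1.0, size=np.shape(z)) * cap
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return mean + sd * ndtri(u)


def fit_mcmc(
    data: CensoredCount,
    priors: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
    *,
    fix_p0: float | None = None,
    fix_mu: float | None = None,
    fix_sigma: float | None = None,
) -> PosteriorDraws:
    """Gibbs sampler for the zero-inflated censored lognormal model.

    Runs ``settings.n_chains`` chains of ``n_iterations`` sweeps each and
    retains everything after ``n_burn_in``, flattened.  Reproducible given
    ``settings.seed``.  The ``fix_*`` arguments clamp a parameter at a
    known value (useful for conjugate-oracle checks and for profiling one
    parameter at a time).

    When every sample is a non-detect, p0 and (mu, sigma) are only weakly
    identified — the sampler still runs but emits a warning.
    """
    if data.n_total < 1:
        raise InsufficientDataError("need at least one sample")
    if data.n_detected == 0:
        warnings.warn(
            "all samples are non-detects: p0 and (mu, sigma) are weakly identified; "
            "posterior is prior-dominated",
            UserWarning,
            stacklevel=2,
        )

    a0, b0 = priors.p0_beta
    mu0, tau0 = priors.mu_mean, priors.mu_precision
    ga, gb = priors.sigma2_inv_gamma
    y_obs = data.observed_log_values
    n_obs = y_obs.size
    sum_obs = float(y_obs.sum())
    log_lods = np.log(data.lods) if data.n_below_lod else np.empty(0)
    n_nd = data.n_below_lod

    keep = settings.n_iterations - settings.n_burn_in
    root = np.random.SeedSequence(settings.seed)
    chains_p0, chains_mu, chains_sigma, chain_ix, iter_ix = [], [], [], [], []

    for c, child in enumerate(root.spawn(settings.n_chains)):
        rng = np.random.default_rng(child)
        # init from data moments (or prior center when nothing detected)
        mu = float(y_obs.mean()) if n_obs else mu0
        sigma = float(y_obs.std()) if n_obs > 1 else 1.0
        sigma = max(sigma, 1e-3)
        p0 = (n_nd + 1.0) / (data.n_total + 2.0)
        if fix_mu is not None:
            mu = fix_mu
        if fix_sigma is not None:
            sigma = fix_sigma
        if fix_p0 is not None:
            p0 = fix_p0

        p0_out = np.empty(keep)
        mu_out = np.empty(keep)
        sig_out = np.empty(keep)

        for it in range(settings.n_iterations):
            # --- augment non-detects: true zero vs censored positive
            if n_nd:
                alpha = (log_lods - mu) / sigma
                phi = ndtr(alpha)
                denom = p0 + (1.0 - p0) * phi
                w_zero = np.where(denom > 0, p0 / np.maximum(denom, 1e-300), 1.0)
                is_zero = rng.uniform(size=n_nd) < w_zero
                cens = ~is_zero
                n_cens = int(cens.sum())
                if n_cens:
                    y_lat = _truncated_normal_below(rng, np.full(n_cens, mu), sigma, log_lods[cens])
                else:
                    y_lat = np.empty(0)
                n_zero = n_nd - n_cens
            else:
                y_lat = np.empty(0)
                n_zero = n_cens = 0

            n_pos = n_obs + n_cens
            sum_y = sum_obs + float(y_lat.sum())

            # --- p0 | labels  ~ Beta
            if fix_p0 is None:
                p0 = rng.beta(a0 + n_zero, b0 + data.n_total - n_zero)

            # --- mu | y, sigma  ~ Normal (conjugate)
            if fix_mu is None:
                prec = tau0 + n_pos / sigma**2
                mean = (tau0 * mu0 + sum_y / sigma**2) / prec
                mu = rng.normal(mean, prec**-0.5)

            # --- sigma^-2 | y, mu  ~ Gamma (conjugate)
            if fix_sigma is None:
                if n_pos:
                    ss = float(np.sum((y_obs - mu) ** 2)) + float(np.sum((y_lat - mu) ** 2))
                else:
                    ss = 0.0
                prec_draw = rng.gamma(ga + n_pos / 2.0, 1.0 / (gb + ss / 2.0))
                sigma = prec_draw**-0.5

            if it >= settings.n_burn_in:
                k = it - settings.n_burn_in
                p0_out[k] = p0
                mu_out[k] = mu
                sig_out[k] = sigma

        chains_p0.append(p0_out)
        chains_mu.append(mu_out)
        chains_sigma.append(sig_out)
        chain_ix.append(np.full(keep, c))
        iter_ix.append(np.arange(settings.n_burn_in, settings.n_iterations))

    return PosteriorDraws(
        p0=np.concatenate(chains_p0),
        mu=np.concatenate(chains_mu),
        sigma=np.concatenate(chains_sigma),
        chain=np.concatenate(chain_ix),
        iteration=np.concatenate(iter_ix),
    )


def posterior_mean_concentration(draws: PosteriorDraws) -> ResidueDistribution:
    """Posterior of the mixture mean E[C] = (1-p0)exp(mu + sigma^2/2)."""
    if len(draws) == 0:
        raise InsufficientDataError("no retained draws")
    per_draw = (1.0 - draws.p0) * np.exp(draws.mu + draws.sigma**2 / 2.0)
    mean = float(per_draw.mean())
    sd = float(per_draw.std(ddof=1)) if len(draws) > 1 else 0.0
    p0m, mum, sgm = float(draws.p0.mean()), float(draws.mu.mean()), float(draws.sigma.mean())
    return ResidueDistribution(
        mean_c1=mean,
        sd_c1=sd,
        plug_in=expected_concentration(p0m, mum, sgm),
        p0_mean=p0m,
        p0_sd=float(draws.p0.std(ddof=1)) if len(draws) > 1 else 0.0,
        mu_mean=mum,
        mu_sd=float(draws.mu.std(ddof=1)) if len(draws) > 1 else 0.0,
        sigma_mean=sgm,
        sigma_sd=float(draws.sigma.std(ddof=1)) if len(draws) > 1 else 0.0,
    )


def sample_concentration(draws: PosteriorDraws, n: int, seed: int) -> np.ndarray:
    """Posterior-predictive concentrations (ng/g).

    Each sample picks one retained draw uniformly, then is 0 with
    probability p0 and lognormal(mu, sigma) otherwise.
    """
    if len(draws) == 0:
        raise InsufficientDataError("no retained draws")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ix = rng.integers(0, len(draws), size=n)
    zero = rng.uniform(size=n) < draws.p0[ix]
    out = np.exp(rng.normal(draws.mu[ix], draws.sigma[ix]))
    out[zero] = 0.0
    return out


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat convergence diagnostic for one parameter's draws.

    Each chain (or the single chain) is split in half; R-hat compares
    between-half and within-half variances.  Values near 1 indicate the
    chains have mixed.
    """
    x = np.asarray(x, dtype=float)
    m = x.size // 2
    halves = np.stack([x[:m], x[m : 2 * m]])
    w = halves.var(axis=1, ddof=1).mean()
    b = m * halves.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (m - 1) / m * w + b / m
    return float(np.sqrt(var_plus / w))
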