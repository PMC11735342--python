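"""Monte-Carlo simulation of estimated daily intake (EDI).

EDI = C x IR / BW in ng/kg body weight/day, where C is the residue
concentration (ng/g), IR the daily ingestion rate of the food (g/day,
lognormal) and BW the body weight (kg, normal truncated at zero).  Two
concentration sources are supported:

* the posterior-predictive mixture from the Bayesian censored model
  (:class:`~bpdrisk.censored.PosteriorDraws`), and
* a plain lognormal fitted directly to the residue data
  (:class:`LogNormalFit`), with non-detects handled by left-censored
  maximum likelihood (default) or LOD/2 substitution.

C, IR and BW are sampled independently; observed correlations between
analytes are not propagated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .censored import CensoredCount, PosteriorDraws, sample_concentration
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "ConsumptionProfile",
    "EdiDraws",
    "LogNormalFit",
    "lognormal_params_from_mean_sd",
    "fit_c2_distribution",
    "simulate_edi",
    "total_edi",
    "percentile",
]

AGE_GROUPS = ("0-3", "3-6", "6-12", "12-16", "16-18", "19-65", ">65")

_SIGMA_FLOOR = 1e-8


def lognormal_params_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD.

    sigma^2 = ln(1 + (sd/mean)^2); mu = ln(mean) - sigma^2/2.  An sd of 0
    degenerates to a point mass (sigma = 0 is returned as-is and handled
    downstream)."""
    if mean <= 0:
        raise ValidationError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


@dataclass(frozen=True)
class ConsumptionProfile:
    """Ingestion-rate and body-weight distributions for one age group.

    ``ir`` maps food category -> (arithmetic mean, SD) of the lognormal
    daily ingestion rate in g/day; ``bw`` is (mean, SD) of the normal body
    weight in kg, truncated at zero when sampling.
    """

    age_group: str
    ir: dict[str, tuple[float, float]]
    bw: tuple[float, float]

    def __post_init__(self) -> None:
        for food, (m, s) in self.ir.items():
            if m <= 0 or s < 0:
                raise ValidationError(f"{self.age_group}/{food}: ir mean must be > 0, sd >= 0")
        if self.bw[0] <= 0 or self.bw[1] < 0:
            raise ValidationError(f"{self.age_group}: bw mean must be > 0, sd >= 0")


@dataclass(frozen=True)
class EdiDraws:
    """Simulated daily-intake samples for one (age group, analyte, food) cell.

    ``components`` optionally retains the aligned per-iteration input draws
    (concentration, ingestion rate, body weight) so downstream sensitivity
    analysis can correlate inputs with outputs.
    """

    age_group: str
    analyte: str
    food_category: str
    values: np.ndarray
    components: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValidationError("EDI draws must be a 1-D vector")
        if np.any(vals < 0):
            raise ValidationError("EDI draws must be nonnegative")
        object.__setattr__(self, "values", vals)

    @property
    def n_iterations(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class LogNormalFit:
    """Lognormal concentration model fitted directly to residue data."""

    mu: float
    sigma: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


def fit_c2_distribution(data: CensoredCount, method: str = "censored-mle") -> LogNormalFit:
    """Fit a lognormal to residue data with non-detects.

    ``censored-mle`` (default) maximizes the likelihood with each
    non-detect contributing the log-CDF at its own LOD; ``substitution``
    replaces non-detects by LOD/2 and takes moments of the logs.  At least
    2 detected values are required.  A fit with (numerically) zero log-SD
    is returned with ``degenerate=True``.
    """
    if data.n_detected < 2:
        raise InsufficientDataError("censored lognormal fit needs >= 2 detected values")
    y = data.observed_log_values

    if method == "substitution":
        logs = np.concatenate([y, np.log(data.lods / 2.0)]) if data.n_below_lod else y
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=1))
        return LogNormalFit(mu=mu, sigma=max(sigma, 0.0), method=method, degenerate=sigma < 1e-6)
    if method != "censored-mle":
        raise ValidationError(f"unknown method {method!r}")

    if data.n_below_lod == 0:
        # closed-form MLE: mean and (ML, ddof=0) SD of the logs
        mu = float(y.mean())
        sigma = float(y.std(ddof=0))
        return LogNormalFit(mu=mu, sigma=sigma, method=method, degenerate=sigma < 1e-6)

    log_lods = np.log(data.lods)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        ll = np.sum(stats.norm.logpdf(y, mu, sigma))
        ll += np.sum(stats.norm.logcdf(log_lods, mu, sigma))
        return -float(ll)

    x0 = np.array([y.mean(), np.log(max(y.std(ddof=0), 1e-2))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return LogNormalFit(mu=mu, sigma=sigma, method=method, degenerate=sigma < 1e-6)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    mu, sigma = lognormal_params_from_mean_sd(mean, sd)
    return np.exp(rng.normal(mu, sigma, size=n))


def _draw_bw(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal body weights truncated at zero by redrawing."""
    if sd == 0:
        return np.full(n, mean)
    if mean <= 3 * sd:
        warnings.warn(
            f"body-weight distribution N({mean}, {sd}^2) puts non-trivial mass below 0; "
            "truncation will noticeably reshape it",
            UserWarning,
            stacklevel=3,
        )
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _draw_concentration(source, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(source, PosteriorDraws):
        return sample_concentration(source, n, seed=int(rng.integers(0, 2**31 - 1)))
    if isinstance(source, LogNormalFit):
        if source.sigma == 0:
            return np.full(n, np.exp(source.mu))
        return np.exp(rng.normal(source.mu, source.sigma, size=n))
    if np.isscalar(source):
        return np.full(n, float(source))
    raise ValidationError(f"unsupported concentration source {type(source)!r}")


def simulate_edi(
    conc_source,
    profile: ConsumptionProfile,
    food_category: str,
    analyte: str = "",
    n_iterations: int = 10_000,
    seed: int = 0,
    *,
    keep_components: bool = False,
    ir_draws: np.ndarray | None = None,
    bw_draws: np.ndarray | None = None,
) -> EdiDraws:
    """Monte-Carlo EDI draws for one (age group, analyte, food) cell.

    Per iteration, draws C (posterior-predictive mixture, lognormal fit or
    a degenerate constant), IR (lognormal, g/day) and BW (truncated normal,
    kg) independently and returns C*IR/BW in ng/kg/day.  ``ir_draws`` /
    ``bw_draws`` allow the caller to share one stream of IR or BW draws
    across cells — required for joint sensitivity analysis, where body
    weight is a single variable common to every food.
    """
    if food_category not in profile.ir:
        raise ValidationError(f"profile {profile.age_group!r} has no ingestion rate for {food_category!r}")
    rng = np.random.default_rng(seed)
    c = _draw_concentration(conc_source, rng, n_iterations)
    if ir_draws is None:
        ir_draws = _draw_lognormal(rng, *profile.ir[food_category], n_iterations)
    if bw_draws is None:
        bw_draws = _draw_bw(rng, *profile.bw, n_iterations)
    edi = c * ir_draws / bw_draws
    comps = {"concentration": c, "ingestion_rate": ir_draws, "body_weight": bw_draws} if keep_components else None
    return EdiDraws(
        age_group=profile.age_group,
        analyte=analyte,
        food_category=food_category,
        values=edi,
        components=comps,
    )


def total_edi(parts: list[EdiDraws]) -> EdiDraws:
    """Iteration-wise sum of EDI draws across foods (and analytes).

    All parts must share the age group and iteration count; parts are
    expected to come from independent streams.  Summing draw-wise before
    taking quantiles is the default convention for totals.
    """
    if not parts:
        raise ValidationError("need at least one EdiDraws part")
    n = parts[0].n_iterations
    group = parts[0].age_group
    for p in parts[1:]:
        if p.n_iterations != n:
            raise ValidationError("mismatched iteration counts in total_edi")
        if p.age_group != group:
            raise ValidationError("total_edi parts must share the age group")
    values = np.sum([p.values for p in parts], axis=0)
    analytes = sorted({p.analyte for p in parts if p.analyte})
    foods = sorted({p.food_category for p in parts})
    return EdiDraws(
        age_group=group,
        analyte="+".join(analytes) if len(analytes) > 1 else (analytes[0] if analytes else ""),
        food_category="+".join(foods) if len(foods) > 1 else foods[0],
        values=values,
    )


def percentile(draws: EdiDraws | np.ndarray, p: float) -> float:
    """Empirical quantile with linear interpolation between order statistics.

    The convention matters in the P97.5 tail of 10,000 draws, so it is
    fixed here (numpy's ``linear`` method) rather than left to callers.
    """
    values = draws.values if isinstance(draws, EdiDraws) else np.asarray(draws, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("no draws")
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p must be in (0, 1), got {p}")
    return float(np.quantile(values, p, method="linear"))
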