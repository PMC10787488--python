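"""Fitting and sampling of the model's stochastic inputs.

Daily arrivals follow a negative binomial distribution fitted to a printed
mean/SD by the method of moments; when the variance does not exceed the
mean (no overdispersion) the sampler falls back to Poisson. Durations --
operative time, lab clean-up, length of stay, pre-operative stay -- follow
lognormal distributions truncated to the tabulated min/max range, sampled
by inverse-CDF. Stays are rounded to whole days (half-up), and the pre-op
stay is conditioned on not exceeding the realized length of stay, so the
post-operative stay (LOS minus pre-op) is never negative.

Three readings of the tabulated mean/SD are provided:
:func:`fit_truncated_lognormal` treats them as the *untruncated*
lognormal's moments (closed-form fit, then truncate);
``fit_truncated_lognormal(..., refit=True)`` solves for both truncated
moments (not always feasible); :func:`fit_mean_calibrated` -- the
simulation engine's default -- keeps the closed-form shape but shifts the
location so the truncated mean reproduces the tabulated mean, which is
the right reading when the tabulated values are sample statistics of
already-bounded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .input_model import DurationSpec, ProcedureClass, WeekdayAllocation

__all__ = [
    "DistributionError",
    "NegBinParams",
    "LogNormalParams",
    "fit_negative_binomial",
    "fit_truncated_lognormal",
    "fit_mean_calibrated",
    "sample_truncated",
    "sample_truncated_batch",
    "sample_integer_days",
    "sample_integer_days_batch",
    "sample_preop_given_los",
    "sample_daily_arrivals",
    "draw_procedure_class",
    "assign_physician",
    "round_half_up",
]

#: Truncation intervals carrying less lognormal mass than this are rejected
#: (they would make rejection sampling loop indefinitely).
MIN_TRUNCATION_MASS = 1e-12


class DistributionError(ValueError):
    """Invalid distribution parameters or an impossible sampling request."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class NegBinParams:
    """Negative binomial in (r, p) form: mean r(1-p)/p, variance r(1-p)/p^2.

    ``fallback_poisson`` marks under/equi-dispersed inputs (variance <= mean),
    sampled as Poisson(mean) instead.
    """

    r: float
    p: float
    mean: float
    fallback_poisson: bool = False

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise DistributionError(f"arrival mean must be > 0, got {self.mean}")
        if not self.fallback_poisson and not (self.r > 0 and 0 < self.p <= 1):
            raise DistributionError(f"invalid negative-binomial params r={self.r}, p={self.p}")

    @property
    def variance(self) -> float:
        if self.fallback_poisson:
            return self.mean
        return self.r * (1 - self.p) / self.p**2


def fit_negative_binomial(mean: float, sd: float) -> NegBinParams:
    """Method-of-moments negative binomial fit from a mean and SD.

    r = mean^2 / (var - mean), p = r / (r + mean).  Returns a Poisson
    fallback when var <= mean (the negative binomial cannot be
    under-dispersed).
    """
    if mean <= 0:
        raise DistributionError(f"arrival mean must be > 0, got {mean}")
    if sd < 0:
        raise DistributionError(f"arrival SD must be >= 0, got {sd}")
    var = sd * sd
    if var <= mean:
        return NegBinParams(r=math.nan, p=math.nan, mean=mean, fallback_poisson=True)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return NegBinParams(r=r, p=p, mean=mean)


def _phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


@dataclass(frozen=True)
class LogNormalParams:
    """Lognormal(mu_log, sigma_log) truncated to [lower, upper].

    ``sigma_log == 0`` denotes a constant at exp(mu_log).
    """

    mu_log: float
    sigma_log: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise DistributionError(f"sigma_log must be >= 0, got {self.sigma_log}")
        if self.lower > self.upper:
            raise DistributionError(
                f"truncation interval inverted: [{self.lower}, {self.upper}]"
            )

    @property
    def is_constant(self) -> bool:
        return self.sigma_log == 0

    @property
    def constant_value(self) -> float:
        return math.exp(self.mu_log)

    def truncation_mass(self) -> float:
        """Probability mass of [lower, upper] under the untruncated lognormal."""
        if self.is_constant:
            return 1.0 if self.lower <= self.constant_value <= self.upper else 0.0
        f_lo = 0.0
        if self.lower > 0:
            f_lo = _phi((math.log(self.lower) - self.mu_log) / self.sigma_log)
        f_hi = _phi((math.log(self.upper) - self.mu_log) / self.sigma_log)
        return f_hi - f_lo

    def untruncated_moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the untruncated lognormal."""
        m = math.exp(self.mu_log + self.sigma_log**2 / 2)
        v = (math.exp(self.sigma_log**2) - 1) * m * m
        return m, math.sqrt(v)

    def truncated_moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the truncated lognormal."""
        if self.is_constant:
            return self.constant_value, 0.0
        s, scale = self.sigma_log, math.exp(self.mu_log)
        a = -math.inf if self.lower <= 0 else (math.log(self.lower) - self.mu_log) / s
        b = (math.log(self.upper) - self.mu_log) / s
        # E[X^k | a < Z < b] for X = exp(mu + s Z)
        denom = _phi(b) - _phi(a)
        if denom < MIN_TRUNCATION_MASS:
            raise DistributionError("truncation interval carries (almost) no mass")

        def raw(k: int) -> float:
            lo = 0.0 if a == -math.inf else _phi(a - k * s)
            return math.exp(k * self.mu_log + 0.5 * k * k * s * s) * (
                (_phi(b - k * s) - lo) / denom
            )

        m1, m2 = raw(1), raw(2)
        return m1, math.sqrt(max(m2 - m1 * m1, 0.0))


def _moment_match(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def fit_truncated_lognormal(spec: DurationSpec, refit: bool = False) -> LogNormalParams:
    """Moment-match a lognormal to a DurationSpec and truncate to its range.

    By default sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2 on
    the untruncated scale (constant when sd == 0).  With ``refit=True``,
    (mu, sigma) are solved numerically so the *truncated* distribution's
    moments match the spec instead.
    """
    if spec.mean <= 0:
        raise DistributionError(f"duration mean must be > 0, got {spec.mean}")
    if spec.is_constant:
        return LogNormalParams(
            mu_log=math.log(spec.mean), sigma_log=0.0, lower=spec.min, upper=spec.max
        )
    mu, sigma = _moment_match(spec.mean, spec.sd)
    params = LogNormalParams(mu_log=mu, sigma_log=sigma, lower=spec.min, upper=spec.max)
    if not refit:
        return params

    # nested solve: for each sigma, mu is pinned by the truncated mean
    # (monotone in mu), then sigma is chosen to match the truncated SD.
    # Solutions whose truncation window keeps almost no mass are rejected:
    # the truncated SD saturates below the printed value for some
    # summaries, in which case no acceptable fit exists.
    def sd_at(sig: float) -> float | None:
        mu_s = _calibrate_mu(sig, spec.min, spec.max, spec.mean, mu)
        if mu_s is None:
            return None
        cand = LogNormalParams(
            mu_log=mu_s, sigma_log=sig, lower=spec.min, upper=spec.max
        )
        if cand.truncation_mass() < 1e-9:
            return None
        return cand.truncated_moments()[1]

    infeasible = DistributionError(
        f"no truncated lognormal on [{spec.min}, {spec.max}] with mean "
        f"{spec.mean} attains SD {spec.sd} (refit infeasible)"
    )
    lo_sig, hi_sig = 1e-6, max(sigma, 0.05)
    for _ in range(200):
        sd_hi = sd_at(hi_sig)
        if sd_hi is None:
            raise infeasible
        if sd_hi >= spec.sd:
            break
        hi_sig *= 1.25
    else:
        raise infeasible
    sig_star = optimize.brentq(
        lambda s: (sd_at(s) or 0.0) - spec.sd, lo_sig, hi_sig, xtol=1e-10
    )
    mu_star = _calibrate_mu(sig_star, spec.min, spec.max, spec.mean, mu)
    if mu_star is None:
        raise infeasible
    return LogNormalParams(
        mu_log=float(mu_star), sigma_log=float(sig_star),
        lower=spec.min, upper=spec.max,
    )


def _calibrate_mu(
    sigma: float, lower: float, upper: float, target_mean: float, mu0: float
) -> float | None:
    """Solve for mu such that the truncated mean equals ``target_mean``.

    The truncated mean is increasing in mu and spans (lower, upper); returns
    None when a bracket cannot be established (degenerate inputs).
    """
    if not (lower + 1e-12 < target_mean < upper - 1e-12):
        return None

    def gap(mu: float) -> float:
        cand = LogNormalParams(mu_log=mu, sigma_log=sigma, lower=lower, upper=upper)
        if cand.truncation_mass() < MIN_TRUNCATION_MASS:
            # monotone continuation: vanished mass piles up at the near bound
            return (lower if mu < mu0 else upper) - target_mean
        return cand.truncated_moments()[0] - target_mean

    lo, hi = mu0 - 1.0, mu0 + 1.0
    for _ in range(80):
        if gap(lo) < 0:
            break
        lo -= 1.0
    for _ in range(80):
        if gap(hi) > 0:
            break
        hi += 1.0
    if not (gap(lo) < 0 < gap(hi)):
        return None
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def fit_mean_calibrated(spec: DurationSpec) -> LogNormalParams:
    """Lognormal fit whose *truncated* mean reproduces the spec mean.

    Tabulated duration summaries are sample statistics of already-bounded
    data, so a plain moment fit followed by truncation realizes a mean
    above the printed one (the lower bound cuts small values).  This fit
    keeps sigma from the untruncated moment match but shifts mu so the
    truncated distribution's mean equals ``spec.mean`` exactly.  A full
    two-moment refit under truncation is not always feasible (some
    tabulated SDs exceed the maximum variance any distribution on
    [min, max] with that mean can have), so only the mean is calibrated.

    Falls back to the plain fit when the mean sits on a truncation bound
    or the calibrated interval would carry negligible mass.
    """
    params = fit_truncated_lognormal(spec)
    if params.is_constant:
        return params
    mu_star = _calibrate_mu(
        params.sigma_log, spec.min, spec.max, spec.mean, params.mu_log
    )
    if mu_star is None:
        return params
    cand = LogNormalParams(mu_log=mu_star, sigma_log=params.sigma_log,
                           lower=spec.min, upper=spec.max)
    # a target mean very close to a bound forces a near-degenerate fit;
    # keep the uncalibrated fit rather than a window of negligible mass
    if cand.truncation_mass() < 1e-6:
        return params
    return cand


def _check_mass(params: LogNormalParams) -> None:
    if params.truncation_mass() < MIN_TRUNCATION_MASS:
        raise DistributionError(
            f"truncation interval [{params.lower}, {params.upper}] carries "
            "(almost) no probability mass under the fitted lognormal"
        )


def _cdf_bounds(params: LogNormalParams) -> tuple[float, float]:
    f_lo = 0.0
    if params.lower > 0:
        f_lo = _phi((math.log(params.lower) - params.mu_log) / params.sigma_log)
    f_hi = _phi((math.log(params.upper) - params.mu_log) / params.sigma_log)
    return f_lo, f_hi


def sample_truncated(params: LogNormalParams, rng: np.random.Generator) -> float:
    """One draw from the truncated lognormal, by inverse-CDF.

    A uniform draw on [F(lower), F(upper)] is pushed through the lognormal
    quantile function; this is distributionally identical to rejection from
    the untruncated lognormal but costs one uniform per draw regardless of
    how little mass the truncation window carries.
    """
    if params.is_constant:
        v = params.constant_value
        if not (params.lower - 1e-9 <= v <= params.upper + 1e-9):
            raise DistributionError("constant value outside truncation interval")
        return min(max(v, params.lower), params.upper)
    _check_mass(params)
    f_lo, f_hi = _cdf_bounds(params)
    u = f_lo + rng.random() * (f_hi - f_lo)
    v = math.exp(params.mu_log + params.sigma_log * float(special.ndtri(u)))
    return min(max(v, params.lower), params.upper)


def sample_truncated_batch(
    params: LogNormalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized inverse-CDF sampling of ``n`` truncated-lognormal draws."""
    if n <= 0:
        return np.empty(0)
    if params.is_constant:
        return np.full(n, min(max(params.constant_value, params.lower), params.upper))
    _check_mass(params)
    f_lo, f_hi = _cdf_bounds(params)
    u = f_lo + rng.random(n) * (f_hi - f_lo)
    v = np.exp(params.mu_log + params.sigma_log * special.ndtri(u))
    return np.clip(v, params.lower, params.upper)


def _integer_bounds(params: LogNormalParams) -> tuple[int, int]:
    return math.ceil(params.lower), math.floor(params.upper)


def sample_integer_days(params: LogNormalParams, rng: np.random.Generator) -> int:
    """A whole-day draw: truncated lognormal, rounded half-up, clamped to
    the integer part of the truncation range."""
    lo, hi = _integer_bounds(params)
    if lo > hi:
        raise DistributionError(
            f"truncation interval [{params.lower}, {params.upper}] contains no integer"
        )
    k = round_half_up(sample_truncated(params, rng))
    return min(max(k, lo), hi)


def sample_integer_days_batch(
    params: LogNormalParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = _integer_bounds(params)
    if lo > hi:
        raise DistributionError(
            f"truncation interval [{params.lower}, {params.upper}] contains no integer"
        )
    k = np.floor(sample_truncated_batch(params, n, rng) + 0.5).astype(np.int64)
    return np.clip(k, lo, hi)


def sample_preop_given_los(
    preop: LogNormalParams, los_days: int, rng: np.random.Generator
) -> int:
    """Integer pre-operative stay conditioned on the realized length of stay.

    Resamples until the draw does not exceed ``los_days`` so the implied
    post-operative stay (LOS - pre-op) is non-negative; the distribution
    below the cap is unchanged.
    """
    if los_days < 1:
        raise DistributionError(f"length of stay must be >= 1 day, got {los_days}")
    lo, _ = _integer_bounds(preop)
    hi = min(math.floor(preop.upper), los_days)
    if lo > hi:
        raise DistributionError(
            f"pre-op range [{preop.lower}, {preop.upper}] incompatible with "
            f"length of stay {los_days} (config inconsistency)"
        )
    if preop.is_constant:
        k = round_half_up(preop.constant_value)
        return min(max(k, lo), hi)
    if hi >= math.floor(preop.upper):
        return sample_integer_days(preop, rng)
    # resampling until the rounded draw is <= hi is distributionally
    # identical to truncating the continuous draw just below hi + 0.5
    capped = LogNormalParams(
        mu_log=preop.mu_log, sigma_log=preop.sigma_log,
        lower=preop.lower, upper=min(preop.upper, hi + 0.5 - 1e-9),
    )
    if capped.truncation_mass() < MIN_TRUNCATION_MASS:
        raise DistributionError(
            f"pre-op draws cannot fall below the LOS cap {hi} "
            f"(params {preop}); check the configuration"
        )
    k = round_half_up(sample_truncated(capped, rng))
    return min(max(k, lo), hi)


def sample_daily_arrivals(params: NegBinParams, rng: np.random.Generator) -> int:
    """One day's arrival count (negative binomial, or Poisson fallback)."""
    if params.fallback_poisson:
        return int(rng.poisson(params.mean))
    return int(rng.negative_binomial(params.r, params.p))


def draw_procedure_class(
    classes: Sequence[ProcedureClass], rng: np.random.Generator
) -> ProcedureClass:
    """Categorical draw of a procedure type by its (normalized) proportion."""
    if not classes:
        raise DistributionError("empty procedure-class list")
    cum = np.cumsum([pc.proportion for pc in classes])
    idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    return classes[min(idx, len(classes) - 1)]


def assign_physician(
    weekday: str, alloc: WeekdayAllocation, rng: np.random.Generator
) -> str:
    """Assign physician slot "A" (probability p_first) or "B" for a workday."""
    if alloc.weekday != weekday:
        raise DistributionError(
            f"allocation is for {alloc.weekday}, procedure day is {weekday}"
        )
    return "A" if rng.random() < alloc.p_first else "B"
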