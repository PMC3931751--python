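"""Poisson statistics for limiting-dilution PCR.

When a standard is diluted to a handful of molecules per reaction, the number
of template molecules actually captured in a well is Poisson distributed, so
the fraction of wells with any detectable product is 1 - exp(-lambda).
Comparing observed positive fractions with this expectation across a dilution
series verifies the nominal concentration of a standard; maximising the
corresponding binomial likelihood over the concentration gives the classic
most-probable-number (MPN) estimate with a profile-likelihood interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateFitError, InvalidInputError

#: chi-square(1)/2 drop in log-likelihood bounding a 95% profile interval
_PROFILE_DROP = 1.92


@dataclass(frozen=True)
class DilutionLevel:
    """One dilution level: nominal copies per reaction and replicate outcomes."""

    expected_copies: float
    n_replicates: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.expected_copies < 0:
            raise InvalidInputError("expected_copies must be >= 0")
        if not 0 <= self.n_positive <= self.n_replicates:
            raise InvalidInputError("need 0 <= n_positive <= n_replicates")


@dataclass(frozen=True)
class DilutionSeries:
    """A limiting-dilution design for one gene, levels sorted by decreasing copies."""

    gene: str
    levels: tuple[DilutionLevel, ...]

    def __init__(self, gene: str, levels: Sequence[DilutionLevel]):
        object.__setattr__(self, "gene", gene)
        object.__setattr__(
            self,
            "levels",
            tuple(sorted(levels, key=lambda l: -l.expected_copies)),
        )


@dataclass(frozen=True)
class AccuracyFit:
    """Observed-vs-expected positive-fraction regression."""

    points: tuple[tuple[float, float], ...]  # (expected fraction, observed fraction)
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class MpnEstimate:
    """Maximum-likelihood concentration from positive/negative outcomes.

    ``flag`` is ``"ok"`` for an interior estimate, ``"all_negative"`` (point
    estimate 0, upper bound only) or ``"all_positive"`` (lower bound only, no
    point estimate).
    """

    concentration: float | None  # molecules per microlitre
    log_likelihood: float
    ci_low: float | None
    ci_high: float | None
    flag: str = "ok"


def expected_positive_fraction(lambda_copies: float) -> float:
    """Poisson probability that a reaction receives at least one molecule."""
    if lambda_copies < 0:
        raise InvalidInputError(f"negative expected copies: {lambda_copies}")
    return float(-np.expm1(-lambda_copies))


def accuracy_curve(
    series: Sequence[DilutionSeries] | DilutionSeries,
    pooling: str = "pooled",
) -> AccuracyFit | dict[str, AccuracyFit]:
    """OLS fit of observed on expected positive fraction across dilution levels.

    ``pooling="pooled"`` averages the observed fraction across genes at each
    nominal level (the headline accuracy figure); ``"per_gene"`` returns one
    fit per series keyed by gene.  Saturated endpoints are included — dropping
    them is a caller decision.
    """
    if isinstance(series, DilutionSeries):
        series = [series]
    if pooling == "per_gene":
        return {s.gene: _fit_one(_points(s.levels)) for s in series}
    if pooling != "pooled":
        raise InvalidInputError(f"unknown pooling mode {pooling!r}")
    by_level: dict[float, list[float]] = {}
    for s in series:
        for lvl in s.levels:
            if lvl.n_replicates < 1:
                continue
            by_level.setdefault(lvl.expected_copies, []).append(lvl.n_positive / lvl.n_replicates)
    points = [
        (expected_positive_fraction(lam), float(np.mean(obs)))
        for lam, obs in sorted(by_level.items())
    ]
    return _fit_one(points)


def _points(levels: Sequence[DilutionLevel]) -> list[tuple[float, float]]:
    return [
        (expected_positive_fraction(l.expected_copies), l.n_positive / l.n_replicates)
        for l in levels
        if l.n_replicates >= 1
    ]


def _fit_one(points: Sequence[tuple[float, float]]) -> AccuracyFit:
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if len(points) >= 1 and np.allclose(x, x[0] if len(x) else 0.0):
        raise DegenerateFitError("all expected fractions identical; cannot fit")
    if len(points) < 3:
        raise InvalidInputError("accuracy_curve needs at least 3 informative levels")
    res = stats.linregress(x, y)
    return AccuracyFit(
        points=tuple((float(a), float(b)) for a, b in points),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def _log_likelihood(c: float, vd: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    """Binomial log-likelihood of outcomes at concentration ``c`` (per ul)."""
    lam = c * vd
    with np.errstate(divide="ignore"):
        log_p = np.where(lam > 0, np.log(-np.expm1(-np.maximum(lam, 1e-300))), -np.inf)
    ll = np.where(k > 0, k * log_p, 0.0) - (n - k) * lam
    return float(np.sum(ll))


def mpn_estimate(series: DilutionSeries, volume_per_reaction: float = 1.0) -> MpnEstimate:
    """Most-probable-number concentration estimate from a dilution series.

    The top level (largest nominal copies) defines relative dilution d = 1;
    lower levels scale as their nominal copy ratio.  The likelihood
    sum_i [k_i log(1 - exp(-c v d_i)) - (n_i - k_i) c v d_i] is maximised over
    c > 0 with a bracketed root of its derivative; the 95% CI is the profile
    interval at a log-likelihood drop of 1.92.
    """
    levels = [l for l in series.levels if l.n_replicates > 0 and l.expected_copies > 0]
    if not levels:
        raise InvalidInputError("series has no informative level")
    top = levels[0].expected_copies
    vd = np.array([l.expected_copies / top for l in levels]) * volume_per_reaction
    n = np.array([l.n_replicates for l in levels], dtype=float)
    k = np.array([l.n_positive for l in levels], dtype=float)

    if k.sum() == 0:
        # no positives anywhere: the MLE is zero; report the 95% upper bound
        upper = _PROFILE_DROP / float(np.sum(n * vd))
        return MpnEstimate(0.0, 0.0, ci_low=0.0, ci_high=upper, flag="all_negative")
    if np.all(k == n):
        # every well positive: likelihood increases without bound in c
        lower = _profile_bound_saturated(vd, n)
        return MpnEstimate(None, 0.0, ci_low=lower, ci_high=None, flag="all_positive")

    def score(log_c: float) -> float:
        c = math.exp(log_c)
        lam = c * vd
        with np.errstate(over="ignore"):
            pos = k * vd * np.exp(-lam) / (-np.expm1(-lam))
        return float(np.sum(pos) - np.sum((n - k) * vd))

    lo, hi = -30.0, 30.0
    # score is decreasing in c; positive at lo (positives dominate), negative at hi
    c_hat = math.exp(optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-14))
    ll_max = _log_likelihood(c_hat, vd, n, k)

    target = ll_max - _PROFILE_DROP

    def deficit(log_c: float) -> float:
        return _log_likelihood(math.exp(log_c), vd, n, k) - target

    log_hat = math.log(c_hat)
    ci_low = math.exp(optimize.brentq(deficit, -60.0, log_hat, xtol=1e-12))
    ci_high = math.exp(optimize.brentq(deficit, log_hat, 60.0, xtol=1e-12))
    return MpnEstimate(c_hat, ll_max, ci_low=ci_low, ci_high=ci_high, flag="ok")


def _profile_bound_saturated(vd: np.ndarray, n: np.ndarray) -> float:
    """95% lower bound when every replicate is positive (ll sup = 0)."""

    def deficit(log_c: float) -> float:
        lam = math.exp(log_c) * vd
        return float(np.sum(n * np.log(-np.expm1(-np.maximum(lam, 1e-300))))) + _PROFILE_DROP

    return math.exp(optimize.brentq(deficit, -60.0, 60.0, xtol=1e-12))
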