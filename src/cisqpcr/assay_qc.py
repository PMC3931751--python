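"""Analytical-validation metrics: specificity, linearity, imprecision, robustness.

These are the standard assay-qualification checks for a quantitative PCR
method: probe cross-reactivity expressed as a molecule fraction (2**-dCq),
log-log linearity of recovered versus expected copies across a dilution
series, replicate CV profiles by input range, and perturbation comparisons.
Default acceptance thresholds (r^2 > 0.99, slope 1 +/- 0.05, cross-reactivity
<= 10%) are the published criteria and are configurable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError
from .quantify import is_determined, summarize_replicates


@dataclass(frozen=True)
class SpecificityResult:
    """Cross-reactivity of a probe against the non-homologous template."""

    probe_id: str
    homologous_cq: float
    nonhomologous_cq: float | None
    cross_rate: float
    passed: bool


@dataclass(frozen=True)
class LinearityFit:
    """Log-log dilution-series regression with acceptance flags."""

    gene: str
    log_base: float
    slope: float
    intercept: float
    r_squared: float
    n_levels: int
    acceptance: bool


@dataclass(frozen=True)
class ImprecisionProfile:
    """Per-level CVs plus bracket averages over input-copy ranges."""

    gene: str
    level_cvs: tuple[tuple[float, float], ...]  # (expected copies, cv)
    bracket_cvs: tuple[tuple[tuple[float, float], float], ...]  # ((lo, hi), mean cv)


@dataclass(frozen=True)
class RobustnessResult:
    """Welch comparison of the same quantity under two assay conditions."""

    mean_difference: float
    p_value: float
    significant: bool


def cross_reactivity(
    homologous_cq: float,
    nonhomologous_cq: float | None,
    threshold: float = 0.10,
    probe_id: str = "",
) -> SpecificityResult:
    """Non-specific binding rate of a probe, as a fraction of homologous signal.

    rate = 2**-(nonhomologous Cq - homologous Cq); an undetermined
    non-homologous Cq means no detectable cross-binding (rate 0).  A probe
    passes when the rate is at or below ``threshold`` (inclusive boundary).
    """
    if not is_determined(homologous_cq):
        raise InvalidInputError("homologous Cq must be determined")
    if not is_determined(nonhomologous_cq):
        return SpecificityResult(probe_id, float(homologous_cq), None, 0.0, True)
    rate = 2.0 ** (-(float(nonhomologous_cq) - float(homologous_cq)))
    # inclusive boundary with a relative guard so dCq == log2(1/threshold) passes
    return SpecificityResult(
        probe_id, float(homologous_cq), float(nonhomologous_cq), rate,
        rate <= threshold * (1.0 + 1e-12),
    )


def linearity_fit(
    levels: Sequence[tuple[float, Sequence[float]]],
    *,
    gene: str = "",
    pooled: bool = False,
    log_base: float = 10.0,
    r2_threshold: float = 0.99,
    slope_tolerance: float = 0.05,
) -> LinearityFit:
    """OLS of log(observed copies) on log(expected copies) across dilution levels.

    ``levels`` is a sequence of (expected copies, observed replicate copies).
    By default the replicate mean enters the fit (series are plotted as
    triplicate means); ``pooled=True`` regresses every replicate individually.
    Levels whose observed mean is non-positive are dropped with a warning
    (their log is undefined).  Acceptance requires r^2 > ``r2_threshold`` and
    |slope - 1| <= ``slope_tolerance``.
    """
    xs, ys = [], []
    n_used = 0
    for expected, observed in levels:
        if expected <= 0:
            raise InvalidInputError("expected copies must be > 0 at every level")
        obs = np.asarray(list(observed), dtype=float)
        obs = obs[np.isfinite(obs)]
        if obs.size == 0 or np.mean(obs) <= 0:
            warnings.warn(
                f"linearity_fit: dropping level expected={expected:g} "
                "(non-positive or empty observed mean)",
                stacklevel=2,
            )
            continue
        n_used += 1
        if pooled:
            pos = obs[obs > 0]
            xs.extend([expected] * pos.size)
            ys.extend(pos)
        else:
            xs.append(expected)
            ys.append(float(np.mean(obs)))
    if n_used < 3:
        raise InvalidInputError("linearity_fit needs >= 3 usable levels")
    lx = np.log(np.asarray(xs)) / np.log(log_base)
    ly = np.log(np.asarray(ys)) / np.log(log_base)
    res = stats.linregress(lx, ly)
    slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return LinearityFit(
        gene=gene,
        log_base=log_base,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_levels=n_used,
        acceptance=(r2 > r2_threshold and abs(slope - 1.0) <= slope_tolerance),
    )


def imprecision_profile(
    levels: Sequence[tuple[float, Sequence[float]]],
    ranges: Sequence[tuple[float, float]],
    gene: str = "",
) -> ImprecisionProfile:
    """Replicate CV per dilution level, averaged over input-copy brackets.

    ``ranges`` are inclusive (lo, hi) brackets on the expected input copies;
    the bracket figure is the arithmetic mean of the level CVs inside it.
    Use ``math.inf`` as an open upper bound.
    """
    level_cvs = []
    for expected, observed in levels:
        obs = [v for v in observed if is_determined(v)]
        if len(obs) < 2:
            raise InvalidInputError(
                f"imprecision needs >= 2 replicates per level (expected={expected:g})"
            )
        s = summarize_replicates(obs)
        if s.cv is None:
            raise InvalidInputError(f"CV undefined at level expected={expected:g} (zero mean)")
        level_cvs.append((float(expected), s.cv))
    brackets = []
    for lo, hi in ranges:
        inside = [cv for exp, cv in level_cvs if lo <= exp <= hi]
        brackets.append(((float(lo), float(hi)), float(np.mean(inside)) if inside else float("nan")))
    return ImprecisionProfile(gene=gene, level_cvs=tuple(level_cvs), bracket_cvs=tuple(brackets))


def robustness_compare(
    condition_a: Sequence[float],
    condition_b: Sequence[float],
    alpha: float = 0.05,
) -> RobustnessResult:
    """Two-sided Welch t-test for a perturbation's effect on a measured quantity.

    Degenerate case: identical constant arms give p = 1 by convention (no
    evidence of a difference, not a numerical failure).
    """
    a = np.asarray(list(condition_a), dtype=float)
    b = np.asarray(list(condition_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("robustness_compare needs >= 2 replicates per arm")
    diff = float(np.mean(b) - np.mean(a))
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return RobustnessResult(mean_difference=diff, p_value=p, significant=p < alpha)
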