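"""Lung-cancer diagnostic index (LCDT) and ROC evaluation.

The LCDT combines three growth-regulation transcripts, each expressed as
molecules per 1e6 ACTB molecules:

    index = (MYC * E2F1) / CDKN1A

Higher values indicate malignancy (proliferative drive up, CDK inhibition
down).  Evaluation uses the empirical ROC: the AUC is the Mann-Whitney
probability that a malignant sample outranks a benign one (ties count 1/2),
with a Hanley-McNeil normal-approximation CI reported unclipped, and the
operating cutoff maximises the Youden index over midpoints of adjacent
sorted values.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: Default index expression; kept as a pandas-eval string over gene symbols so
#: the functional form is visible in config and overridable without code edits.
DEFAULT_INDEX_FORMULA = "MYC * E2F1 / CDKN1A"

LCDT_GENES = ("MYC", "E2F1", "CDKN1A")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: tuple[tuple[float, float], ...]  # (FPR, TPR) points


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class GroupComparison:
    levene_p: float
    t_p: float
    test_used: str  # "pooled" or "welch"
    mean_benign: float
    mean_malignant: float
    degenerate: bool = False


def lcdt_index(myc: float, e2f1: float, cdkn1a: float) -> float:
    """Diagnostic index from the three normalized expression values."""
    if cdkn1a <= 0:
        raise InvalidInputError("CDKN1A must be > 0; index undefined")
    if myc < 0 or e2f1 < 0:
        raise InvalidInputError("expression values must be >= 0")
    return myc * e2f1 / cdkn1a


def evaluate_index(expression: pd.DataFrame, formula: str = DEFAULT_INDEX_FORMULA) -> pd.Series:
    """Apply the configured index expression to a per-sample expression table.

    ``expression`` must carry one column per gene symbol used in ``formula``
    (values per 1e6 reference molecules).  Returns the index as a Series
    aligned with the input rows.
    """
    return expression.eval(formula)


def _check_classes(benign, malignant) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(list(benign), dtype=float)
    m = np.asarray(list(malignant), dtype=float)
    if b.size == 0 or m.size == 0:
        raise InvalidInputError("both classes need at least one value")
    return b, m


def auc_mann_whitney(benign: Sequence[float], malignant: Sequence[float]) -> float:
    """AUC as the tie-adjusted Mann-Whitney U statistic over n_b * n_m.

    Computed from midranks, which is algebraically identical to counting all
    (benign, malignant) pairs with ties weighted 1/2.
    """
    b, m = _check_classes(benign, malignant)
    ranks = stats.rankdata(np.concatenate([b, m]))
    r_m = ranks[b.size:].sum()
    u = r_m - m.size * (m.size + 1) / 2.0
    return float(u / (b.size * m.size))


def hanley_mcneil_ci(auc: float, n_neg: int, n_pos: int, z: float = 1.959964) -> tuple[float, float]:
    """Normal-approximation CI for an AUC (may exceed [0, 1]; reported unclipped)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_neg * n_pos)
    se = float(np.sqrt(max(var, 0.0)))
    return auc - z * se, auc + z * se


def roc_curve_points(benign: Sequence[float], malignant: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical ROC as (FPR, TPR) steps over descending thresholds."""
    b, m = _check_classes(benign, malignant)
    thresholds = np.unique(np.concatenate([b, m]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        fpr = float(np.mean(b >= t))
        tpr = float(np.mean(m >= t))
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def optimal_cutoff(benign: Sequence[float], malignant: Sequence[float]) -> CutoffResult:
    """Youden-optimal cutoff with the rule ``index > cutoff => malignant``.

    Candidates are midpoints between adjacent distinct pooled values plus
    sentinels beyond both extremes.  Ties in the Youden index resolve to the
    cutoff with the higher specificity (the conservative clinical choice).
    """
    b, m = _check_classes(benign, malignant)
    pooled = np.unique(np.concatenate([b, m]))
    candidates = [pooled[0] - 1.0]
    candidates += [0.5 * (x + y) for x, y in zip(pooled[:-1], pooled[1:])]
    candidates += [pooled[-1] + 1.0]
    best: CutoffResult | None = None
    for c in candidates:
        sens = float(np.mean(m > c))
        spec = float(np.mean(b <= c))
        j = sens + spec - 1.0
        if (
            best is None
            or j > best.youden_j + 1e-12
            or (abs(j - best.youden_j) <= 1e-12 and spec > best.specificity + 1e-12)
        ):
            best = CutoffResult(float(c), sens, spec, j)
    return best


def roc_auc(benign: Sequence[float], malignant: Sequence[float]) -> RocResult:
    """Full ROC evaluation: AUC with Hanley-McNeil CI, Youden cutoff, curve points."""
    b, m = _check_classes(benign, malignant)
    auc = auc_mann_whitney(b, m)
    lo, hi = hanley_mcneil_ci(auc, b.size, m.size)
    cut = optimal_cutoff(b, m)
    return RocResult(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        cutoff=cut.cutoff,
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
        curve=tuple(roc_curve_points(b, m)),
    )


def group_compare(
    benign: Sequence[float],
    malignant: Sequence[float],
    log_transform: bool = False,
) -> GroupComparison:
    """Two-sample comparison of index values between diagnostic classes.

    Levene's test (mean-centred) assesses variance equality; the t-test is
    pooled-variance when Levene p >= 0.05 and Welch otherwise, two-sided.
    The index spans orders of magnitude, so ``log_transform=True`` compares
    log10 values instead — both are offered because either convention is
    defensible for a ratio-scale index.
    """
    b, m = _check_classes(benign, malignant)
    if b.size < 2 or m.size < 2:
        raise InvalidInputError("group_compare needs >= 2 values per class")
    if log_transform:
        if np.any(b <= 0) or np.any(m <= 0):
            raise InvalidInputError("log transform requires strictly positive values")
        b, m = np.log10(b), np.log10(m)
    degenerate = np.std(b, ddof=1) == 0 and np.std(m, ddof=1) == 0
    if degenerate:
        t_p = 1.0 if np.mean(b) == np.mean(m) else 0.0
        return GroupComparison(
            levene_p=float("nan"), t_p=t_p, test_used="degenerate",
            mean_benign=float(np.mean(b)), mean_malignant=float(np.mean(m)),
            degenerate=True,
        )
    levene_p = float(stats.levene(b, m, center="mean").pvalue)
    equal_var = levene_p >= 0.05
    t_p = float(stats.ttest_ind(b, m, equal_var=equal_var).pvalue)
    return GroupComparison(
        levene_p=levene_p,
        t_p=t_p,
        test_used="pooled" if equal_var else "welch",
        mean_benign=float(np.mean(b)),
        mean_malignant=float(np.mean(m)),
    )
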