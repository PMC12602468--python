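"""Correlation of connectivity with clinical scores and group comparisons.

Continuous, normally-distributed scores (e.g. MDS-UPDRS part-III motor
sums, behavioural-inhibition or conscientiousness scales) use Pearson's r;
ordinal scales (Hoehn & Yahr stage) must use Spearman's rank correlation —
a score-type registry enforces the choice. Group differences in a
connection's TPDC values are tested by OLS regression on a 0/1 group
indicator, whose t-test is algebraically the two-sample equal-variance
t-test and whose r^2 is the squared point-biserial correlation.
Multiplicity over an explicit test family is controlled with Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Registry of known score types: 'continuous' -> Pearson, 'ordinal' -> Spearman.
SCORE_TYPES: dict[str, str] = {
    "hy_stage": "ordinal",
    "np3_total": "continuous",
    "bis": "continuous",
    "barratt": "continuous",
    "conscientiousness": "continuous",
}


def register_score(name: str, kind: str) -> None:
    """Declare a score as 'continuous' or 'ordinal' for method selection."""
    if kind not in ("continuous", "ordinal"):
        raise ValueError("kind must be 'continuous' or 'ordinal'")
    SCORE_TYPES[name] = kind


def _resolve_method(method: str, score_name: str | None) -> str:
    kind = SCORE_TYPES.get(score_name or "")
    if method == "auto":
        if kind is None:
            raise ValueError(
                f"score {score_name!r} not registered; pass method explicitly "
                "or register_score() it"
            )
        return "spearman" if kind == "ordinal" else "pearson"
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if method == "pearson" and kind == "ordinal":
        raise ValueError(
            f"score {score_name!r} is registered as ordinal; Pearson "
            "correlation is not valid, use spearman"
        )
    return method


@dataclass
class CorrelationResult:
    connection: tuple[str, str]  # (source, target)
    score_name: str
    method: str
    r: float
    p: float
    n: int
    p_adjusted: float | None = None


def correlate(
    values: np.ndarray,
    scores: np.ndarray,
    method: str = "auto",
    score_name: str | None = None,
    connection: tuple[str, str] = ("", ""),
) -> CorrelationResult:
    """Pearson or Spearman correlation of one connection's TPDC with a score.

    ``method='auto'`` resolves through the score-type registry; requesting
    Pearson for a registered ordinal score raises.
    """
    values = np.asarray(values, float)
    scores = np.asarray(scores, float)
    if values.shape != scores.shape or values.ndim != 1:
        raise ValueError("values and scores must be equal-length 1-D arrays")
    n = values.size
    if n < 5:
        raise ValueError(f"need n >= 5 paired observations, got {n}")
    if not (np.isfinite(values).all() and np.isfinite(scores).all()):
        raise ValueError("non-finite values in correlation input")
    if values.std() == 0 or scores.std() == 0:
        raise ValueError("zero variance in correlation input")
    method = _resolve_method(method, score_name)
    if method == "pearson":
        r, p = stats.pearsonr(values, scores)
    else:
        r, p = stats.spearmanr(values, scores)
    return CorrelationResult(
        connection=connection,
        score_name=score_name or "",
        method=method,
        r=float(r),
        p=float(p),
        n=n,
    )


@dataclass
class GroupComparison:
    connection: tuple[str, str]
    groups: tuple[str, str]
    slope: float
    p: float
    r_squared: float
    n_a: int
    n_b: int


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    connection: tuple[str, str] = ("", ""),
) -> GroupComparison:
    """OLS of a connection's values on a 0/1 group indicator.

    slope = mean(b) - mean(a); the regression t-test p equals the classic
    two-sample equal-variance t-test p; r^2 is the squared point-biserial
    correlation.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    if pooled.std() == 0:
        raise ValueError("zero pooled variance")
    indicator = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    fit = stats.linregress(indicator, pooled)
    return GroupComparison(
        connection=connection,
        groups=labels,
        slope=float(fit.slope),
        p=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        n_a=a.size,
        n_b=b.size,
    )


def friedman_across_groups(*groups: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test over k >= 3 matched groups of equal n.

    Subjects are matched by position (row-wise ranking across groups).
    """
    if len(groups) < 3:
        raise ValueError("Friedman test needs k >= 3 groups")
    arrays = [np.asarray(g, float) for g in groups]
    n = arrays[0].size
    for g in arrays[1:]:
        if g.size != n:
            raise ValueError(
                f"groups must have equal n (matched samples): {[a.size for a in arrays]}"
            )
    data = np.column_stack(arrays)
    if (data == data[:, :1]).all():
        # every row fully tied: no between-group rank variation at all
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*arrays)
    return float(stat), float(p)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * family size)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def adjust_family(results: list[CorrelationResult]) -> list[CorrelationResult]:
    """Apply Bonferroni over an explicit family of correlation results."""
    adj = bonferroni([r.p for r in results])
    for res, pa in zip(results, adj):
        res.p_adjusted = float(pa)
    return results
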