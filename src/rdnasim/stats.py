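"""Brunner-Munzel rank test and the shift-based equivalence procedure.

The Brunner-Munzel test compares two samples through the relative effect

    p = P(X < Y) + 0.5 * P(X = Y),

estimated from midranks and studentised with separate placement variances
and Welch-Satterthwaite degrees of freedom, which makes it robust to
unequal variances and ties.  ``alternative`` follows the usual two-sample
convention: ``"less"`` tests whether the distribution underlying ``x`` is
stochastically smaller than that of ``y`` (relative effect > 1/2).

Equivalence between two copy-number distributions is declared with a
shift procedure run from both directions: ``x`` is shifted by +margin and
by -margin copies and each shifted sample is compared to ``y`` with a
one-sided test oriented so that its p-value is large when the two
distributions differ by no more than the shift.  Both directional
p-values above the threshold (default 0.95) declare equivalence; this is
numerically the complement of the standard TOST "both one-sided p < 0.05"
readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
from scipy import special, stats as sps

__all__ = ["BMResult", "EquivalenceResult", "brunner_munzel",
           "equivalence_test", "compare_pools"]

#: Below this per-group size the asymptotic t reference is unreliable and
#: a permutation p-value is used instead (method="auto").
SMALL_SAMPLE_N = 10

#: Exact permutation enumeration is used up to this many label assignments.
MAX_EXACT_PERMUTATIONS = 20_000


@dataclass(frozen=True)
class BMResult:
    """Result of one Brunner-Munzel test.

    ``degenerate`` flags samples whose placement variances are both zero
    (e.g. completely separated samples, or two identical constant
    samples); the relative effect is then 0, 1/2 or 1 and the p-value is
    assigned directly rather than through the t reference.
    """

    p_hat: float
    statistic: float
    df: float
    p_value: float
    alternative: str
    degenerate: bool = False
    method: str = "asymptotic"

    def to_dict(self) -> dict:
        return {
            "p_hat": self.p_hat,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "degenerate": self.degenerate,
            "method": self.method,
        }


@dataclass(frozen=True)
class EquivalenceResult:
    """Two directional shift-test p-values and the equivalence verdict."""

    margin: float
    threshold: float
    p_lower: float
    p_upper: float
    equivalent: bool
    lower: BMResult
    upper: BMResult

    def to_dict(self) -> dict:
        return {
            "margin": self.margin,
            "threshold": self.threshold,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "equivalent": self.equivalent,
            "lower": self.lower.to_dict(),
            "upper": self.upper.to_dict(),
        }


_ALTERNATIVES = ("two-sided", "less", "greater")


def _relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    """p_hat from midranks: P(X<Y) + 0.5 P(X=Y)."""
    nx, ny = len(x), len(y)
    rank_c = sps.rankdata(np.concatenate((x, y)))
    return float((rank_c[nx:].mean() - (ny + 1) / 2) / nx)


def _degenerate_pvalue(p_hat: float, alternative: str) -> tuple[float, float]:
    """(statistic placeholder, p-value) for zero-variance samples."""
    if p_hat > 0.5:  # x completely below y
        stat = -math.inf
        p = {"less": 0.0, "greater": 1.0, "two-sided": 0.0}[alternative]
    elif p_hat < 0.5:
        stat = math.inf
        p = {"less": 1.0, "greater": 0.0, "two-sided": 0.0}[alternative]
    else:  # no ordering information at all
        stat = 0.0
        p = 1.0 if alternative == "two-sided" else 0.5
    return stat, p


def brunner_munzel(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
    n_resamples: int = 9_999,
    random_state: Optional[Union[int, np.random.Generator]] = None,
) -> BMResult:
    """Brunner-Munzel test of the relative effect P(X<Y) + 0.5 P(X=Y).

    Parameters
    ----------
    x, y
        Samples with at least two observations each.
    alternative
        ``"two-sided"``, ``"less"`` (x stochastically smaller than y) or
        ``"greater"``.
    method
        ``"asymptotic"`` (t reference with Satterthwaite df),
        ``"permutation"`` (relative effect as permutation statistic), or
        ``"auto"``: permutation when either group has fewer than
        ``SMALL_SAMPLE_N`` observations, asymptotic otherwise.
    n_resamples, random_state
        Monte-Carlo permutation settings; enumeration is exact when the
        number of group assignments is at most
        ``MAX_EXACT_PERMUTATIONS``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if method not in ("auto", "asymptotic", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    rank_c = sps.rankdata(np.concatenate((x, y)))
    rank_cx, rank_cy = rank_c[:nx], rank_c[nx:]
    rank_x, rank_y = sps.rankdata(x), sps.rankdata(y)
    mx, my = rank_cx.mean(), rank_cy.mean()
    p_hat = float((my - (ny + 1) / 2) / nx)

    sx2 = np.sum((rank_cx - rank_x - mx + (nx + 1) / 2) ** 2) / (nx - 1)
    sy2 = np.sum((rank_cy - rank_y - my + (ny + 1) / 2) ** 2) / (ny - 1)
    pooled = nx * sx2 + ny * sy2

    degenerate = pooled == 0.0
    if degenerate:
        statistic, p_value = _degenerate_pvalue(p_hat, alternative)
        return BMResult(p_hat, statistic, math.nan, p_value, alternative,
                        degenerate=True, method="degenerate")

    # Positive statistic <=> y ranks higher (x stochastically smaller).
    statistic = float(nx * ny * (my - mx) / ((nx + ny) * math.sqrt(pooled)))
    df = float(
        pooled ** 2
        / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    )

    use_permutation = method == "permutation" or (
        method == "auto" and min(nx, ny) < SMALL_SAMPLE_N
    )
    if not use_permutation:
        if alternative == "two-sided":
            p_value = float(2 * sps.t.sf(abs(statistic), df))
        elif alternative == "less":
            p_value = float(sps.t.sf(statistic, df))
        else:  # greater
            p_value = float(sps.t.cdf(statistic, df))
        p_value = min(p_value, 1.0)
        return BMResult(p_hat, statistic, df, p_value, alternative)

    p_value, perm_method = _permutation_pvalue(
        x, y, p_hat, alternative, n_resamples, random_state
    )
    return BMResult(p_hat, statistic, df, p_value, alternative,
                    method=perm_method)


def _permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    observed: float,
    alternative: str,
    n_resamples: int,
    random_state: Optional[Union[int, np.random.Generator]],
) -> tuple[float, str]:
    """Permutation p-value using the relative effect as test statistic.

    The relative effect is monotone in the evidence for stochastic
    ordering and is defined for every relabelling, including the
    zero-variance ones where the studentised statistic is not.
    """
    nx = len(x)
    pooled = np.concatenate((x, y))
    n = len(pooled)

    def extremity(vals: np.ndarray) -> np.ndarray:
        if alternative == "less":      # evidence: p_hat large
            return vals >= observed - 1e-12
        if alternative == "greater":
            return vals <= observed + 1e-12
        return np.abs(vals - 0.5) >= abs(observed - 0.5) - 1e-12

    n_exact = special.comb(n, nx, exact=True)
    if n_exact <= MAX_EXACT_PERMUTATIONS:
        idx = np.arange(n)
        vals = np.empty(n_exact)
        for k, keep in enumerate(combinations(range(n), nx)):
            mask = np.zeros(n, dtype=bool)
            mask[list(keep)] = True
            vals[k] = _relative_effect(pooled[mask], pooled[~mask])
        return float(extremity(vals).mean()), "permutation-exact"

    rng = (random_state if isinstance(random_state, np.random.Generator)
           else np.random.default_rng(random_state))
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        val = _relative_effect(perm[:nx], perm[nx:])
        hits += bool(extremity(np.asarray([val]))[0])
    return float((hits + 1) / (n_resamples + 1)), "permutation-mc"


def equivalence_test(
    x: Sequence[float],
    y: Sequence[float],
    margin: float = 1.0,
    threshold: float = 0.95,
    method: str = "auto",
    random_state: Optional[Union[int, np.random.Generator]] = None,
) -> EquivalenceResult:
    """Shift-based two-direction equivalence test on an additive scale.

    Tests whether the distributions of ``x`` and ``y`` differ by no more
    than ``margin`` copies.  ``x - margin`` vs ``y`` is tested with
    alternative "greater" (large p when ``y`` lies above the lowered
    sample) and ``x + margin`` vs ``y`` with alternative "less" (large p
    when ``y`` lies below the raised sample); equivalence is declared
    when both p-values exceed ``threshold``.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lower = brunner_munzel(x - margin, y, alternative="greater",
                           method=method, random_state=random_state)
    upper = brunner_munzel(x + margin, y, alternative="less",
                           method=method, random_state=random_state)
    equivalent = (lower.p_value > threshold) and (upper.p_value > threshold)
    return EquivalenceResult(
        margin=float(margin),
        threshold=float(threshold),
        p_lower=lower.p_value,
        p_upper=upper.p_value,
        equivalent=bool(equivalent),
        lower=lower,
        upper=upper,
    )


def compare_pools(
    pool_x,
    pool_y,
    margin: float = 1.0,
    threshold: float = 0.95,
    by: str = "sperm",
    method: str = "auto",
) -> EquivalenceResult:
    """Equivalence test between two sperm pools.

    ``by="sperm"`` compares the pooled per-sperm copy numbers (default);
    ``by="fly-mean"`` first averages within flies and compares the
    per-fly means (a conservative unit-of-analysis alternative).
    """
    if by == "sperm":
        x = pool_x["sperm_cn"].to_numpy(dtype=float)
        y = pool_y["sperm_cn"].to_numpy(dtype=float)
    elif by == "fly-mean":
        x = pool_x.groupby("fly_id")["sperm_cn"].mean().to_numpy()
        y = pool_y.groupby("fly_id")["sperm_cn"].mean().to_numpy()
    else:
        raise ValueError("by must be 'sperm' or 'fly-mean'")
    return equivalence_test(x, y, margin=margin, threshold=threshold,
                            method=method)
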