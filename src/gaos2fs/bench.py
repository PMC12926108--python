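"""Evaluation protocol: repeated cross-validated accuracy, Friedman test
across methods x datasets, and the exact Wilcoxon signed-rank pairwise test.

Accuracies are reported on the percent scale (mean +/- sd over
repeats x folds).  The Friedman statistic uses per-dataset ranks (rank 1 =
best accuracy, average ranks on ties):

    chi2_F = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

with k methods, n datasets and rank sums R_j, referred to a chi-square
distribution with k-1 degrees of freedom.  The Wilcoxon test is exact: the
null distribution of the positive-rank sum R+ is the distribution of
sum_i s_i r_i over all 2^n independent sign assignments s_i in {0, 1}, which
this module evaluates by convolution over the (tie-averaged) ranks —
algebraically identical to full enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitness import ClassifierSpec
from ._utils import seed_to_int

__all__ = [
    "cross_validated_accuracy",
    "friedman_test",
    "wilcoxon_signed_rank_exact",
    "WilcoxonResult",
]


def cross_validated_accuracy(X, y, spec: ClassifierSpec | None = None,
                             folds: int = 5, repeats: int = 10,
                             seed: int = 0) -> tuple[float, float]:
    """Mean and sd of accuracy (percent) over ``repeats`` stratified k-fold runs.

    Splits are re-randomised on every repeat; deterministic given ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold

    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer samples than folds={folds}"
        )
    accs = []
    for rep_ss in np.random.SeedSequence(seed).spawn(repeats):
        rep_seed = seed_to_int(rep_ss)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for tr, te in skf.split(X, y):
            clf = spec.build(rep_seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    accs = 100.0 * np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1))


def friedman_test(accuracy_table) -> tuple[float, float, np.ndarray]:
    """Friedman chi-square test on a methods x datasets accuracy matrix.

    Returns ``(statistic, p_value, rank_sums)``; ``rank_sums[j]`` is method
    j's rank sum over datasets (rank 1 = highest accuracy, ties averaged).
    """
    table = np.asarray(accuracy_table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a methods x datasets matrix with >= 2 of each")
    k, n = table.shape
    # rank within each dataset column: best accuracy -> rank 1
    ranks = np.column_stack(
        [stats.rankdata(-table[:, d]) for d in range(n)]
    )
    rank_sums = ranks.sum(axis=1)
    statistic = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), p, rank_sums


@dataclass
class WilcoxonResult:
    r_plus: float
    r_minus: float
    p_value: float
    n_used: int
    exact: bool


def _exact_tail_ge(ranks: np.ndarray, observed: float) -> float:
    """P(R+ >= observed) under the exact sign-flip null.

    Ranks are tie-averaged and hence multiples of 1/2; doubling makes them
    integers, and the distribution of 2*R+ is the coefficient vector of
    prod_i (1 + x^(2 r_i)) / 2^n, built by convolution.
    """
    scaled = np.round(2 * ranks).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    threshold = int(np.ceil(round(2 * observed, 9)))
    return float(dist[threshold:].sum())


def wilcoxon_signed_rank_exact(a, b, alternative: str = "greater") -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test on paired sequences a and b.

    Zero differences are discarded before ranking; |differences| receive
    average ranks on ties.  ``alternative='greater'`` tests whether a tends
    to exceed b (one-sided on R+); ``'two-sided'`` doubles the smaller tail.
    The p-value is exact (full sign-assignment null) for n <= 25 pairs and
    falls back to the tie-corrected normal approximation beyond.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length vectors")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    ranks = stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())

    exact = n <= 25
    if exact:
        p_ge = _exact_tail_ge(ranks, r_plus)
        if alternative == "greater":
            p = p_ge
        else:
            # exact lower tail: P(R+ <= r_plus) = 1 - P(R+ >= r_plus + 1/2)
            p_le = 1.0 - _exact_tail_ge(ranks, r_plus + 0.5)
            p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        mu = n * (n + 1) / 4.0
        tie_groups = np.unique(np.abs(d), return_counts=True)[1]
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_groups**3 - tie_groups
        ) / 48.0
        z = (r_plus - mu) / np.sqrt(sigma2)
        p = float(stats.norm.sf(z)) if alternative == "greater" else float(
            2 * stats.norm.sf(abs(z))
        )
    return WilcoxonResult(r_plus=r_plus, r_minus=r_minus, p_value=float(p),
                          n_used=n, exact=exact)
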