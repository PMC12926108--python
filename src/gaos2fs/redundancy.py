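"""Conditional-independence relevance analysis and redundancy pruning.

Relevance of a candidate feature to the class label is judged by testing
dependence conditioned on subsets of the already-selected features (up to a
bounded conditioning size d): dependent under every tested subset -> strongly
relevant; dependent under some but not all -> weakly relevant; independent
under all -> irrelevant.

Redundancy uses the Markov-blanket criterion: a selected feature F is
redundant if some subset zeta of the remaining selected features renders F
conditionally independent of the label, P(C | F, zeta) = P(C | zeta).

The workhorse test is Fisher's z transform of the partial correlation
(continuous vs continuous, with a binary label encoded numerically); labels
with three or more classes fall back to a G^2 likelihood-ratio contingency
test on quantile-discretised values, stratified over the conditioning set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError

__all__ = [
    "CITestResult",
    "conditional_independence_test",
    "classify_relevance",
    "redundancy_prune",
]

_VAR_EPS = 1e-12


@dataclass
class CITestResult:
    """Outcome of one conditional-independence test at level alpha."""

    statistic: float
    p_value: float
    independent: bool
    conditioning_size: int = 0


def _as_numeric(v: np.ndarray) -> np.ndarray:
    """Encode a possibly categorical vector numerically (class codes)."""
    v = np.asarray(v)
    if v.dtype.kind in "fiub":
        return v.astype(float)
    _, codes = np.unique(v, return_inverse=True)
    return codes.astype(float)


def _partial_corr(x: np.ndarray, y: np.ndarray, Z: np.ndarray | None) -> float:
    """Partial correlation of x and y given the columns of Z (residual method)."""
    x0, y0 = x - x.mean(), y - y.mean()
    if Z is None or Z.shape[1] == 0:
        rx, ry = x0, y0
    else:
        design = np.column_stack([np.ones(x.shape[0]), Z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    # degeneracy is judged relative to each variable's own scale so that an
    # exact duplicate (residual ~ 1e-13 of numerical noise) is caught
    sx0 = max(np.sqrt(x0 @ x0), _VAR_EPS)
    sy0 = max(np.sqrt(y0 @ y0), _VAR_EPS)
    if sx < _VAR_EPS or sy < _VAR_EPS or sx < 1e-7 * sx0 or sy < 1e-7 * sy0:
        raise DegenerateVarianceError(
            "zero residual variance: a tested variable is constant "
            "(or fully explained by the conditioning set)"
        )
    return float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))


def _fisher_z_test(x, y, Z, alpha: float) -> CITestResult:
    M = x.shape[0]
    q = 0 if Z is None else Z.shape[1]
    if M <= q + 3:
        raise ValueError(f"Fisher-z needs M > |conditioning| + 3; got M={M}, |Z|={q}")
    r = _partial_corr(x, y, Z)
    r = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = np.arctanh(r) * np.sqrt(M - q - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return CITestResult(statistic=float(z), p_value=float(p),
                        independent=bool(p > alpha), conditioning_size=q)


def _discretize(v: np.ndarray, bins: int = 3) -> np.ndarray:
    """Quantile-bin a vector; already-discrete vectors pass through as codes."""
    v = _as_numeric(v)
    uniq = np.unique(v)
    if uniq.size <= bins:
        return np.searchsorted(uniq, v)
    edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
    return np.digitize(v, np.unique(edges))


def _g2_test(x, y, Z, alpha: float, bins: int = 3) -> CITestResult:
    """G^2 likelihood-ratio test of x vs y, stratified over discretised Z."""
    xd = _discretize(x, bins)
    yd = _discretize(y, bins)
    if np.unique(xd).size < 2 or np.unique(yd).size < 2:
        raise DegenerateVarianceError("a tested variable is constant after discretisation")
    if Z is None or Z.shape[1] == 0:
        strata = np.zeros(x.shape[0], dtype=int)
    else:
        Zd = np.column_stack([_discretize(Z[:, j], bins) for j in range(Z.shape[1])])
        _, strata = np.unique(Zd, axis=0, return_inverse=True)
    g2, dof = 0.0, 0
    for s in np.unique(strata):
        sel = strata == s
        tab = np.zeros((np.max(xd) + 1, np.max(yd) + 1))
        np.add.at(tab, (xd[sel], yd[sel]), 1.0)
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        nz = tab > 0
        g2 += 2.0 * float(np.sum(tab[nz] * np.log(tab[nz] / expected[nz])))
        dof += (tab.shape[0] - 1) * (tab.shape[1] - 1)
    if dof == 0:
        # every stratum degenerate: no evidence against independence
        return CITestResult(statistic=0.0, p_value=1.0, independent=True,
                            conditioning_size=0 if Z is None else Z.shape[1])
    p = float(stats.chi2.sf(g2, dof))
    return CITestResult(statistic=float(g2), p_value=p, independent=bool(p > alpha),
                        conditioning_size=0 if Z is None else Z.shape[1])


def conditional_independence_test(x, y, conditioning=None, alpha: float = 0.05) -> CITestResult:
    """Test x independent-of y given the conditioning columns, at level alpha.

    Continuous pairs (and binary labels, numerically encoded) use Fisher's z
    transform of the partial correlation; a variable with >= 3 discrete
    levels and few unique values triggers the G^2 contingency fallback.
    """
    x = _as_numeric(x)
    y = _as_numeric(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if np.std(x) < _VAR_EPS or np.std(y) < _VAR_EPS:
        raise DegenerateVarianceError("constant input column in independence test")
    Z = None
    if conditioning is not None:
        cols = [_as_numeric(c) for c in conditioning]
        if cols:
            Z = np.column_stack(cols)
            if Z.shape[0] != x.shape[0]:
                raise ValueError("conditioning columns must match the sample count")
    # multiclass discrete variable -> contingency test
    for v in (x, y):
        uniq = np.unique(v)
        if 3 <= uniq.size <= 10 and np.allclose(v, np.round(v)):
            return _g2_test(x, y, Z, alpha)
    return _fisher_z_test(x, y, Z, alpha)


def _subsets(cols: list, d: int):
    """All subsets of ``cols`` (by index) up to size d, smallest first."""
    for size in range(0, min(d, len(cols)) + 1):
        yield from combinations(range(len(cols)), size)


def classify_relevance(candidate, labels, selected, alpha: float = 0.05,
                       max_cond: int = 3) -> str:
    """Classify a candidate feature as strong / weak / irrelevant w.r.t. labels.

    Dependence with the label is tested conditioned on every subset of the
    selected columns up to size ``max_cond`` (the empty set included):
    dependent under all -> "strong"; under some -> "weak"; under none ->
    "irrelevant".
    """
    candidate = _as_numeric(candidate)
    selected = [np.asarray(c, dtype=float) for c in selected]
    seen_dep = seen_indep = False
    for subset in _subsets(selected, max_cond):
        Z = [selected[j] for j in subset]
        if subset:
            try:
                res = conditional_independence_test(candidate, labels, Z, alpha)
            except DegenerateVarianceError:
                # residual variance vanished: the subset fully explains the
                # candidate, the limiting case of conditional independence
                seen_indep = True
                continue
        else:
            res = conditional_independence_test(candidate, labels, None, alpha)
        if res.independent:
            seen_indep = True
        else:
            seen_dep = True
        if seen_dep and seen_indep:
            break  # mixed verdicts already decide the class
    if seen_dep and seen_indep:
        return "weak"
    if seen_dep:
        return "strong"
    return "irrelevant"


def _label_association(col: np.ndarray, y: np.ndarray) -> float:
    """|Pearson correlation| with the numerically encoded label."""
    col = _as_numeric(col)
    y = _as_numeric(y)
    if np.std(col) < _VAR_EPS:
        return 0.0
    return abs(float(np.corrcoef(col, y)[0, 1]))


def redundancy_prune(selected, labels, alpha: float = 0.05, max_cond: int = 3) -> list[int]:
    """Markov-blanket redundancy pruning; returns surviving column indices.

    Features are visited weakest-association-first; feature F is removed if
    some subset zeta of the other remaining features (|zeta| <= max_cond)
    renders F conditionally independent of the label.  Idempotent on its own
    output.  A constant column is always prunable.
    """
    cols = [_as_numeric(c) for c in selected]
    y = _as_numeric(labels)
    if not cols:
        return []
    order = sorted(range(len(cols)), key=lambda j: _label_association(cols[j], y))
    remaining = set(range(len(cols)))
    for j in order:
        if np.std(cols[j]) < _VAR_EPS:
            remaining.discard(j)
            continue
        others = [k for k in sorted(remaining) if k != j]
        removed = False
        for subset in _subsets(others, max_cond):
            Z = [cols[others[i]] for i in subset]
            try:
                res = conditional_independence_test(cols[j], y, Z, alpha)
            except DegenerateVarianceError:
                # fully explained by the conditioning set -> redundant
                removed = True
                break
            if res.independent:
                removed = True
                break
        if removed:
            remaining.discard(j)
    return sorted(remaining)
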