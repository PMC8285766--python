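"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: plain normal-equations
least squares with t-tests, exhaustive pair counting for the AUC, and an
exhaustive threshold scan for the Youden index.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """OLS via the normal equations with classical t-test p-values.

    Returns (beta, se, pvalues); X must include its intercept column.
    """
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def auc_pair_count(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive pair enumeration: P(pos < neg) + half ties,
    for the 'lower score is more positive' orientation."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = np.sum(pos[:, None] < neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_brute_force(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max of sens + spec - 1 over every threshold (midpoints + sentinels),
    classifying positive when score < threshold."""
    u = np.unique(scores)
    thresholds = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, u, [u[-1] + 1.0]])
    pos = scores[labels]
    neg = scores[~labels]
    best = -np.inf
    for c in thresholds:
        sens = np.mean(pos < c)
        spec = np.mean(neg >= c)
        best = max(best, sens + spec - 1.0)
    return float(best)
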