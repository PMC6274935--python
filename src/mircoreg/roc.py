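"""ROC curves and AUC for single-marker case/control discrimination.

The AUC is the probability that a randomly chosen case scores above a
randomly chosen control (ties counted half), i.e. the Mann-Whitney U
statistic divided by n_case * n_control. Its standard error uses the
Hanley-McNeil formula and the p-value tests H0: AUC = 0.5 with a normal
z statistic; an exact permutation p is available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ROCResult", "roc_auc"]


@dataclass
class ROCResult:
    mirna_id: str | None
    auc: float
    se_auc: float
    p_value: float
    curve: pd.DataFrame  # columns fpr, tpr, threshold
    n_case: int
    n_control: int


def _auc_mann_whitney(case: np.ndarray, control: np.ndarray) -> float:
    # tie-aware U via midranks
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return u / (case.size * control.size)


def _hanley_mcneil_se(auc: float, n1: int, n2: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(
    scores,
    labels,
    mirna_id: str | None = None,
    method: str = "hanley",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> ROCResult:
    """ROC curve and AUC of ``scores`` for discriminating cases from controls.

    Parameters
    ----------
    scores : array-like
        Per-sample marker values (e.g. relative quantities).
    labels : array-like of bool
        True for case samples, False for controls.
    method : {"hanley", "permutation"}
        How the p-value against AUC = 0.5 is computed: Hanley-McNeil normal
        approximation (default) or label permutation (exact Monte Carlo).

    The curve is evaluated at every observed threshold, starts at (0, 0), ends
    at (1, 1) and its trapezoidal area equals the U-statistic AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("Both case and control samples are required")

    case = scores[labels]
    control = scores[~labels]
    auc = _auc_mann_whitney(case, control)

    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    if np.unique(scores).size == 1:
        return ROCResult(mirna_id, 0.5, float("nan"), 1.0, curve, n1, n2)

    se = _hanley_mcneil_se(auc, n1, n2)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(scores)
            a = _auc_mann_whitney(perm[:n1], perm[n1:])
            if abs(a - 0.5) >= abs(auc - 0.5) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    elif method == "hanley":
        if se == 0.0:
            p = 1.0 if auc == 0.5 else 0.0
        else:
            z = (auc - 0.5) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"Unknown method {method!r}")
    return ROCResult(mirna_id, float(auc), se, float(p), curve, n1, n2)
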