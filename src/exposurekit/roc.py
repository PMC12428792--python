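"""ROC evaluation of an ordinal severity score against binary disease endpoints.

The AUC is the Mann-Whitney concordance probability (ties counted one half),
computed from midranks in O(n log n).  Confidence intervals come from a
percentile bootstrap of paired (score, label) records; a DeLong variance
interval is available as an alternative.  Internal validation follows the
bootstrap optimism-correction recipe: for each resample the optimism is the
resample AUC minus the original-data AUC, and the corrected AUC is the
apparent AUC minus the mean optimism.  For a prespecified score with no
refitting the correction is close to zero by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cohort import Cohort

__all__ = [
    "ENDPOINTS",
    "RocResult",
    "endpoint_labels",
    "auc_mann_whitney",
    "roc_curve",
    "bootstrap_auc_ci",
    "delong_auc_ci",
    "optimism_corrected_auc",
    "evaluate_score",
]

logger = logging.getLogger(__name__)

#: Named binary endpoints: positive TNM-stage sets.
ENDPOINTS: dict[str, frozenset[str]] = {
    "stageIV_vs_rest": frozenset({"IV"}),
    "stageIII_IV_vs_I_II": frozenset({"III", "IV"}),
}


@dataclass(frozen=True)
class RocResult:
    """Apparent AUC, bootstrap CI, optimism-corrected AUC and the ROC curve."""

    endpoint: str
    auc: float
    ci_low: float
    ci_high: float
    corrected_auc: float
    optimism: float
    replicates: int
    seed: int
    curve: tuple[tuple[float, float], ...]
    n_positive: int
    n_negative: int


def endpoint_labels(cohort: Cohort, endpoint: str) -> np.ndarray:
    """0/1 labels for a named stage endpoint; 1 iff the stage is in the positive set."""
    try:
        positive = ENDPOINTS[endpoint]
    except KeyError:
        raise ValueError(
            f"unknown endpoint {endpoint!r}; choose from {sorted(ENDPOINTS)}"
        ) from None
    return np.array([1 if r.tnm_stage in positive else 0 for r in cohort], dtype=int)


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return s, y


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the probability a positive outranks a negative (ties count 1/2)."""
    s, y = _validate(scores, labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_curve(scores, labels) -> tuple[tuple[float, float], ...]:
    """ROC points (fpr, tpr), one per distinct threshold, thresholds descending.

    Starts at (0, 0), ends at (1, 1); the trapezoidal area under the returned
    polyline equals the Mann-Whitney AUC.
    """
    s, y = _validate(scores, labels)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n1, n0 = int(y.sum()), int((1 - y).sum())
    # index of the last observation at each distinct threshold
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[cut]
    fps = np.cumsum(1 - y)[cut]
    fpr = np.r_[0.0, fps / n0]
    tpr = np.r_[0.0, tps / n1]
    return tuple((float(f), float(t)) for f, t in zip(fpr, tpr))


def _curve_area(curve) -> float:
    pts = np.asarray(curve, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def bootstrap_auc_ci(
    scores, labels, B: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over paired resamples of records.

    Resamples containing a single class are redrawn (and logged).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    s, y = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    n = s.size
    aucs = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redraws += 1
        aucs[b] = auc_mann_whitney(s[idx], yb)
    if redraws:
        logger.info("bootstrap_auc_ci: redrew %d single-class resamples", redraws)
    alpha = 1 - level
    low, high = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def delong_auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based CI for the AUC (alternative to the bootstrap)."""
    s, y = _validate(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = pos.size, neg.size
    # placement values via midranks
    all_ranks = sps.rankdata(np.r_[pos, neg])
    v10 = (all_ranks[:n1] - sps.rankdata(pos)) / n0
    v01 = 1.0 - (all_ranks[n1:] - sps.rankdata(neg)) / n1
    auc = float(v10.mean())
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def optimism_corrected_auc(
    scores, labels, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap optimism correction of the apparent AUC.

    Returns ``(corrected_auc, optimism)`` where ``optimism`` is the mean over
    resamples of (resample AUC - original-data AUC) and
    ``corrected = apparent - optimism``.  The score is prespecified (no
    refitting inside the loop), so the correction is expected to be small.
    """
    s, y = _validate(scores, labels)
    apparent = auc_mann_whitney(s, y)
    rng = np.random.default_rng(seed)
    n = s.size
    optimisms = np.empty(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        optimisms[b] = auc_mann_whitney(s[idx], y[idx]) - apparent
    optimism = float(optimisms.mean())
    return float(apparent - optimism), optimism


def evaluate_score(
    scores,
    labels,
    endpoint: str = "custom",
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    ci_method: str = "bootstrap",
) -> RocResult:
    """Full ROC evaluation: AUC, CI, optimism-corrected AUC and the curve."""
    s, y = _validate(scores, labels)
    auc = auc_mann_whitney(s, y)
    if ci_method == "bootstrap":
        low, high = bootstrap_auc_ci(s, y, B=B, seed=seed, level=level)
    elif ci_method == "delong":
        low, high = delong_auc_ci(s, y, level=level)
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'delong'")
    corrected, optimism = optimism_corrected_auc(s, y, B=B, seed=seed)
    return RocResult(
        endpoint=endpoint,
        auc=auc,
        ci_low=low,
        ci_high=high,
        corrected_auc=corrected,
        optimism=optimism,
        replicates=B,
        seed=seed,
        curve=roc_curve(s, y),
        n_positive=int(y.sum()),
        n_negative=int((1 - y).sum()),
    )
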