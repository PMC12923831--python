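"""Clinical association statistics.

The scalar brain summary (mean relevance over the brain mask) is related to
symptom scores — PANSS factor scores, SANS factors, GAF, BDI-II, VisDys —
at baseline (T0) and as nine-month change scores (T1 − T0).  Associations
use Spearman rank correlation with the t-transform p-value,

    t = rho · sqrt((n − 2) / (1 − rho²)),   p two-sided from t(n − 2),

and each table's family of variables is corrected with the Bonferroni-Holm
step-down procedure, which controls the family-wise error rate without the
full conservativeness of plain Bonferroni.  Associations are typically
restricted to correctly classified subjects: the heatmap of a misclassified
subject explains a wrong decision and carries no interpretable severity
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .relevance import RelevanceHeatmap, mean_relevance

__all__ = [
    "AssociationResult",
    "change_scores",
    "spearman_rho",
    "holm_bonferroni",
    "associate_relevance",
]

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """One variable's association with mean brain relevance."""

    variable: str
    n: int
    rho: float
    t: float
    p_raw: float
    p_corrected: float
    significant: bool


def change_scores(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Per-subject T1 − T0 change scores.

    Subjects lacking a T1 row are omitted.  A variable with no usable pair
    of observations at both timepoints raises an error.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables missing from clinical table: {missing}")
    t0 = table[table["timepoint"] == "T0"].set_index("subject_id")
    t1 = table[table["timepoint"] == "T1"].set_index("subject_id")
    both = t0.index.intersection(t1.index)
    out = pd.DataFrame({"subject_id": both}).set_index("subject_id")
    for var in variables:
        change = t1.loc[both, var].astype(float) - t0.loc[both, var].astype(float)
        if change.notna().sum() == 0:
            raise ValueError(
                f"variable {var!r} has no subject observed at both timepoints"
            )
        out[var] = change
    return out.reset_index()


def spearman_rho(x, y) -> tuple[float, float, float]:
    """Spearman correlation with t-statistic and two-sided p-value.

    rho is the Pearson correlation of average ranks (ties get mean ranks);
    the p-value comes from the t(n − 2) approximation.  |rho| = 1 maps to
    p = 0 by convention.  Constant input vectors are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        rho = float(np.sign(rho))
        return rho, float(np.sign(rho) * np.inf), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(t), float(p)


def holm_bonferroni(p_values, alpha=0.05):
    """Bonferroni-Holm step-down adjustment.

    Sorted ascending, the i-th adjusted p is the running maximum of
    min(1, (m − i + 1)·p_(i)); a hypothesis is rejected while its adjusted p
    is below alpha.  Returns (adjusted p-values, reject flags) in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    reject = adjusted < alpha
    return adjusted, reject


def associate_relevance(
    heatmaps,
    mask,
    clinical: pd.DataFrame,
    variables,
    timepoint_mode="t0",
    subset=None,
    alpha=0.05,
) -> list[AssociationResult]:
    """Mean brain relevance versus clinical scores, Holm-corrected.

    For every subject in ``subset`` (default: all subjects with a heatmap)
    the mean relevance over ``mask`` is correlated with the T0 score
    (``timepoint_mode="t0"``) or the T1 − T0 change score
    (``timepoint_mode="change"``) of each variable; p-values are corrected
    across the call's variable family.  Subjects lacking a heatmap or a
    score are excluded (the count is logged).  Results sorted by corrected p.
    """
    if timepoint_mode not in ("t0", "change"):
        raise ValueError("timepoint_mode must be 't0' or 'change'")
    variables = list(variables)
    if not variables:
        return []
    subset = list(subset) if subset is not None else list(heatmaps)
    if not subset:
        raise ValueError("subset is empty")
    if timepoint_mode == "t0":
        scores = (clinical[clinical["timepoint"] == "T0"]
                  .set_index("subject_id"))
    else:
        scores = change_scores(clinical, variables).set_index("subject_id")
    usable = [s for s in subset if s in heatmaps and s in scores.index]
    dropped = len(subset) - len(usable)
    if dropped:
        logger.info("excluded %d subjects lacking heatmap or scores", dropped)
    rel = {s: _mean_rel(heatmaps[s], mask) for s in usable}
    raw = []
    for var in variables:
        if var not in scores.columns:
            raise ValueError(f"variable {var!r} missing from clinical table")
        pairs = [(rel[s], float(scores.loc[s, var])) for s in usable
                 if np.isfinite(scores.loc[s, var])]
        xv = np.array([a for a, _ in pairs])
        yv = np.array([b for _, b in pairs])
        rho, t, p = spearman_rho(xv, yv)
        raw.append((var, len(pairs), rho, t, p))
    adjusted, reject = holm_bonferroni([r[4] for r in raw], alpha=alpha)
    results = [
        AssociationResult(variable=var, n=n, rho=rho, t=t, p_raw=p,
                          p_corrected=float(adj), significant=bool(rej))
        for (var, n, rho, t, p), adj, rej in zip(raw, adjusted, reject)
    ]
    return sorted(results, key=lambda r: r.p_corrected)


def _mean_rel(hm, mask):
    if isinstance(hm, RelevanceHeatmap):
        return mean_relevance(hm, mask)
    arr = np.asarray(hm, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    return float(arr[mask].mean())
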