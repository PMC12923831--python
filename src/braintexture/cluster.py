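"""Affinity-propagation clustering of relevance heatmaps.

Cohorts can be too heterogeneous for one whole-group brain–symptom
association; clustering the per-subject relevance heatmaps finds subgroups
that share a brain texture pattern.  Affinity propagation is used because
the number of clusters emerges from the data (via the preference parameter)
instead of being fixed in advance: subjects exchange responsibility and
availability messages until a set of exemplars stabilizes, and every subject
is assigned to its best exemplar.

Heatmaps are z-scored within the brain mask before computing similarities
(negative squared Euclidean distance), removing per-subject output-scale
differences that score conservation ties to the logit magnitude.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .relevance import RelevanceHeatmap

__all__ = ["ClusterSolution", "affinity_propagation", "cluster_profiles"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterSolution:
    """An exemplar-based partition of subjects."""

    exemplars: list
    assignment: dict
    n_clusters: int
    converged: bool

    def members(self, exemplar) -> list:
        return [s for s, e in self.assignment.items() if e == exemplar]

    def cluster_index(self) -> dict:
        """subject → 0-based cluster number (by exemplar order)."""
        order = {e: i for i, e in enumerate(self.exemplars)}
        return {s: order[e] for s, e in self.assignment.items()}


def _heatmap_matrix(heatmaps, mask):
    subjects = list(heatmaps)
    rows = []
    for sid in subjects:
        hm = heatmaps[sid]
        rel = hm.relevance if isinstance(hm, RelevanceHeatmap) else np.asarray(hm)
        v = rel[mask] if mask is not None else rel.ravel()
        sd = v.std()
        rows.append((v - v.mean()) / (sd if sd > 0 else 1.0))
    return subjects, np.stack(rows)


def affinity_propagation(
    heatmaps,
    mask=None,
    preference="median",
    damping=0.9,
    max_iter=500,
    convergence_iter=15,
    seed=0,
) -> ClusterSolution:
    """Cluster subjects by the similarity of their relevance heatmaps.

    ``heatmaps`` maps subject id → heatmap (or bare array); ``mask``
    restricts the comparison to brain voxels.  Similarity is the negative
    squared Euclidean distance between within-mask z-scored heatmaps;
    ``preference="median"`` uses the median similarity (the conventional
    choice giving a moderate number of clusters).  Message passing runs with
    the given damping until assignments are stable for ``convergence_iter``
    iterations or ``max_iter`` is reached; on non-convergence the solution
    is still returned, flagged ``converged=False``.
    """
    if len(heatmaps) < 2:
        raise ValueError("need at least 2 subjects")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    subjects, x = _heatmap_matrix(heatmaps, mask)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    sim = -d2
    # Degenerate geometry: all heatmaps coincide -> a single cluster.
    if np.allclose(d2, 0.0):
        return ClusterSolution(
            exemplars=[subjects[0]],
            assignment={s: subjects[0] for s in subjects},
            n_clusters=1,
            converged=True,
        )
    pref = float(np.median(sim)) if preference == "median" else float(preference)
    ap = AffinityPropagation(
        affinity="precomputed",
        preference=pref,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap.fit(sim)
        except ConvergenceWarning:
            converged = False
            logger.warning("affinity propagation did not converge")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ap = AffinityPropagation(
                    affinity="precomputed", preference=pref, damping=damping,
                    max_iter=max_iter, convergence_iter=convergence_iter,
                    random_state=seed,
                ).fit(sim)
    centers = ap.cluster_centers_indices_
    if centers is None or len(centers) == 0:
        # Non-convergence without exemplars: fall back to one cluster.
        return ClusterSolution(
            exemplars=[subjects[0]],
            assignment={s: subjects[0] for s in subjects},
            n_clusters=1,
            converged=False,
        )
    exemplars = [subjects[i] for i in centers]
    assignment = {
        s: exemplars[lab] for s, lab in zip(subjects, ap.labels_)
    }
    for e in exemplars:  # exemplar self-assignment is part of the contract
        assignment[e] = e
    return ClusterSolution(
        exemplars=exemplars,
        assignment=assignment,
        n_clusters=len(exemplars),
        converged=converged,
    )


def cluster_profiles(solution: ClusterSolution, clinical: pd.DataFrame,
                     variables) -> pd.DataFrame:
    """Per-cluster clinical profiles: baseline means and mean change scores.

    Returns a tidy frame (cluster, exemplar, variable, mean_t0, mean_change,
    n_t0, n_change); change scores are T1 − T0 over the cluster's subjects
    that have a follow-up row.  Every clustered subject must have a T0 row,
    and every requested variable must exist in the table.
    """
    missing = [v for v in variables if v not in clinical.columns]
    if missing:
        raise ValueError(f"variables missing from clinical table: {missing}")
    t0 = clinical[clinical["timepoint"] == "T0"].set_index("subject_id")
    t1 = clinical[clinical["timepoint"] == "T1"].set_index("subject_id")
    absent = [s for s in solution.assignment if s not in t0.index]
    if absent:
        raise ValueError(f"subjects missing baseline rows: {absent}")
    rows = []
    for ci, exemplar in enumerate(solution.exemplars):
        members = solution.members(exemplar)
        with_t1 = [s for s in members if s in t1.index]
        for var in variables:
            base = t0.loc[members, var].astype(float)
            change = (t1.loc[with_t1, var].astype(float)
                      - t0.loc[with_t1, var].astype(float))
            rows.append({
                "cluster": ci,
                "exemplar": exemplar,
                "variable": var,
                "mean_t0": float(base.mean()),
                "mean_change": float(change.mean()) if len(change) else np.nan,
                "n_t0": int(base.notna().sum()),
                "n_change": int(change.notna().sum()),
            })
    return pd.DataFrame(rows)
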