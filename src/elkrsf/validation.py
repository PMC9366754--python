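"""Fivefold by-individual cross-validation of RSF predictions.

Following the Boyce approach: individuals are randomly partitioned into k
folds; the model is refit with each fold withheld; withheld predictions
are binned into ordinal habitat ranks using percentile cutoffs of the
withheld AVAILABLE predictions; and the frequency of withheld USED
locations per bin is compared to the bin ranks 1..k_bins with a Spearman
rank correlation.  A well-calibrated selection model concentrates used
locations in the high-rank bins (r_s near 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import RSFModelSpec, design_matrix, fit_hierarchical_rsf

__all__ = [
    "FoldAssignment",
    "assign_folds",
    "spearman_rank",
    "bin_ranks",
    "boyce_statistic",
    "boyce_cross_validate",
]


@dataclass
class FoldAssignment:
    folds: dict[str, int]  # individual id -> fold in 1..k
    k: int
    seed: int | None = None

    def withheld(self, fold: int) -> list[str]:
        return [i for i, f in self.folds.items() if f == fold]

    def retained(self, fold: int) -> list[str]:
        return [i for i, f in self.folds.items() if f != fold]


def assign_folds(ids, k: int = 5, seed: int | None = None) -> FoldAssignment:
    """Balanced random partition of individuals into k folds (sizes differ <= 1)."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} individuals for {k} folds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = pos % k + 1
    return FoldAssignment(folds=assignment, k=k, seed=seed)


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    Ties get midranks.  For n <= 8 the p value is exact, by enumerating
    all permutations of one ranking; for larger n the large-sample
    t approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rs = _corr(rx, ry)
    if n <= 8:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_corr(rx, np.asarray(perm))) >= abs(rs) - 1e-12:
                count += 1
        p = count / total
    else:
        t = rs * math.sqrt((n - 2) / max(1 - rs**2, 1e-300))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rs, float(min(p, 1.0))


def bin_ranks(pred_used, pred_avail, n_bins: int = 5):
    """Bin withheld used predictions by available-percentile cutoffs.

    Cutoffs are the (100/k, 200/k, ...) percentiles of the withheld
    available predictions; bins are ranked 1 (lowest suitability) to
    ``n_bins``.  Returns (counts per bin, cutoffs).
    """
    pred_used = np.asarray(pred_used, float)
    pred_avail = np.asarray(pred_avail, float)
    qs = np.arange(1, n_bins) / n_bins
    cutoffs = np.quantile(pred_avail, qs)
    ranks = np.searchsorted(cutoffs, pred_used, side="right") + 1
    counts = np.bincount(ranks, minlength=n_bins + 1)[1 : n_bins + 1]
    return counts, cutoffs


def boyce_statistic(pred_used, pred_avail, n_bins: int = 5,
                    area_adjusted: bool = False):
    """Spearman correlation between used-location frequency and habitat rank.

    ``area_adjusted=True`` divides each bin's used count by the share of
    available points in the bin (the classical Boyce ratio) before
    correlating; the default uses raw counts.
    """
    counts, cutoffs = bin_ranks(pred_used, pred_avail, n_bins)
    if np.ptp(np.asarray(pred_avail, float)) == 0:
        warnings.warn("degenerate predictions: all available values equal")
    freq = counts.astype(float)
    if area_adjusted:
        a_counts, _ = bin_ranks(pred_avail, pred_avail, n_bins)
        share = np.maximum(a_counts / max(len(pred_avail), 1), 1e-12)
        freq = freq / share
    if np.ptp(freq) == 0:
        # completely uninformative predictions: no correlation measurable
        return 0.0, 1.0, counts, cutoffs
    rs, p = spearman_rank(freq, np.arange(1, n_bins + 1))
    return rs, p, counts, cutoffs


def boyce_cross_validate(
    table: pd.DataFrame,
    spec: RSFModelSpec | None = None,
    folds: FoldAssignment | None = None,
    n_bins: int = 5,
    k: int = 5,
    seed: int | None = None,
    method: str = "map",
    area_adjusted: bool = False,
) -> dict:
    """k-fold by-individual cross-validation of the population RSF.

    Each fold's model is refit on the retained individuals (``method``
    defaults to the fast MAP mode); withheld rows are scored with the
    population coefficients; used counts per habitat-rank bin are tested
    against the ranks with Spearman correlation.
    """
    spec = spec or RSFModelSpec()
    ids = table["individual_id"].astype(str).unique()
    if folds is None:
        folds = assign_folds(ids, k=k, seed=seed)
    report = {"folds": [], "n_bins": n_bins, "k": folds.k, "seed": folds.seed}
    rss = []
    idcol = table["individual_id"].astype(str)
    for f in range(1, folds.k + 1):
        withheld_ids = set(folds.withheld(f))
        test = table[idcol.isin(withheld_ids)]
        train = table[~idcol.isin(withheld_ids)]
        if test["used"].sum() == 0 or (1 - test["used"]).sum() == 0:
            raise ValueError(f"fold {f} withheld data lacks used or available rows")
        post = fit_hierarchical_rsf(train, spec, method=method, draws=0, seed=folds.seed)
        X = design_matrix(test, spec.terms)
        pred = X @ post.beta_map
        rs, p, counts, cutoffs = boyce_statistic(
            pred[test["used"] == 1], pred[test["used"] == 0],
            n_bins=n_bins, area_adjusted=area_adjusted,
        )
        rss.append(rs)
        report["folds"].append(
            {
                "fold": f,
                "r_s": rs,
                "p": p,
                "bin_counts": counts.tolist(),
                "cutoffs": np.asarray(cutoffs).tolist(),
                "n_withheld_used": int(test["used"].sum()),
            }
        )
    report["mean_r_s"] = float(np.mean(rss))
    return report
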