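"""Binned k-fold cross-validation of RSF predictive capability.

Used points are repeatedly split into k folds; for each fold the model is
refitted without the held-out dens, all available points are scored and cut
into equal-count bins, and the observed proportion of held-out dens per bin
is rank-correlated (Spearman) against the expected proportion derived from
bin-mean RSF scores.  A well-calibrated selection model concentrates
held-out dens in the high-score bins, driving the correlation toward 1;
a model no better than chance hovers around 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rsf_model import ModelSpec, design_matrix
from . import rsf_model


@dataclass
class ValidationResult:
    """Cross-validation summary over random re-partitions."""

    per_iteration_rho: np.ndarray
    k_folds: int
    n_bins: int

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.per_iteration_rho))

    @property
    def sd_rho(self) -> float:
        return float(np.std(self.per_iteration_rho, ddof=1))

    @property
    def range(self) -> tuple[float, float]:
        return (float(np.min(self.per_iteration_rho)),
                float(np.max(self.per_iteration_rho)))

    @property
    def n_iterations(self) -> int:
        return len(self.per_iteration_rho)


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties get average ranks.  Raises when either vector has zero rank
    variance (correlation undefined) or fewer than three values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("zero rank variance: Spearman undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _score(design: pd.DataFrame, fit, shift: float = 0.0) -> np.ndarray:
    """RSF scores w = exp(sum beta x - shift), intercept omitted.

    The shift rescales all scores by a common positive factor, which leaves
    both the rank-based statistic and the bin-mean proportions unchanged
    but keeps extreme fitted coefficients from overflowing the exponential.
    """
    X = design_matrix(design, fit.spec.terms)[:, 1:]
    return np.exp(X @ fit.beta.to_numpy() - shift)


def _linear_predictor_max(design: pd.DataFrame, fit) -> float:
    X = design_matrix(design, fit.spec.terms)[:, 1:]
    return float(np.max(X @ fit.beta.to_numpy()))


def _bin_edges(sorted_scores: np.ndarray, n_bins: int) -> np.ndarray:
    """Upper limits of bins 0..n_bins-2 for equal-count binning."""
    m = sorted_scores.size
    idx = [int(np.ceil(m * (i + 1) / n_bins)) - 1 for i in range(n_bins - 1)]
    return sorted_scores[idx]


def _assign_bins(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # a score equal to an upper limit belongs to the lower bin
    return np.searchsorted(edges, scores, side="left")


def expected_observed(avail_scores: np.ndarray, held_scores: np.ndarray,
                      n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Expected and observed bin proportions for one fold.

    Available scores are cut into ``n_bins`` equal-count bins; the expected
    proportion per bin is the bin mean score over the sum of bin means, and
    the observed proportion is the share of held-out scores falling in each
    bin using the same breakpoints (ties assign to the lower bin).  Both
    vectors sum to one.
    """
    avail_scores = np.asarray(avail_scores, dtype=float)
    held_scores = np.asarray(held_scores, dtype=float)
    if np.ptp(avail_scores) == 0:
        raise ValueError("constant RSF scores: bins undefined")
    edges = _bin_edges(np.sort(avail_scores), n_bins)
    avail_bins = _assign_bins(avail_scores, edges)
    bin_means = np.array([
        avail_scores[avail_bins == b].mean() if np.any(avail_bins == b)
        else 0.0 for b in range(n_bins)])
    expected = bin_means / bin_means.sum()
    held_bins = _assign_bins(held_scores, edges)
    observed = np.bincount(held_bins, minlength=n_bins) / held_bins.size
    return expected, observed


def kfold_validate(design: pd.DataFrame, spec: ModelSpec, k: int = 5,
                   n_bins: int = 10, iterations: int = 100, seed: int = 0,
                   pool_folds: bool = False) -> ValidationResult:
    """Binned k-fold cross-validation with Spearman rank correlation.

    Per iteration the used points are shuffled into ``k`` folds.  For each
    fold the model is fitted on the remaining used points plus *all*
    available points; the available points are scored and split into
    ``n_bins`` equal-count bins; the expected proportion per bin is the bin
    mean score over the sum of bin means, and the observed proportion is the
    share of held-out dens falling in the bin (same breakpoints).  The
    iteration statistic is the mean Spearman rho over folds, or a single
    rho on fold-pooled proportions when ``pool_folds`` is set.
    """
    used_idx = np.flatnonzero((design["label"] == "used").to_numpy())
    avail = design[design["label"] == "available"]
    if used_idx.size < k:
        raise ValueError(f"need at least k={k} used points")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    rng = np.random.default_rng(seed)
    rhos = np.empty(iterations)
    for it in range(iterations):
        perm = rng.permutation(used_idx)
        folds = np.array_split(perm, k)
        fold_rhos = []
        pooled_obs = np.zeros(n_bins)
        pooled_exp = np.zeros(n_bins)
        for fold in folds:
            if fold.size == 0:
                raise ValueError("fold with zero held-out points")
            train_used = np.setdiff1d(perm, fold)
            train = pd.concat([design.iloc[train_used], avail],
                              ignore_index=True)
            fitted = rsf_model.fit(train, spec)
            held = design.iloc[fold]
            shift = max(_linear_predictor_max(avail, fitted),
                        _linear_predictor_max(held, fitted))
            avail_scores = _score(avail, fitted, shift)
            held_scores = _score(held, fitted, shift)
            expected, observed = expected_observed(avail_scores, held_scores,
                                                   n_bins)
            if pool_folds:
                pooled_obs += observed * fold.size
                pooled_exp += expected
            else:
                fold_rhos.append(spearman(observed, expected))
        if pool_folds:
            rhos[it] = spearman(pooled_obs / pooled_obs.sum(),
                                pooled_exp / k)
        else:
            rhos[it] = float(np.mean(fold_rhos))
    return ValidationResult(rhos, k_folds=k, n_bins=n_bins)
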