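"""Evaluation metrics for simulated-network recovery.

Two measures: the root-mean-square error between inferred and true
connection strengths, computed over the unordered off-diagonal pairs in
partial-correlation space and usually reported as a proportion of the error
of naive covariance inversion (so the naive estimator scores exactly 1);
and the area under the ROC curve for recovering the binary graph as a
threshold sweeps over the absolute inferred strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .core import partial_correlation

__all__ = ["EvalResult", "rms_error", "normalise_rms", "edge_roc_auc", "summarise_posterior"]


@dataclass
class EvalResult:
    """Per-subject errors and graph-recovery scores for one estimator."""

    estimator: str
    rms: np.ndarray  # (N,)
    normalised_rms: np.ndarray | None = None  # (N,), vs the naive estimator
    auc: np.ndarray | None = None  # (N,)

    @property
    def mean_rms(self) -> float:
        return float(np.mean(self.rms))

    @property
    def mean_normalised_rms(self) -> float:
        return float(np.mean(self.normalised_rms))

    @property
    def sd_normalised_rms(self) -> float:
        return float(np.std(self.normalised_rms, ddof=1))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    def as_dict(self) -> dict:
        out = {"estimator": self.estimator, "mean_rms": self.mean_rms}
        if self.normalised_rms is not None:
            out["mean_normalised_rms"] = self.mean_normalised_rms
            out["sd_normalised_rms"] = self.sd_normalised_rms
        if self.auc is not None:
            out["mean_auc"] = self.mean_auc
        return out


def rms_error(estimated, truth, *, space: str = "pcorr") -> float:
    """RMS over the p(p-1)/2 unordered off-diagonal entries.

    ``estimated`` is a partial-correlation (or precision) matrix;``truth``
    is the true strength matrix, converted to partial correlation unless
    ``space='precision'``.
    """
    estimated = np.asarray(estimated, float)
    truth = np.asarray(truth, float)
    if estimated.shape != truth.shape:
        raise ValueError("shape mismatch between estimate and truth")
    if space == "pcorr":
        truth = partial_correlation(truth, check_pd=False)
    elif space != "precision":
        raise ValueError("space must be 'pcorr' or 'precision'")
    iu = np.triu_indices(truth.shape[0], k=1)
    d = estimated[iu] - truth[iu]
    return float(np.sqrt(np.mean(d**2)))


def rms_errors(estimates, truths, *, space: str = "pcorr") -> np.ndarray:
    """Per-subject :func:`rms_error` over matched lists."""
    if len(estimates) != len(truths):
        raise ValueError("subject count mismatch")
    return np.array([rms_error(e, t, space=space) for e, t in zip(estimates, truths)])


def normalise_rms(results, naive_results) -> np.ndarray:
    """Elementwise ratio of per-subject RMS errors to the naive estimator's.

    The naive estimator normalised against itself is exactly 1 for every
    subject, which anchors comparisons across estimators.
    """
    results = np.asarray(results, float)
    naive = np.asarray(naive_results, float)
    if results.shape != naive.shape:
        raise ValueError("subject count mismatch")
    if np.any(naive == 0):
        raise ZeroDivisionError("naive RMS error of zero")
    return results / naive


def edge_roc_auc(scores: np.ndarray, true_graph: np.ndarray) -> float:
    """Area under the ROC curve for graph recovery.

    ``scores`` may be a symmetric matrix of inferred strengths (absolute
    values are taken over the unordered pairs) or a vector already indexed
    by pair.  1.0 means some threshold perfectly separates true edges from
    non-edges; 0.5 is chance.  Ties are handled by the midrank convention
    (the implementation is the Mann-Whitney statistic).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(true_graph)
    if scores.ndim == 2:
        iu = np.triu_indices(scores.shape[0], k=1)
        scores = np.abs(scores[iu])
        truth = truth[iu]
    truth = truth.astype(int)
    if truth.min() == truth.max():
        raise ValueError("true graph has no class separation (all edges present or absent)")
    return float(roc_auc_score(truth, np.abs(scores)))


def summarise_posterior(draws, level: float = 0.95) -> dict:
    """Posterior summaries of a sampler run.

    Returns per-subject posterior-mean partial correlations (mean of
    per-draw partial correlations), the group-level mean, per-edge inclusion
    probabilities when the model carries shared edge indicators, and central
    credible intervals on the subject partial correlations.
    """
    if draws.Omega.size == 0:
        raise ValueError("empty draw archive")
    lo, hi = draws.credible_interval(level)
    out = {
        "subject_pcorr_mean": draws.subject_partial_corr_mean(),
        "group_pcorr_mean": draws.group_partial_corr_mean(),
        "pcorr_ci_low": lo,
        "pcorr_ci_high": hi,
    }
    if draws.edge_prob is not None:
        out["edge_probabilities"] = draws.edge_probabilities()
    return out
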