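"""Domain containers and deterministic linear algebra for multi-subject
Gaussian graphical models.

The central objects are a panel of per-subject multivariate time series
``Y_s`` (``p`` regions x ``n_s`` samples), their inner products
``S_s = Y_s Y_s^T``, and symmetric positive-definite precision matrices
``Omega_s`` whose off-diagonal zeros encode conditional independence.
Everything here is pure computation shared by the samplers, baselines and
simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "TimeSeriesPanel",
    "InnerProductSet",
    "PrecisionSet",
    "ColumnState",
    "standardise_panel",
    "inner_products",
    "partial_correlation",
    "partition_column",
    "reassemble_column",
    "is_positive_definite",
]

PD_TOL = 1e-10  # default minimum Cholesky pivot certifying positive definiteness


class DegenerateSeriesError(ValueError):
    """A region has zero temporal variance where unit variance was requested."""


class NotPositiveDefiniteError(ValueError):
    """A matrix required to be symmetric positive definite is not."""


@dataclass
class TimeSeriesPanel:
    """Multi-subject collection of region-by-time data matrices.

    Parameters
    ----------
    subjects
        List of arrays, each of shape ``(p, n_s)`` -- one row per region of
        interest, one column per time point.  All subjects must share ``p``.
    labels
        Optional region names, length ``p``.
    """

    subjects: list[np.ndarray]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.subjects = [np.asarray(y, dtype=float) for y in self.subjects]
        if not self.subjects:
            raise ValueError("panel needs at least one subject")
        ps = {y.shape[0] for y in self.subjects}
        if len(ps) != 1:
            raise ValueError(f"subjects disagree on region count: {sorted(ps)}")
        for i, y in enumerate(self.subjects):
            if y.ndim != 2 or y.shape[1] < 2:
                raise ValueError(f"subject {i}: need a (p, n_s) matrix with n_s >= 2")
        if self.labels is not None and len(self.labels) != self.p:
            raise ValueError("label count does not match region count")

    @property
    def p(self) -> int:
        return self.subjects[0].shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_s(self) -> tuple[int, ...]:
        return tuple(y.shape[1] for y in self.subjects)

    def concatenated(self) -> "TimeSeriesPanel":
        """All subjects' series joined in time, as a single-subject panel."""
        return TimeSeriesPanel([np.concatenate(self.subjects, axis=1)], self.labels)


@dataclass
class InnerProductSet:
    """Per-subject inner-product matrices ``S_s = Y_s Y_s^T`` with sample counts."""

    S: list[np.ndarray]
    n_s: tuple[int, ...]

    @property
    def p(self) -> int:
        return self.S[0].shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.S)


@dataclass
class PrecisionSet:
    """Per-subject symmetric positive definite precision matrices."""

    Omega: list[np.ndarray]

    def __post_init__(self) -> None:
        self.Omega = [np.asarray(om, dtype=float) for om in self.Omega]

    @property
    def p(self) -> int:
        return self.Omega[0].shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.Omega)

    def partial_correlations(self) -> list[np.ndarray]:
        return [partial_correlation(om) for om in self.Omega]


@dataclass
class ColumnState:
    """Partitioned quantities for one column sweep, across subjects.

    ``j`` is the (0-based) column under update.  For each subject ``s`` the
    precision is split into the principal minor ``Omega11`` (column ``j``
    deleted), the off-diagonal column ``omega12`` and the diagonal entry
    ``omega22``; the substituted variables are ``u = omega12`` and
    ``nu = omega22 - omega12' Omega11^{-1} omega12`` (the Schur complement,
    strictly positive on the PD cone).  ``Upsilon = (S22 + lambda) Omega11^{-1}``.
    """

    j: int
    Omega11_inv: list[np.ndarray]
    u: list[np.ndarray]
    nu: list[float]
    Upsilon: list[np.ndarray]
    S12: list[np.ndarray]
    S22: list[float] = field(default_factory=list)


def standardise_panel(panel: TimeSeriesPanel, unit_variance: bool = False) -> TimeSeriesPanel:
    """Temporally demean (and optionally variance-normalise) every region.

    Each row of each subject's matrix has its temporal mean removed; with
    ``unit_variance`` the rows are additionally scaled to unit sample
    variance (ddof=1).  Raises :class:`DegenerateSeriesError` for a
    zero-variance region when scaling is requested.
    """
    out = []
    for i, y in enumerate(panel.subjects):
        yc = y - y.mean(axis=1, keepdims=True)
        if unit_variance:
            sd = yc.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                raise DegenerateSeriesError(f"subject {i} has a constant region")
            yc = yc / sd
        out.append(yc)
    return TimeSeriesPanel(out, panel.labels)


def inner_products(panel: TimeSeriesPanel) -> InnerProductSet:
    """Gram matrices ``S_s = Y_s Y_s^T`` for every subject."""
    S = []
    for y in panel.subjects:
        g = y @ y.T
        S.append((g + g.T) / 2.0)
    return InnerProductSet(S, panel.n_s)


def partial_correlation(Omega: np.ndarray, *, check_pd: bool = True) -> np.ndarray:
    """Partial-correlation matrix of a precision matrix.

    ``P_ij = -omega_ij / sqrt(omega_ii omega_jj)`` off the diagonal and 1 on
    it.  With ``check_pd`` (the default) a non-PD input raises
    :class:`NotPositiveDefiniteError`; evaluation code disables the check to
    normalise ground-truth strength matrices that need not be PD.
    """
    Omega = np.asarray(Omega, dtype=float)
    if check_pd and not is_positive_definite(Omega):
        raise NotPositiveDefiniteError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(Omega))
    P = -Omega / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def partition_column(Omega: np.ndarray, S: np.ndarray, j: int):
    """Split ``Omega`` and ``S`` around column ``j`` (0-based).

    Returns ``(Omega11, omega12, omega22, S12, S22)`` where ``Omega11`` is
    ``Omega`` with row and column ``j`` deleted, ``omega12`` the off-diagonal
    part of column ``j`` and ``omega22`` its diagonal entry; identically for
    ``S``.
    """
    p = Omega.shape[0]
    if not 0 <= j < p:
        raise IndexError(f"column index {j} out of range for p={p}")
    keep = np.arange(p) != j
    Omega11 = Omega[np.ix_(keep, keep)]
    omega12 = Omega[keep, j]
    omega22 = Omega[j, j]
    S12 = S[keep, j]
    S22 = S[j, j]
    return Omega11, omega12, omega22, S12, S22


def reassemble_column(Omega11: np.ndarray, u: np.ndarray, nu: float, j: int) -> np.ndarray:
    """Rebuild a full precision matrix from a column decomposition.

    Inverse of :func:`partition_column` under the substitution
    ``(u, nu) = (omega12, omega22 - omega12' Omega11^{-1} omega12)``: column
    ``j`` is re-inserted with off-diagonal ``u`` and diagonal
    ``nu + u' Omega11^{-1} u``.  For PD ``Omega11`` and ``nu > 0`` the result
    is PD by the Schur-complement argument, which is what lets the column
    sampler stay inside the PD cone at every update.
    """
    if nu <= 0:
        raise ValueError(f"Schur complement nu must be positive, got {nu}")
    pm1 = Omega11.shape[0]
    p = pm1 + 1
    if not 0 <= j < p:
        raise IndexError(f"column index {j} out of range for p={p}")
    w = sla.solve(Omega11, u, assume_a="pos")
    omega22 = nu + float(u @ w)
    keep = np.arange(p) != j
    Omega = np.empty((p, p))
    Omega[np.ix_(keep, keep)] = Omega11
    Omega[keep, j] = u
    Omega[j, keep] = u
    Omega[j, j] = omega22
    return Omega


def is_positive_definite(M: np.ndarray, tol: float = PD_TOL) -> bool:
    """Certify symmetric positive definiteness by Cholesky factorisation.

    True iff the factorisation succeeds with every pivot above ``tol``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    try:
        L = np.linalg.cholesky((M + M.T) / 2.0)
    except np.linalg.LinAlgError:
        return False
    return bool(np.min(np.diag(L)) ** 2 > tol)
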