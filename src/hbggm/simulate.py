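"""Synthetic multi-subject network data.

Generators for the benchmark designs used to validate the samplers: sparse
circle-structured precision matrices shared or perturbed across subjects,
random-edge models in which connections toggle on and off per time point,
and G-Wishart-structured group/subject hierarchies on an arbitrary graph.
Each generator returns a :class:`~hbggm.core.TimeSeriesPanel` together with
the :class:`GroundTruth` it was drawn from.

Presets ``sim1`` .. ``sim8`` parameterise the standard benchmark table:

========  ========  =====  ======  ==========  =================
preset    subjects    p     n_s    subject sd  structure
========  ========  =====  ======  ==========  =================
sim1          5       6      18        0       circle
sim2         25       6      18        0       circle
sim3         25       6     500        0       circle
sim4         25       6    1000        0       circle
sim6         25      25     500       --       random edges
sim7         25       6      25      0.05      circle
sim8         25      30    1100      0.15      circle
========  ========  =====  ======  ==========  =================

(The netsim and cortical-adjacency designs require external data; any
user-supplied adjacency is accepted in their place via the
``gwishart_structured`` / ``custom_graph`` structures.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import TimeSeriesPanel, partial_correlation

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "circle_precision",
    "perturb_subjects",
    "random_edge_dataset",
    "gwishart_draw",
    "structured_group_dataset",
    "nearest_pd",
    "sample_timeseries",
    "generate",
    "PRESETS",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset."""

    sim_id: str = "custom"
    n_subjects: int = 5
    p: int = 6
    structure: Literal["circle", "random_edges", "gwishart_structured", "custom_graph"] = "circle"
    n_s: int = 18
    subject_sd: float = 0.0
    edge_mean: float = 0.25
    edge_sd: float = 0.05
    df_group: float | None = None
    df_subject: float = 50.0
    graph: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p < 3:
            raise ValueError("need p >= 3")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


@dataclass
class GroundTruth:
    """True per-subject strengths behind a simulated panel.

    ``precisions`` holds the matrices the data were generated from (for the
    random-edge design, the probability-weighted strength matrices, which
    need not be PD).  ``graph`` is the binary adjacency whose complement
    marks structural zeros.
    """

    precisions: list[np.ndarray]
    graph: np.ndarray
    group_mean: np.ndarray
    partial_correlations: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.partial_correlations:
            self.partial_correlations = [
                partial_correlation(om, check_pd=False) for om in self.precisions
            ]


def circle_precision(p: int) -> np.ndarray:
    """The standard sparse 'circle' benchmark precision.

    Unit diagonal, 0.5 on the first off-diagonals, 0.4 linking nodes 1 and
    ``p`` (closing the ring), zero elsewhere; positive definite for all p.
    """
    if p < 3:
        raise ValueError("need p >= 3")
    Om = np.eye(p)
    idx = np.arange(p - 1)
    Om[idx, idx + 1] = Om[idx + 1, idx] = 0.5
    Om[0, p - 1] = Om[p - 1, 0] = 0.4
    return Om


def nearest_pd(M: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Frobenius-nearest symmetric matrix with eigenvalues >= ``epsilon``.

    For symmetric input this is exactly eigenvalue clipping (Higham): keep
    the eigenvectors, floor the spectrum at ``epsilon``.
    """
    Ms = (M + M.T) / 2.0
    w, V = np.linalg.eigh(Ms)
    if w.min() >= epsilon:
        return Ms
    return (V * np.maximum(w, epsilon)) @ V.T


def _rescale_unit_variance(Omega: np.ndarray) -> np.ndarray:
    """Rescale a precision so the implied covariance is a correlation matrix."""
    Cov = np.linalg.inv(Omega)
    d = np.sqrt(np.diag(Cov))
    Corr = Cov / np.outer(d, d)
    Om = np.linalg.inv(Corr)
    return (Om + Om.T) / 2.0


def perturb_subjects(
    group_Omega: np.ndarray,
    n_subjects: int,
    sd: float,
    rng: np.random.Generator,
    *,
    random_signs: bool = True,
) -> list[np.ndarray]:
    """Per-subject precisions scattered about a group-mean network.

    Each nonzero group edge receives a random sign shared by all subjects;
    subject strengths are then drawn ``N(signed group value, sd^2)``.  Any
    indefinite draw is repaired to the PD cone (nearest-PD) and every matrix
    is rescaled so its implied covariance has unit variances.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    p = group_Omega.shape[0]
    iu = np.triu_indices(p, k=1)
    base = group_Omega[iu].copy()
    nz = base != 0
    if random_signs:
        signs = np.where(rng.random(nz.sum()) < 0.5, -1.0, 1.0)
        base[nz] = base[nz] * signs
    out = []
    for _ in range(n_subjects):
        off = np.zeros_like(base)
        off[nz] = rng.normal(base[nz], sd) if sd > 0 else base[nz]
        Om = np.zeros((p, p))
        Om[iu] = off
        Om.T[iu] = off
        np.fill_diagonal(Om, np.diag(group_Omega))
        if np.linalg.eigvalsh(Om).min() <= 1e-4:
            Om = nearest_pd(Om, epsilon=1e-4)
        out.append(_rescale_unit_variance(Om))
    return out


def sample_timeseries(Omega: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` iid draws from ``N(0, Omega^{-1})``, arranged ``p x n``."""
    if n < 1:
        raise ValueError("need n >= 1")
    L = np.linalg.cholesky(Omega)
    # x = L^{-T} z has covariance (L L^T)^{-1} = Omega^{-1}
    z = rng.standard_normal((Omega.shape[0], n))
    return np.linalg.solve(L.T, z)


def random_edge_dataset(
    spec: SimulationSpec,
    rng: np.random.Generator,
    prob_choices: tuple[float, ...] = (0.0, 0.5, 1.0),
):
    """The random-edge design mimicking the spike-and-slab prior.

    Each unordered pair gets an inclusion probability drawn uniformly from
    {0, 0.5, 1}; subject strengths are ``N(edge_mean, edge_sd^2)``.  At every
    time point the probability-0.5 edges are independently toggled on or
    off, the realised matrix is PD-repaired, and one sample is drawn from
    it.  The ground truth is the elementwise product of the probability
    matrix and the subject's strengths.
    """
    if spec.structure != "random_edges":
        raise ValueError("spec.structure must be 'random_edges'")
    p, iu = spec.p, np.triu_indices(spec.p, k=1)
    E = len(iu[0])
    probs = rng.choice(prob_choices, size=E)
    graph = np.zeros((p, p))
    graph[iu] = (probs > 0).astype(float)
    graph += graph.T

    subjects, truths = [], []
    for _ in range(spec.n_subjects):
        strength = rng.normal(spec.edge_mean, spec.edge_sd, size=E)
        truth = np.eye(p)
        truth[iu] = probs * strength
        truth.T[np.triu_indices(p, k=1)] = truth[iu]
        cols = np.empty((p, spec.n_s))
        on_fixed = probs == 1.0
        maybe = probs == 0.5
        for t in range(spec.n_s):
            on = on_fixed | (maybe & (rng.random(E) < 0.5))
            Om = np.eye(p)
            off = np.where(on, strength, 0.0)
            Om[iu] = off
            Om.T[np.triu_indices(p, k=1)] = off
            if np.linalg.eigvalsh(Om).min() <= 1e-6:
                Om = nearest_pd(Om, epsilon=1e-6)
            cols[:, t] = sample_timeseries(Om, 1, rng)[:, 0]
        subjects.append(cols)
        truths.append(truth)

    panel = TimeSeriesPanel(subjects)
    group = np.mean(truths, axis=0)
    return panel, GroundTruth(truths, (graph > 0).astype(int), group)


def gwishart_draw(
    graph: np.ndarray,
    df: float,
    scale: np.ndarray,
    rng: np.random.Generator,
    *,
    n_sweeps: int = 200,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One draw from the G-Wishart distribution conditional on a graph.

    Density ``|Omega|^{(df-2)/2} exp(-tr(scale^{-1} Omega)/2)`` restricted to
    PD matrices with zeros off ``graph``; for the complete graph this is a
    standard Wishart with ``df + p - 1`` degrees of freedom and the given
    scale.  Sampling is by block Gibbs over columns: each column's free
    (in-graph) entries have a Gaussian conditional and its Schur complement
    a Gamma conditional, so every sweep stays in the PD cone.
    """
    graph = np.asarray(graph)
    if not np.array_equal(graph, graph.T):
        raise ValueError("graph must be symmetric")
    p = graph.shape[0]
    if df <= 0:
        raise ValueError("need df > 0")
    V_inv = np.linalg.inv(scale)
    Omega = init.copy() if init is not None else (df + p - 1) * np.asarray(scale, float).copy()
    Omega = Omega * (graph + np.eye(p) > 0)  # respect the zero pattern
    if np.linalg.eigvalsh(Omega).min() <= 0:
        Omega = nearest_pd(Omega, epsilon=1e-3)
        Omega = Omega * (graph + np.eye(p) > 0)
        Omega = Omega + np.eye(p) * max(0.0, 1e-3 - np.linalg.eigvalsh(Omega).min())

    keepers = [np.flatnonzero(np.arange(p) != j) for j in range(p)]
    for _ in range(n_sweeps):
        for j in range(p):
            keep = keepers[j]
            free = np.flatnonzero(graph[keep, j] > 0)
            Om11 = Omega[np.ix_(keep, keep)]
            Om11_inv = np.linalg.inv(Om11)
            v22 = V_inv[j, j]
            nu = rng.gamma(df / 2.0, 2.0 / v22)
            u = np.zeros(p - 1)
            if free.size:
                Q = v22 * Om11_inv[np.ix_(free, free)]
                b = -V_inv[keep, j][free]
                L = np.linalg.cholesky(Q)
                mean = np.linalg.solve(Q, b)
                u[free] = mean + np.linalg.solve(L.T, rng.standard_normal(free.size))
            w = Om11_inv @ u
            Omega[keep, j] = u
            Omega[j, keep] = u
            Omega[j, j] = nu + float(u @ w)
    return (Omega + Omega.T) / 2.0


def structured_group_dataset(spec: SimulationSpec, rng: np.random.Generator):
    """Group/subject hierarchy of G-Wishart draws on a fixed graph.

    The group matrix is a G-Wishart draw with identity scale and ``df_group``
    (default ``p - 1``) degrees of freedom; subject matrices are G-Wishart
    draws using the group matrix as scale and ``df_subject`` degrees of
    freedom (larger values concentrate subjects about the group).  Time
    series are then drawn from each subject's Gaussian.
    """
    if spec.graph is None:
        raise ValueError("structured_group_dataset needs spec.graph")
    if spec.df_subject <= 0:
        raise ValueError("df_subject must be positive")
    p = spec.p
    graph = (np.asarray(spec.graph) > 0).astype(int)
    np.fill_diagonal(graph, 0)
    df_group = spec.df_group if spec.df_group is not None else p - 1
    group = gwishart_draw(graph, df_group, np.eye(p), rng)
    truths, subjects = [], []
    for _ in range(spec.n_subjects):
        Om = gwishart_draw(graph, spec.df_subject, group, rng, n_sweeps=100)
        truths.append(Om)
        subjects.append(sample_timeseries(Om, spec.n_s, rng))
    panel = TimeSeriesPanel(subjects)
    return panel, GroundTruth(truths, graph, group)


def _circle_dataset(spec: SimulationSpec, rng: np.random.Generator):
    group = circle_precision(spec.p)
    graph = (group != 0).astype(int)
    np.fill_diagonal(graph, 0)
    if spec.subject_sd > 0:
        truths = perturb_subjects(group, spec.n_subjects, spec.subject_sd, rng)
    else:
        truths = [group.copy() for _ in range(spec.n_subjects)]
    subjects = [sample_timeseries(om, spec.n_s, rng) for om in truths]
    return TimeSeriesPanel(subjects), GroundTruth(truths, graph, np.mean(truths, axis=0))


PRESETS: dict[str, SimulationSpec] = {
    "sim1": SimulationSpec("sim1", n_subjects=5, p=6, n_s=18),
    "sim2": SimulationSpec("sim2", n_subjects=25, p=6, n_s=18),
    "sim3": SimulationSpec("sim3", n_subjects=25, p=6, n_s=500),
    "sim4": SimulationSpec("sim4", n_subjects=25, p=6, n_s=1000),
    "sim6": SimulationSpec("sim6", n_subjects=25, p=25, n_s=500, structure="random_edges"),
    "sim7": SimulationSpec("sim7", n_subjects=25, p=6, n_s=25, subject_sd=0.05),
    "sim8": SimulationSpec("sim8", n_subjects=25, p=30, n_s=1100, subject_sd=0.15),
}


def generate(spec: SimulationSpec | str, rng: np.random.Generator | int | None = None):
    """Dispatch a :class:`SimulationSpec` (or preset name) to its generator."""
    if isinstance(spec, str):
        try:
            spec = PRESETS[spec]
        except KeyError:
            raise ValueError(f"unknown preset {spec!r}; have {sorted(PRESETS)}") from None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    if spec.structure == "circle":
        return _circle_dataset(spec, rng)
    if spec.structure == "random_edges":
        return random_edge_dataset(spec, rng)
    if spec.structure in ("gwishart_structured", "custom_graph"):
        return structured_group_dataset(spec, rng)
    raise ValueError(f"unknown structure {spec.structure!r}")
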