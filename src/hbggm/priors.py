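"""Hierarchical prior on multi-subject precision matrices.

Each off-diagonal precision entry gets a spike-and-(non-central-)slab prior
shared across subjects: with edge indicator ``z_ij = 1`` the subject
strengths are ``omega_ijs ~ N(mu_ij, sigma_ij^2)``; with ``z_ij = 0`` they
are exactly zero.  The group means are shrunk, ``mu_ij ~ N(0, chi^2)`` with
``chi ~ C+(0, A)`` (half-Cauchy), the between-subject scales have a
log-normal prior ``log sigma_ij ~ N(log m_sigma, s_sigma^2)``, edges are
``z_ij ~ Bernoulli(a)`` with ``a ~ Beta(a_pi, b_pi)``, and diagonals are
exponential ``Exp(omega_ii; lambda_s / 2)`` with the neutral Gamma
hyperprior ``lambda_s ~ Ga(1/3, 0)`` (improper; used only through its
conjugate update).

The half-Cauchy scale is handled by the standard conditionally-conjugate
parameter expansion ``chi^2 | xi ~ Inv-Gamma(1/2, 1/xi)``,
``xi ~ Inv-Gamma(1/2, 1/A^2)``, which marginalises back to ``C+(0, A)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PrecisionSet

__all__ = [
    "HyperConstants",
    "HierarchyParams",
    "default_hyperconstants",
    "log_slab_density",
    "sample_prior_predictive",
]


@dataclass(frozen=True)
class HyperConstants:
    """Fixed hyper-parameters of the hierarchy.

    ``m_sigma``, ``s_sigma``: centre and spread of the log-normal prior on
    the between-subject scale.  ``A``: half-Cauchy scale for the group
    shrinkage, appropriate for variance-scaled data where partial
    correlations rarely exceed 0.7.  ``a_pi``, ``b_pi``: Beta prior on the
    edge-inclusion probability, placing most mass in (0.3, 0.7).
    ``gamma_shape``: shape of the neutral Gamma hyperprior on the diagonal
    rates (rate 0, improper).
    """

    m_sigma: float = 0.5
    s_sigma: float = 1.0
    A: float = 0.7
    a_pi: float = 6.0
    b_pi: float = 6.0
    gamma_shape: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("m_sigma", "s_sigma", "A", "a_pi", "b_pi", "gamma_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_hyperconstants() -> HyperConstants:
    """The default constants used for functional-network modelling."""
    return HyperConstants()


@dataclass
class HierarchyParams:
    """Sampled state of the hierarchical prior.

    All pair-indexed arrays are ``(p, p)`` symmetric with the diagonal
    unused.  ``mu``, ``sigma`` and ``Z`` exist for every pair, including
    currently excluded edges (which refresh from their priors), so the chain
    lives on the full parameter space.
    """

    mu: np.ndarray
    sigma: np.ndarray
    chi: float
    a: float
    Z: np.ndarray
    lambda_s: np.ndarray
    xi: float = 1.0
    constants: HyperConstants = field(default_factory=default_hyperconstants)

    def validate(self) -> None:
        if not (0 < self.a <= 1):
            raise ValueError("a must lie in (0, 1]")
        if self.chi <= 0 or self.xi <= 0:
            raise ValueError("chi and xi must be positive")
        if np.any(self.sigma <= 0) or np.any(self.lambda_s <= 0):
            raise ValueError("sigma and lambda_s must be positive")
        if not np.array_equal(self.Z, self.Z.T):
            raise ValueError("Z must be symmetric")

    @property
    def p(self) -> int:
        return self.mu.shape[0]


def log_slab_density(omega: float | np.ndarray, mu_ij: float, sigma_ij: float):
    """Log density of the slab, ``N(omega; mu_ij, sigma_ij^2)``."""
    if sigma_ij <= 0:
        raise ValueError("sigma_ij must be positive")
    return stats.norm.logpdf(omega, loc=mu_ij, scale=sigma_ij)


def sample_prior_predictive(
    p: int,
    n_subjects: int,
    constants: HyperConstants | None = None,
    rng: np.random.Generator | None = None,
    *,
    a: float | None = None,
    lambda_s: float = 1.0,
) -> tuple[HierarchyParams, PrecisionSet]:
    """One ancestral draw from the full hierarchy.

    Draws ``a`` (unless forced), ``chi``, then per-pair ``(z, mu, sigma)``
    and per-subject precision entries; diagonals come from
    ``Exp(lambda_s/2)`` with the supplied fixed rate, because the neutral
    ``Ga(1/3, 0)`` hyperprior is improper and admits no ancestral draw.  Raw
    subject matrices violating positive definiteness are repaired to the PD
    cone with :func:`hbggm.simulate.nearest_pd`.
    """
    from .simulate import nearest_pd  # local import: simulate depends on core only

    if p < 2:
        raise ValueError("need p >= 2")
    c = constants or default_hyperconstants()
    rng = np.random.default_rng(rng)

    a_draw = float(rng.beta(c.a_pi, c.b_pi)) if a is None else float(a)
    chi = float(stats.halfcauchy(scale=c.A).rvs(random_state=rng))
    xi = float(1.0 / rng.gamma(0.5, 1.0 / c.A**2))  # expansion companion

    iu = np.triu_indices(p, k=1)
    E = len(iu[0])
    z = (rng.random(E) < a_draw).astype(int)
    mu = rng.normal(0.0, chi, size=E)
    sigma = np.exp(rng.normal(np.log(c.m_sigma), c.s_sigma, size=E))

    def sym(vals, diag=0.0):
        M = np.full((p, p), float(diag))
        M[iu] = vals
        M.T[iu] = vals
        return M

    Z = sym(z).astype(int)
    Mu = sym(mu)
    Sigma = sym(sigma, diag=c.m_sigma)

    omegas = []
    for _ in range(n_subjects):
        off = np.where(z == 1, rng.normal(mu, sigma), 0.0)
        Om = sym(off)
        np.fill_diagonal(Om, rng.exponential(2.0 / lambda_s, size=p))
        if np.linalg.eigvalsh(Om).min() <= 0:
            Om = nearest_pd(Om, epsilon=1e-6)
        omegas.append(Om)

    params = HierarchyParams(
        mu=Mu,
        sigma=Sigma,
        chi=chi,
        a=max(a_draw, 1e-12),
        Z=Z,
        lambda_s=np.full(n_subjects, lambda_s),
        xi=xi,
        constants=c,
    )
    return params, PrecisionSet(omegas)
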