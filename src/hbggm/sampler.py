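"""Block-Gibbs / collapsed Metropolis-Hastings samplers for multi-subject
sparse precision matrices.

The posterior over each column of the precision matrices factorises, across
subjects, into a Gaussian on the off-diagonal strengths ``u_s`` and a Gamma
on the Schur complement ``nu_s`` -- a linked linear-regression form.  One
sweep visits every column (random order), drawing all column variables for
all subjects jointly; the Gamma draw on ``nu_s > 0`` keeps every matrix
inside the positive-definite cone at every update.  In the strongly sparse
model the shared edge indicators ``z_ij`` are updated first by
Metropolis-Hastings on the column's model evidence, with the strengths
``u_s`` and group means ``mu_ij`` integrated out analytically (both layers
are Gaussian given the scales), then ``mu`` and ``u`` are re-drawn from
their exact conditionals -- a partially collapsed Gibbs step.

Five model variants run through the same column machinery:

``strong``
    spike-and-slab shared graph, hierarchical slab (the full model);
``weak``
    the same hierarchy with the graph fixed full (``a = 1``, ``z = 1``);
``single_subject``
    concatenated data, central slab ``N(0, 0.7^2)``, spike-and-slab graph;
``bayesian_glasso``
    per-subject double-exponential (Laplace) prior via its exponential
    scale mixture, full graph;
``ssvs``
    per-subject two-component normal mixture (stochastic search variable
    selection) with ``v0 = 0.05``, ``v1 = 2.5``, ``a = 0.5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    TimeSeriesPanel,
    inner_products,
    is_positive_definite,
    partial_correlation,
    standardise_panel,
)
from .priors import HyperConstants, default_hyperconstants

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "draw_nu",
    "compute_upsilon",
    "draw_column_strengths",
    "column_log_evidence",
    "update_z_column",
    "update_mu_column",
    "update_sigma",
    "update_chi",
    "update_a",
    "update_lambda",
    "gibbs_sweep",
    "run_sampler",
]

_MODELS = ("strong", "weak", "single_subject", "bayesian_glasso", "ssvs")


@dataclass
class SamplerConfig:
    """Run-time configuration of the MCMC engine.

    Defaults follow standard practice for these models: 30 000 samples after
    10 000 warm-up in a single chain, thinning 10.  ``mh_step_logsigma`` is
    the random-walk scale on ``log sigma_ij``, adapted during warm-up toward
    40% acceptance and frozen afterwards.
    """

    model: str = "strong"
    n_samples: int = 30_000
    n_warmup: int = 10_000
    n_chains: int = 1
    seed: int = 0
    thin: int = 10
    mh_step_logsigma: float = 0.1
    ssvs_v0: float = 0.05
    ssvs_v1: float = 2.5
    ssvs_a: float = 0.5
    bglasso_lambda: float = 1.0
    single_slab_sd: float = 0.7
    sample_z: bool | None = None  # None -> model default
    z_init: np.ndarray | None = None
    z_threshold: float = 0.05
    tikhonov_init: float = 0.01
    check_pd_every: int = 0  # 0: check stored draws only; k>0: check every k-th sweep
    standardise: bool = True
    constants: HyperConstants = field(default_factory=default_hyperconstants)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.n_samples < 0 or self.n_warmup < 0:
            raise ValueError("n_samples and n_warmup must be >= 0")
        if self.mh_step_logsigma <= 0 or self.thin < 1:
            raise ValueError("step sizes must be > 0 and thin >= 1")


# ---------------------------------------------------------------------------
# Exact conditionals (all batched over subjects / pairs where sensible)
# ---------------------------------------------------------------------------

def draw_nu(n_s, S22, lambda_s, rng: np.random.Generator):
    """Schur-complement draw: ``Gamma(n_s/2 + 1, rate=(S22 + lambda_s)/2)``.

    Strict positivity of this draw is what guarantees positive definiteness
    of the reassembled precision matrix.
    """
    rate = (np.asarray(S22, float) + np.asarray(lambda_s, float)) / 2.0
    if np.any(rate <= 0):
        raise ValueError("S22 + lambda_s must be positive")
    shape = np.asarray(n_s, float) / 2.0 + 1.0
    return rng.gamma(shape, 1.0 / rate)


def compute_upsilon(S22, lambda_s, Omega11_inv):
    """``Upsilon_s = (S22 + lambda_s) * Omega11_inv`` (batched)."""
    scale = np.asarray(S22, float) + np.asarray(lambda_s, float)
    Omega11_inv = np.asarray(Omega11_inv, float)
    if Omega11_inv.ndim == 2:
        return scale * Omega11_inv
    return scale[:, None, None] * Omega11_inv


def draw_column_strengths(Upsilon, S12, mu12, sigma12, z12, rng: np.random.Generator):
    """Draw the off-diagonal column strengths ``u_s`` for every subject.

    Entries with ``z = 0`` are exactly zero.  The included subvector of each
    subject is Gaussian with precision ``Q = Upsilon[in,in] + diag(1/sigma^2)``
    and mean ``Q^{-1}(-S12[in] + mu[in]/sigma[in]^2)``.
    """
    Upsilon = np.asarray(Upsilon, float)
    if Upsilon.ndim == 2:
        Upsilon = Upsilon[None]
    S12 = np.atleast_2d(np.asarray(S12, float))
    z12 = np.asarray(z12).astype(bool)
    N, q = S12.shape
    u = np.zeros((N, q))
    idx = np.flatnonzero(z12)
    k = idx.size
    if k == 0:
        return u
    sig = np.asarray(sigma12, float)[idx]
    d_inv = 1.0 / sig**2
    Q = Upsilon[np.ix_(range(N), idx, idx)] + np.diag(d_inv)
    b = -S12[:, idx] + d_inv * np.asarray(mu12, float)[idx]
    L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, b[..., None])[..., 0]
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), rng.standard_normal((N, k, 1)))[..., 0]
    u[:, idx] = mean + noise
    return u


class _ColTerms:
    """All quantities of one column's collapsed conditional for a pattern z.

    Computed once and shared by the evidence, the collapsed ``mu`` draw and
    the ``u | mu`` draw.  ``chi=None`` drops the group-mean layer (central
    fixed slab, single-subject model).
    """

    __slots__ = ("idx", "k", "d_inv", "Q", "L", "Qinv", "Qinv_c", "A", "La", "b", "logE")

    def __init__(self, Upsilon, S12, z12, sigma12, chi):
        idx = np.flatnonzero(z12)
        self.idx = idx
        self.k = k = idx.size
        if k == 0:
            self.logE = 0.0
            return
        N = S12.shape[0]
        sigma_in = np.asarray(sigma12, float)[idx] * np.ones(k)
        d_inv = self.d_inv = 1.0 / sigma_in**2
        if k == z12.size:  # full column included: skip the submatrix gather
            Q = Upsilon + np.diag(d_inv)
        else:
            Q = Upsilon[np.ix_(range(N), idx, idx)] + np.diag(d_inv)
        self.Q = Q
        c = -S12[:, idx]
        # one LU solve yields both Q^{-1} c and Q^{-1}; a Cholesky of Q^{-1}
        # then serves the noise draw (B B' = Q^{-1}) and the log-determinant
        rhs = np.concatenate(
            [c[:, :, None], np.broadcast_to(np.eye(k), (N, k, k))], axis=2
        )
        sol = np.linalg.solve(Q, rhs)
        self.Qinv_c = Qinv_c = sol[:, :, 0]
        Qinv = sol[:, :, 1:]
        self.Qinv = Qinv = (Qinv + np.swapaxes(Qinv, -1, -2)) / 2.0
        self.L = L = np.linalg.cholesky(Qinv)  # NB: factor of the *inverse*
        logdetQ = -2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum()
        quad_c = float(np.sum(c * Qinv_c))
        logE = -N * float(np.log(sigma_in).sum()) - 0.5 * logdetQ + 0.5 * quad_c
        if chi is not None:
            A = N * np.diag(d_inv) + np.eye(k) / chi**2 - (d_inv[:, None] * Qinv.sum(axis=0)) * d_inv
            self.A = A = (A + A.T) / 2.0
            self.b = b = d_inv * Qinv_c.sum(axis=0)
            self.La = La = np.linalg.cholesky(A)
            logdetA = 2.0 * float(np.log(np.diag(La)).sum())
            w = np.linalg.solve(A, b)
            logE += -k * math.log(chi) - 0.5 * logdetA + 0.5 * float(b @ w)
        self.logE = logE


def column_log_evidence(
    Upsilon,
    S12,
    z12,
    sigma12,
    chi: float | None,
    *,
    mu_fixed: float = 0.0,
) -> float:
    """Log marginal density of one column's data given a spike pattern.

    The subject strengths ``u_s`` (and, when ``chi`` is given, the group
    mean ``mu12``) are integrated out analytically under the Gaussian slab.
    Normalised so the empty pattern has evidence 0; constants independent of
    ``z12`` are dropped.  With ``chi=None`` the slab is central at
    ``mu_fixed`` with no group layer (single-subject model).
    """
    if mu_fixed != 0.0:
        raise NotImplementedError("fixed slab is central in this model family")
    Upsilon = np.asarray(Upsilon, float)
    if Upsilon.ndim == 2:
        Upsilon = Upsilon[None]
    S12 = np.atleast_2d(np.asarray(S12, float))
    z12 = np.asarray(z12).astype(bool)
    sigma12 = np.asarray(sigma12, float) * np.ones(z12.size)
    return _ColTerms(Upsilon, S12, z12, sigma12, chi).logE


def update_z_column(
    Upsilon,
    S12,
    z12,
    sigma12,
    chi: float | None,
    a: float,
    rng: np.random.Generator,
    *,
    n_proposals: int = 1,
    current_logE: float | None = None,
):
    """Collapsed Metropolis-Hastings on one column's edge indicators.

    Proposes single-entry flips (``n_proposals`` random entries per call;
    one per column per sweep by default) and accepts with probability
    ``min(1, exp(dlogE) * prior_ratio)`` where the prior ratio is
    ``a/(1-a)`` for an addition and its inverse for a removal.  With
    ``a = 1`` removals are rejected with probability 1.

    Returns ``(z12, logE)`` with the evidence of the accepted pattern.
    """
    z12 = np.asarray(z12).astype(int).copy()
    if current_logE is None:
        current_logE = column_log_evidence(Upsilon, S12, z12, sigma12, chi)
    q = z12.size
    for i in rng.integers(0, q, size=n_proposals):
        adding = z12[i] == 0
        if not adding and a >= 1.0:
            continue  # removal has zero acceptance under a full-graph prior
        z_prop = z12.copy()
        z_prop[i] = 1 - z_prop[i]
        logE_prop = column_log_evidence(Upsilon, S12, z_prop, sigma12, chi)
        log_prior = math.log(a) - math.log1p(-a) if a < 1.0 else math.inf
        log_ratio = logE_prop - current_logE + (log_prior if adding else -log_prior)
        if math.log(rng.random()) < log_ratio:
            z12, current_logE = z_prop, logE_prop
    return z12, current_logE


def update_mu_column(u, sigma12, chi: float, z12, rng: np.random.Generator):
    """Conjugate draw of the group means of one column given the strengths.

    For included entries, precision ``N/sigma^2 + 1/chi^2`` and mean
    ``(sum_s u_s / sigma^2) / precision``; excluded entries refresh from the
    ``N(0, chi^2)`` prior so the chain stays on the full parameter space.
    """
    u = np.atleast_2d(np.asarray(u, float))
    z = np.asarray(z12).astype(bool)
    sigma12 = np.asarray(sigma12, float) * np.ones(z.size)
    N = u.shape[0]
    prec = N / sigma12**2 + 1.0 / chi**2
    mean = (u.sum(axis=0) / sigma12**2) / prec
    mu = rng.normal(mean, 1.0 / np.sqrt(prec))
    mu[~z] = rng.normal(0.0, chi, size=int((~z).sum()))
    return mu


def _draw_mu_collapsed(Upsilon, S12, z12, sigma12, chi, rng):
    """Group means of one column with the strengths integrated out.

    Together with a subsequent ``u | mu`` draw this is an exact joint draw
    of ``(mu, u)`` given the spike pattern -- required for validity after
    the collapsed MH step on ``z``.
    """
    z = np.asarray(z12).astype(bool)
    mu = rng.normal(0.0, chi, size=z.size)
    terms = _ColTerms(np.asarray(Upsilon, float), np.atleast_2d(np.asarray(S12, float)), z,
                      np.asarray(sigma12, float) * np.ones(z.size), chi)
    if terms.k:
        mean = np.linalg.solve(terms.A, terms.b)
        mu[terms.idx] = mean + np.linalg.solve(terms.La.T, rng.standard_normal(terms.k))
    return mu


def _hier_column(Ups, S12, z12, sigma12, chi, a, sample_z, rng):
    """One column's joint draw: (optional z flip, mu | z, u | mu, z).

    Shares every factorisation between the MH evidence and the subsequent
    conditional draws.  ``chi=None`` selects the central fixed slab with no
    group-mean layer.
    """
    q = z12.size
    N = S12.shape[0]
    terms = _ColTerms(Ups, S12, z12, sigma12, chi)
    if sample_z:
        i = int(rng.integers(0, q))
        adding = z12[i] == 0
        if adding or a < 1.0:
            z_prop = z12.copy()
            z_prop[i] = 1 - z_prop[i]
            prop = _ColTerms(Ups, S12, z_prop, sigma12, chi)
            log_prior = math.log(a) - math.log1p(-a) if a < 1.0 else math.inf
            log_ratio = prop.logE - terms.logE + (log_prior if adding else -log_prior)
            if log_ratio >= 0 or math.log(rng.random()) < log_ratio:
                z12, terms = z_prop, prop
    u = np.zeros((N, q))
    mu12 = rng.normal(0.0, chi, size=q) if chi is not None else np.zeros(q)
    if terms.k:
        idx = terms.idx
        if chi is not None:
            mu_in = np.linalg.solve(terms.A, terms.b)
            mu_in = mu_in + np.linalg.solve(terms.La.T, rng.standard_normal(terms.k))
            mu12[idx] = mu_in
            b_s = -S12[:, idx] + terms.d_inv * mu_in
            mean = np.einsum("sij,sj->si", terms.Qinv, b_s)
        else:
            mean = terms.Qinv_c
        noise = np.einsum("sij,sj->si", terms.L, rng.standard_normal((N, terms.k)))
        u[:, idx] = mean + noise
    return z12, mu12, u


def update_sigma(sigma, omega_pairs, mu, z, constants: HyperConstants, rng, step):
    """Random-walk MH on ``log sigma_ij`` for every pair at once.

    ``sigma`` is the current chain state per unordered pair (the random walk
    needs it); ``omega_pairs`` is ``(N, E)`` -- subject strengths per pair.
    Included pairs target (log-normal prior) x (Gaussian slab likelihood)
    with a Gaussian proposal of scale ``step`` on ``log sigma``; excluded
    pairs refresh from the prior.  Returns ``(sigma, accepted_fraction)``
    where the fraction is over included pairs (NaN if none).
    """
    omega = np.atleast_2d(np.asarray(omega_pairs, float))
    mu = np.asarray(mu, float)
    z = np.asarray(z).astype(bool)
    sigma = np.asarray(sigma, float).copy()
    N, E = omega.shape
    lm, s2 = math.log(constants.m_sigma), constants.s_sigma**2
    ss = ((omega - mu) ** 2).sum(axis=0)

    n_excl = int((~z).sum())
    if n_excl:
        sigma[~z] = np.exp(rng.normal(lm, constants.s_sigma, size=n_excl))
    if not z.any():
        return sigma, float("nan")

    x = np.log(sigma[z])
    x_prop = x + step * rng.standard_normal(x.size)

    def logtarget(x_):
        return -0.5 * (x_ - lm) ** 2 / s2 - N * x_ - 0.5 * np.exp(-2.0 * x_) * ss[z]

    log_alpha = logtarget(x_prop) - logtarget(x)
    accept = np.log(rng.random(x.size)) < log_alpha
    x[accept] = x_prop[accept]
    sigma[z] = np.exp(x)
    return sigma, float(accept.mean())


def update_chi(mu_pairs, xi: float, A: float, rng: np.random.Generator):
    """Gibbs update of the global shrinkage scale via the half-Cauchy expansion.

    ``chi^2 | xi, mu ~ Inv-Gamma((E+1)/2, 1/xi + sum(mu^2)/2)`` and
    ``xi | chi^2 ~ Inv-Gamma(1, 1/A^2 + 1/chi^2)``; alternating the two with
    ``mu`` refreshed from its prior marginalises ``chi`` back to ``C+(0, A)``.
    """
    mu = np.asarray(mu_pairs, float).ravel()
    E = mu.size
    chi2 = 1.0 / rng.gamma((E + 1) / 2.0, 1.0 / (1.0 / xi + 0.5 * float(mu @ mu)))
    xi = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A**2 + 1.0 / chi2))
    return math.sqrt(chi2), xi


def update_a(Z, constants: HyperConstants, rng: np.random.Generator) -> float:
    """Beta-Bernoulli conjugate draw of the edge-inclusion probability."""
    Z = np.asarray(Z)
    iu = np.triu_indices(Z.shape[0], k=1)
    e_on = int(Z[iu].sum())
    e_off = len(iu[0]) - e_on
    return float(rng.beta(constants.a_pi + e_on, constants.b_pi + e_off))


def update_lambda(diagonals, constants: HyperConstants, rng: np.random.Generator):
    """Conjugate Gamma draw of the per-subject diagonal rate.

    Neutral ``Ga(1/3, 0)`` hyperprior with ``Exp(omega_ii; lambda/2)``
    likelihood gives ``Gamma(1/3 + p, rate = sum_i omega_ii / 2)``.
    """
    d = np.atleast_2d(np.asarray(diagonals, float))
    if np.any(d <= 0):
        raise ValueError("precision diagonals must be positive")
    N, p = d.shape
    rate = d.sum(axis=1) / 2.0
    return rng.gamma(constants.gamma_shape + p, 1.0 / rate)


# ---------------------------------------------------------------------------
# Sweep engine
# ---------------------------------------------------------------------------

@dataclass
class _State:
    """Mutable chain state for the hierarchical models."""

    Omega: np.ndarray  # (N, p, p)
    Sigma: np.ndarray  # (N, p, p): running inverses, refreshed periodically
    mu: np.ndarray  # (p, p)
    sigma: np.ndarray  # (p, p)
    Z: np.ndarray  # (p, p) int
    chi: float
    xi: float
    a: float
    lam: np.ndarray  # (N,)
    step_logsigma: float
    # per-subject latents for the non-hierarchical variants
    tau: np.ndarray | None = None  # bayesian_glasso: (N, p, p)
    Zs: np.ndarray | None = None  # ssvs: (N, p, p)


def _init_state(S, n_s, config: SamplerConfig) -> _State:
    N, p, _ = S.shape
    Omega = np.empty_like(S)
    for s in range(N):
        Sigma = S[s] / n_s[s]
        Omega[s] = np.linalg.inv(Sigma + config.tikhonov_init * np.eye(p))
        Omega[s] = (Omega[s] + Omega[s].T) / 2.0
    pc = np.mean([partial_correlation(om, check_pd=False) for om in Omega], axis=0)
    if config.z_init is not None:
        Z = np.asarray(config.z_init).astype(int)
    elif config.model in ("weak", "bayesian_glasso", "ssvs"):
        Z = np.ones((p, p), int)
    else:
        Z = (np.abs(pc) > config.z_threshold).astype(int)
    np.fill_diagonal(Z, 0)
    mu = Omega.mean(axis=0)
    np.fill_diagonal(mu, 0.0)
    if config.model == "single_subject":
        mu = np.zeros((p, p))
    c = config.constants
    sigma = np.full((p, p), c.m_sigma)
    if config.model == "single_subject":
        sigma = np.full((p, p), config.single_slab_sd)
    lam = 2.0 * p / np.einsum("sii->s", Omega)
    a = 1.0 if config.model in ("weak", "bayesian_glasso") else 0.5
    if config.model == "ssvs":
        a = config.ssvs_a
    state = _State(
        Omega=Omega, Sigma=np.linalg.inv(Omega), mu=mu, sigma=sigma, Z=Z,
        chi=c.A, xi=1.0 / c.A**2, a=a, lam=lam, step_logsigma=config.mh_step_logsigma,
    )
    if config.model == "bayesian_glasso":
        state.tau = np.abs(Omega) + 0.1
    if config.model == "ssvs":
        state.Zs = np.tile(Z, (N, 1, 1))
    return state


def _column_diag_rate(config: SamplerConfig, lam: np.ndarray) -> np.ndarray:
    if config.model == "bayesian_glasso":
        return np.full_like(lam, config.bglasso_lambda)
    if config.model == "ssvs":
        return np.ones_like(lam)
    return lam


def gibbs_sweep(state: _State, S, n_s, config: SamplerConfig, rng: np.random.Generator) -> _State:
    """One full sweep: every column in random order, then the global layers.

    All precision matrices remain positive definite throughout (Schur
    guarantee: the column diagonal is rebuilt as ``nu + u' Omega11^{-1} u``
    with ``nu > 0``).
    """
    N, p, _ = S.shape
    model = config.model
    hier = model in ("strong", "weak")
    sample_z = config.sample_z
    if sample_z is None:
        sample_z = model in ("strong", "single_subject")
    lam_eff = _column_diag_rate(config, state.lam)
    arange_p = np.arange(p)

    subj_ix = np.arange(N)[:, None, None]

    for j in rng.permutation(p):
        keep = np.flatnonzero(arange_p != j)
        kr, kc = keep[None, :, None], keep[None, None, :]
        # Omega11^{-1} from the maintained inverse: Sigma11 - s12 s12'/s22
        sig12 = state.Sigma[:, keep, j]
        sig22 = state.Sigma[:, j, j]
        Om11_inv = state.Sigma[subj_ix, kr, kc] - (
            sig12[:, :, None] * sig12[:, None, :]
        ) / sig22[:, None, None]
        Om11_inv = (Om11_inv + np.swapaxes(Om11_inv, -1, -2)) / 2.0
        S12 = S[:, keep, j]
        S22 = S[:, j, j]
        Ups = compute_upsilon(S22, lam_eff, Om11_inv)
        sigma12 = state.sigma[keep, j]
        z12 = state.Z[keep, j]

        if model in ("strong", "weak", "single_subject"):
            chi_arg = state.chi if hier else None
            z12, mu12, u = _hier_column(Ups, S12, z12, sigma12, chi_arg, state.a, sample_z, rng)
            if sample_z:
                state.Z[keep, j] = z12
                state.Z[j, keep] = z12
            if hier:
                state.mu[keep, j] = mu12
                state.mu[j, keep] = mu12
        elif model == "bayesian_glasso":
            tau12 = state.tau[:, keep, j]
            u = _draw_strengths_subjectwise(Ups, S12, tau12, rng)
        else:  # ssvs
            zs12 = state.Zs[:, keep, j]
            v = np.where(zs12 == 1, config.ssvs_v1, config.ssvs_v0)
            u = _draw_strengths_subjectwise(Ups, S12, v**2, rng)

        nu = draw_nu(n_s, S22, lam_eff, rng)
        w = np.einsum("sij,sj->si", Om11_inv, u)
        state.Omega[:, keep, j] = u
        state.Omega[:, j, keep] = u
        state.Omega[:, j, j] = nu + np.einsum("si,si->s", u, w)
        # rank-one update of the maintained inverse (Schur blocks in closed form)
        state.Sigma[subj_ix, kr, kc] = Om11_inv + (w[:, :, None] * w[:, None, :]) / nu[:, None, None]
        state.Sigma[:, keep, j] = -w / nu[:, None]
        state.Sigma[:, j, keep] = -w / nu[:, None]
        state.Sigma[:, j, j] = 1.0 / nu

    # global layers
    iu = np.triu_indices(p, k=1)
    if hier:
        om_pairs = state.Omega[:, iu[0], iu[1]]
        sig_pairs, acc = update_sigma(
            state.sigma[iu], om_pairs, state.mu[iu], state.Z[iu],
            config.constants, rng, state.step_logsigma,
        )
        state.sigma[iu] = sig_pairs
        state.sigma.T[iu] = sig_pairs
        state._last_sigma_accept = acc  # type: ignore[attr-defined]
        state.chi, state.xi = update_chi(state.mu[iu], state.xi, config.constants.A, rng)
    if sample_z and model in ("strong", "single_subject"):
        state.a = update_a(state.Z, config.constants, rng)
    if model == "bayesian_glasso":
        om = state.Omega[:, iu[0], iu[1]]
        lamb = config.bglasso_lambda
        mu_ig = lamb / np.maximum(np.abs(om), 1e-12)
        eta = stats.invgauss.rvs(mu_ig / lamb**2, scale=lamb**2, random_state=rng)
        tau = 1.0 / eta
        state.tau[:, iu[0], iu[1]] = tau
        state.tau[:, iu[1], iu[0]] = tau
    if model == "ssvs":
        om = state.Omega[:, iu[0], iu[1]]
        a_ = config.ssvs_a
        logit = (
            math.log(a_ / (1 - a_))
            + stats.norm.logpdf(om, scale=config.ssvs_v1)
            - stats.norm.logpdf(om, scale=config.ssvs_v0)
        )
        prob = 1.0 / (1.0 + np.exp(-logit))
        zs = (rng.random(om.shape) < prob).astype(int)
        state.Zs[:, iu[0], iu[1]] = zs
        state.Zs[:, iu[1], iu[0]] = zs
    if model in ("strong", "weak", "single_subject"):
        diag = np.einsum("sii->si", state.Omega)
        state.lam = update_lambda(diag, config.constants, rng)
    return state


def _draw_strengths_subjectwise(Ups, S12, var12, rng):
    """Column strengths when each subject has its own elementwise slab variances."""
    N, q = S12.shape
    d_inv = 1.0 / var12  # (N, q)
    Q = Ups + d_inv[:, :, None] * np.eye(q)
    L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, -S12[..., None])[..., 0]
    noise = np.linalg.solve(np.swapaxes(L, -1, -2), rng.standard_normal((N, q, 1)))[..., 0]
    return mean + noise


# ---------------------------------------------------------------------------
# Posterior archive
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Stored MCMC output with posterior summaries.

    ``Omega`` holds thinned draws, shape ``(n_chains, n_stored, N, p, p)``.
    Posterior-mean partial correlations are accumulated over *every*
    post-warm-up sweep (not just stored ones): the summary is the mean of
    per-draw partial correlations, not the partial correlation of the mean.
    """

    model: str
    config: SamplerConfig
    Omega: np.ndarray
    Z: np.ndarray | None
    mu: np.ndarray | None
    sigma: np.ndarray | None
    chi: np.ndarray | None
    a: np.ndarray | None
    lam: np.ndarray | None
    loglik: np.ndarray
    pcorr_mean: np.ndarray  # (N, p, p) running mean over all kept sweeps
    edge_prob: np.ndarray | None  # (p, p) running mean of Z
    sigma_accept: float
    n_pd_checked: int
    n_pd_failed: int
    subject_map: list[int] | None = None

    @property
    def n_subjects(self) -> int:
        return self.Omega.shape[2]

    @property
    def p(self) -> int:
        return self.Omega.shape[-1]

    def subject_partial_corr_mean(self) -> np.ndarray:
        return self.pcorr_mean

    def group_partial_corr_mean(self) -> np.ndarray:
        return self.pcorr_mean.mean(axis=0)

    def edge_probabilities(self) -> np.ndarray:
        if self.edge_prob is None:
            raise ValueError(f"model {self.model!r} has no shared edge indicators")
        return self.edge_prob

    def credible_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Central credible interval of per-subject partial correlations."""
        draws = self.Omega.reshape(-1, *self.Omega.shape[2:])
        pcs = np.stack([[partial_correlation(om, check_pd=False) for om in d] for d in draws])
        lo = (1 - level) / 2
        return np.quantile(pcs, lo, axis=0), np.quantile(pcs, 1 - lo, axis=0)

    def diagnostics(self, n_edges: int = 5, seed: int = 0) -> dict:
        """Split-chain potential scale reduction on scalar summaries.

        Rhat above ~1.05 is a convergence warning, not a failure.
        """
        rng = np.random.default_rng(seed)
        out = {}
        scalars = {"loglik": self.loglik}
        if self.chi is not None:
            scalars["chi"] = self.chi
        if self.a is not None:
            scalars["a"] = self.a
        p = self.p
        iu = np.triu_indices(p, k=1)
        picks = rng.choice(len(iu[0]), size=min(n_edges, len(iu[0])), replace=False)
        for e in picks:
            i, j = iu[0][e], iu[1][e]
            scalars[f"omega[0,{i},{j}]"] = self.Omega[:, :, 0, i, j]
        for name, x in scalars.items():
            out[f"rhat_{name}"] = _split_rhat(np.asarray(x))
        out["sigma_accept"] = self.sigma_accept
        return out

    def save(self, path) -> None:
        """Write the archive: ``<path>.npz`` (arrays) + ``<path>.json`` (index)."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays = {
            k: v for k, v in self.__dict__.items()
            if isinstance(v, np.ndarray)
        }
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        index = {
            "model": self.model,
            "arrays": {k: list(v.shape) for k, v in arrays.items()},
            "sigma_accept": self.sigma_accept,
            "n_pd_checked": self.n_pd_checked,
            "n_pd_failed": self.n_pd_failed,
            "seed": self.config.seed,
            "n_samples": self.config.n_samples,
            "n_warmup": self.config.n_warmup,
            "thin": self.config.thin,
        }
        path.with_suffix(".json").write_text(json.dumps(index, indent=2))

    @classmethod
    def load(cls, path, config: SamplerConfig | None = None) -> "PosteriorDraws":
        import json
        from pathlib import Path

        path = Path(path)
        data = dict(np.load(path.with_suffix(".npz")))
        index = json.loads(path.with_suffix(".json").read_text())
        cfg = config or SamplerConfig(model=index["model"])
        kw = {k: data.get(k) for k in (
            "Omega", "Z", "mu", "sigma", "chi", "a", "lam", "loglik",
            "pcorr_mean", "edge_prob",
        )}
        return cls(
            model=index["model"], config=cfg, sigma_accept=index["sigma_accept"],
            n_pd_checked=index["n_pd_checked"], n_pd_failed=index["n_pd_failed"], **kw,
        )


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction with each chain split in half."""
    x = np.atleast_2d(x)
    halves = []
    for c in x:
        m = len(c) // 2
        halves += [c[:m], c[m : 2 * m]]
    h = np.asarray(halves, dtype=float)
    m, n = h.shape
    if n < 2:
        return float("nan")
    means = h.mean(axis=1)
    W = h.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_sampler(panel: TimeSeriesPanel, config: SamplerConfig) -> PosteriorDraws:
    """Run warm-up plus sampling sweeps for every chain and summarise.

    The panel is temporally demeaned and variance-scaled (unless
    ``config.standardise`` is off -- the priors assume variance-scaled
    data).  The ``single_subject`` model concatenates all subjects first.
    """
    for y in panel.subjects:
        if not np.all(np.isfinite(y)):
            raise ValueError("panel contains non-finite values")
    if config.model == "single_subject" and panel.n_subjects > 1:
        panel = panel.concatenated()
    if config.standardise:
        panel = standardise_panel(panel, unit_variance=True)
    ips = inner_products(panel)
    S = np.asarray(ips.S)
    n_s = np.asarray(ips.n_s, dtype=float)
    N, p, _ = S.shape
    if p > int(n_s.sum()):
        import warnings

        warnings.warn("more nodes than total samples; posterior will be prior-dominated")

    hier = config.model in ("strong", "weak")
    keep_z = config.model in ("strong", "single_subject")
    n_store = max(config.n_samples // config.thin, 1)

    all_Omega = np.empty((config.n_chains, n_store, N, p, p))
    all_Z = np.empty((config.n_chains, n_store, p, p), dtype=np.int8) if keep_z else None
    all_mu = np.empty((config.n_chains, n_store, p, p)) if hier else None
    all_sigma = np.empty((config.n_chains, n_store, p, p)) if hier else None
    all_chi = np.empty((config.n_chains, n_store)) if hier else None
    all_a = np.empty((config.n_chains, n_store)) if keep_z else None
    all_lam = np.empty((config.n_chains, n_store, N))
    all_ll = np.empty((config.n_chains, n_store))

    pcorr_sum = np.zeros((N, p, p))
    edge_sum = np.zeros((p, p)) if keep_z else None
    n_kept = 0
    n_pd_checked = 0
    n_pd_failed = 0
    acc_history: list[float] = []

    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        state = _init_state(S, n_s, config)
        stored = 0
        for t in range(config.n_warmup + config.n_samples):
            state = gibbs_sweep(state, S, n_s, config, rng)
            if t % 50 == 49:  # bound drift of the maintained inverses
                state.Sigma = np.linalg.inv(state.Omega)
            warm = t < config.n_warmup
            acc = getattr(state, "_last_sigma_accept", float("nan"))
            if warm and hier and np.isfinite(acc):
                # Robbins-Monro adaptation toward 40% acceptance, frozen after warm-up
                state.step_logsigma = float(
                    np.exp(np.log(state.step_logsigma) + (acc - 0.4) / (1 + t) ** 0.6)
                )
            if not warm and hier and np.isfinite(acc):
                acc_history.append(acc)
            if config.check_pd_every and t % config.check_pd_every == 0:
                for om in state.Omega:
                    n_pd_checked += 1
                    if not is_positive_definite(om):
                        n_pd_failed += 1
            if warm:
                continue
            # summaries over every retained sweep
            d = np.sqrt(np.einsum("sii->si", state.Omega))
            pc = -state.Omega / (d[:, :, None] * d[:, None, :])
            pc[:, np.arange(p), np.arange(p)] = 1.0
            pcorr_sum += pc
            if keep_z:
                edge_sum += state.Z
            n_kept += 1
            if (t - config.n_warmup) % config.thin == 0 and stored < n_store:
                all_Omega[chain, stored] = state.Omega
                if keep_z:
                    all_Z[chain, stored] = state.Z
                    all_a[chain, stored] = state.a
                if hier:
                    all_mu[chain, stored] = state.mu
                    all_sigma[chain, stored] = state.sigma
                    all_chi[chain, stored] = state.chi
                all_lam[chain, stored] = state.lam
                sign, logdet = np.linalg.slogdet(state.Omega)
                all_ll[chain, stored] = float(
                    np.sum(n_s / 2.0 * logdet)
                    - 0.5 * np.einsum("sij,sij->", S, state.Omega)
                )
                if not config.check_pd_every:
                    for om in state.Omega:
                        n_pd_checked += 1
                        if not is_positive_definite(om):
                            n_pd_failed += 1
                stored += 1

    draws = PosteriorDraws(
        model=config.model,
        config=config,
        Omega=all_Omega[:, :stored] if config.n_samples else all_Omega[:, :0],
        Z=all_Z[:, :stored] if keep_z else None,
        mu=all_mu[:, :stored] if hier else None,
        sigma=all_sigma[:, :stored] if hier else None,
        chi=all_chi[:, :stored] if hier else None,
        a=all_a[:, :stored] if keep_z else None,
        lam=all_lam[:, :stored],
        loglik=all_ll[:, :stored],
        pcorr_mean=pcorr_sum / max(n_kept, 1),
        edge_prob=(edge_sum / max(n_kept, 1)) if keep_z else None,
        sigma_accept=float(np.mean(acc_history)) if acc_history else float("nan"),
        n_pd_checked=n_pd_checked,
        n_pd_failed=n_pd_failed,
    )
    if n_pd_failed:
        raise RuntimeError(
            f"{n_pd_failed} stored precision draws failed the PD check -- "
            "this should be unreachable; state archived in the returned draws"
        )
    return draws
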