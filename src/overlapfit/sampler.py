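"""Metropolis-Hastings-within-Gibbs sampler for one candidate model.

Analytic Gibbs updates exist for the abundances ``H_q`` (truncated-normal
full conditionals: the mean structure is linear in each ``H_q``), the noise
precision ``sigma^-2``, the abundance-prior precision ``tau`` and the
(truncated) spacing-prior precision ``tau_s``.  All remaining parameters —
masses ``M_q``, spacing ``S``, peak width ``sigma_s``, skewness ``kappa``,
the odds ``(1-p_1)/p_1`` and the tail reference ratios ``R_{l,q}`` — move by
Gaussian random-walk Metropolis steps (on the log scale for the positive
ratio parameters, with the prior expressed in the sampled coordinate so no
separate Jacobian is needed).

``R_2`` is never sampled directly: after any odds or tail-ratio move it is
recomputed from the virtual constraint ``R_2 = odds - sum_{l>=3} R_l`` and
proposals implying ``R_2 <= 0`` (or violating the mass ordering
``M_1 < ... < M_Q`` in unconstrained mode, or a box constraint) are
rejected.

Implementation note: the chain caches, per peptide, the matrix of peak bin
masses and the resulting basis column ``b_q = sum_l R_{l,q} psi_l``, so a
ratio move is a rank-one recombination and only mass/shape moves pay for
fresh CDF evaluations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammainc, gammaincinv, ndtr, ndtri

from . import model_core
from .isotopic_prior import (
    MonoisotopicFractionModel,
    PolynomialRatioModel,
    odds_prior,
    prior_median_reference_ratios,
    reference_ratio_prior,
)
from .model_core import (
    ModelConfig,
    PeptideState,
    SharedState,
    SpectrumWindow,
    normalize_mass_priors,
)
from .peak_shape import ShapeParams, bin_masses

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "Chain",
    "run_chain",
    "initialize_state",
    "greedy_mass_estimates",
    "compute_dic",
    "compute_bic",
]

_LOG_2PI = math.log(2.0 * math.pi)

#: Default random-walk proposal SDs per parameter family.
DEFAULT_PROPOSAL_SCALES = {
    "M": 0.005,        # Da
    "S": 0.0005,       # Da
    "sigma_s": 0.002,  # Da
    "kappa": 0.02,
    "log_odds": 0.05,
    "log_ratio": 0.05,
}


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.

    ``update_blocks`` restricts the sweep to a subset of named blocks
    (e.g. ``{"H"}`` or ``{"M1"}``) — a diagnostic hook used to compare a
    single full conditional against brute-force integration.  Robbins-Monro
    scale adaptation toward ``target_accept`` runs during burn-in only, so
    the post-burn-in kernel is a fixed Markov kernel.
    """

    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    proposal_scales: dict = field(default_factory=lambda: dict(DEFAULT_PROPOSAL_SCALES))
    adapt: bool = True
    target_accept: float = 0.35
    update_blocks: frozenset | None = None
    reverse_blocks: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        for key, val in self.proposal_scales.items():
            if val <= 0:
                raise ValueError(f"proposal scale {key} must be positive")


@dataclass
class ChainResult:
    """Retained draws plus summaries and information criteria for one chain."""

    draws: pd.DataFrame
    acceptance_rates: dict
    summaries: pd.DataFrame
    dic: float
    bic: float
    p_d: float
    mean_deviance: float
    deviance_at_mean: float
    n_params: int
    n_obs: int
    seed: int

    def export_chain_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            name: {k: float(v) for k, v in row.items()}
            for name, row in self.summaries.iterrows()
        }


def compute_dic(deviances: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC and effective parameter count from retained deviances.

    ``DIC = Dbar + p_D`` with ``p_D = Dbar - D(posterior mean)``.  ``p_D``
    can come out negative for poorly identified models; it is returned as-is
    (a warning is emitted by the chain in that case).
    """
    mean_dev = float(np.mean(deviances))
    p_d = mean_dev - deviance_at_mean
    return mean_dev + p_d, p_d


def compute_bic(deviance_at_mean: float, n_params: int, n_obs: int) -> float:
    """BIC at the posterior-mean plug-in: ``D(theta_hat) + k log N``."""
    return deviance_at_mean + n_params * math.log(n_obs)


# ---------------------------------------------------------------------------
# truncated samplers


def _sample_trunc_normal_lower(rng, mu: float, sd: float, lower: float = 0.0) -> float:
    """Draw from N(mu, sd^2) truncated to [lower, inf) via inverse CDF.

    Falls back to an exponential rejection step (Robert 1995) deep in the
    tail, where the inverse CDF loses accuracy.
    """
    a = (lower - mu) / sd
    if a < 6.0:
        fa = ndtr(a)
        p = fa + rng.uniform() * (1.0 - fa)
        p = min(p, np.nextafter(1.0, 0.0))
        return mu + sd * float(ndtri(p))
    lam = 0.5 * (a + math.sqrt(a * a + 4.0))
    for _ in range(1000):
        z = a - math.log(rng.uniform()) / lam
        if math.log(rng.uniform()) <= -0.5 * (z - lam) ** 2:
            return mu + sd * z
    return mu + sd * a  # pathological; pin at the bound


def _sample_trunc_gamma(rng, shape: float, rate: float, lower: float) -> float:
    """Draw from Gamma(shape, rate) truncated to [lower, inf) via inverse CDF."""
    flo = float(gammainc(shape, rate * lower))
    if flo >= 1.0 - 1e-14:
        return lower
    u = flo + rng.uniform() * (1.0 - flo)
    u = min(u, np.nextafter(1.0, 0.0))
    return float(gammaincinv(shape, u)) / rate


# ---------------------------------------------------------------------------
# initialization


def greedy_mass_estimates(
    window: SpectrumWindow,
    Q: int,
    L: int,
    ratio_model: PolynomialRatioModel | None = None,
    S: float = 1.0015,
    sigma_s: float = 0.075,
    step: float = 0.02,
    refine_halfwidth: float = 0.4,
    n_passes: int = 2,
) -> np.ndarray:
    """Preliminary monoisotopic-mass estimates by greedy envelope matching.

    Correlates the residual spectrum with a prior-median isotope-envelope
    template over a coarse grid of candidate monoisotopic positions,
    subtracting each matched envelope in turn (matching pursuit), then
    refines the Q positions jointly by coordinate descent with non-negative
    least-squares abundances.  Returns the positions in ascending order.
    """
    x, y = window.x, window.y
    m_lo = float(x[0])
    m_hi = max(float(x[-1]) - (L - 1) * S, m_lo + step)
    positions = np.arange(m_lo, m_hi + step / 2.0, step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rvec = prior_median_reference_ratios(0.5 * (m_lo + float(x[-1])), L, ratio_model)
    shape = ShapeParams("normal", sigma_s)
    centers = positions[:, None] + S * np.arange(L)[None, :]
    psi = bin_masses(window.edges, centers.ravel(), shape)
    psi = psi.reshape(positions.size, L, x.size)
    T = np.einsum("l,plj->pj", rvec, psi)
    tn = np.einsum("pj,pj->p", T, T)
    valid = tn > 1e-300
    resid = y.astype(float).copy()
    chosen: list[int] = []
    for _ in range(Q):
        scores = T @ resid
        gains = np.where(valid & (scores > 0), scores * scores / np.where(valid, tn, 1.0), -np.inf)
        if chosen:
            gains[chosen] = -np.inf
        if not np.any(np.isfinite(gains)):
            gains = np.where(valid, -np.abs(scores), -np.inf)  # flat residual: least-bad slot
        idx = int(np.argmax(gains))
        h = max(float(scores[idx] / tn[idx]), 0.0) if valid[idx] else 0.0
        resid -= h * T[idx]
        chosen.append(idx)

    masses = np.sort(positions[chosen])
    if Q == 1 or not np.any(valid):
        return masses

    def _snap(ms: np.ndarray) -> np.ndarray:
        return np.clip(np.round((ms - positions[0]) / step).astype(int), 0, positions.size - 1)

    for _ in range(n_passes):
        for q in range(Q):
            cand = np.nonzero(np.abs(positions - masses[q]) <= refine_halfwidth)[0]
            best_rnorm, best_pos = np.inf, masses[q]
            others = np.delete(masses, q)
            for i in cand:
                if others.size and np.min(np.abs(others - positions[i])) < 0.75 * step:
                    continue
                trial = masses.copy()
                trial[q] = positions[i]
                A = T[_snap(trial)].T
                try:
                    _, rnorm = nnls(A, y)
                except Exception:  # pragma: no cover - singular design
                    continue
                if rnorm < best_rnorm:
                    best_rnorm, best_pos = rnorm, positions[i]
            masses[q] = best_pos
        masses = np.sort(masses)
    return masses


def initialize_state(
    window: SpectrumWindow,
    config: ModelConfig,
    mass_prior=None,
    ratio_model: PolynomialRatioModel | None = None,
    prelim_masses: np.ndarray | None = None,
) -> dict:
    """Deterministic starting state for a chain.

    Masses from :func:`greedy_mass_estimates` (or ``prelim_masses`` if the
    caller already ran it); abundances by non-negative least squares given
    those masses; ratios at the prior medians; ``S = 1.0015``,
    ``sigma_s = 0.075``, ``kappa = 0.85``; noise variance from the NNLS
    residuals.
    """
    Q, L = config.Q, config.L
    if prelim_masses is not None:
        prelim = np.sort(np.asarray(prelim_masses, dtype=float))
        if prelim.size != Q:
            raise ValueError(f"expected {Q} preliminary masses, got {prelim.size}")
    else:
        prelim = greedy_mass_estimates(window, Q, L, ratio_model=ratio_model)
    if config.constraint is not None and Q > 1:
        k = config.constraint.offset_multiple
        m1 = float(prelim[0])
        prelim = m1 + 1.0015 * k * np.arange(Q)

    if mass_prior is not None:
        ref_masses = [eta for eta, _ in normalize_mass_priors(mass_prior, Q)]
    else:
        ref_masses = list(prelim)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = np.vstack(
            [prior_median_reference_ratios(ref_masses[q], L, ratio_model) for q in range(Q)]
        )
    shape = ShapeParams("normal", 0.075)
    basis = np.empty((Q, window.n))
    for q in range(Q):
        centers = prelim[q] + 1.0015 * np.arange(L)
        basis[q] = R[q] @ bin_masses(window.edges, centers, shape)
    H, _ = nnls(basis.T, window.y)
    resid = window.y - H @ basis
    ymax = float(np.max(np.abs(window.y))) if window.n else 1.0
    sigma2 = max(float(resid @ resid) / window.n, (1e-6 * ymax) ** 2, 1e-12)
    odds = R[:, 1:].sum(axis=1)
    return {
        "M": np.asarray(prelim, dtype=float),
        "H": np.asarray(H, dtype=float),
        "S": 1.0015,
        "sigma_s": 0.075,
        "kappa": 0.85,
        "sigma2": sigma2,
        "tau": Q / (float(H @ H) + 1e-12),
        "tau_s": 3200.0,
        "odds": odds,
        "Rtail": R[:, 2:].copy(),
        "R2": R[:, 1].copy(),
    }


# ---------------------------------------------------------------------------
# the chain engine


class Chain:
    """One MCMC chain for a fixed candidate mass prior.

    Parameters mirror :func:`run_chain`; the heavy lifting happens in
    :meth:`run`, while the individual ``update_*``/``mh_*`` methods are
    public so single full conditionals can be exercised in isolation.
    """

    def __init__(
        self,
        window: SpectrumWindow,
        config: ModelConfig,
        mass_prior,
        sampler_config: SamplerConfig | None = None,
        init: dict | None = None,
        ratio_model: PolynomialRatioModel | None = None,
        fraction_model: MonoisotopicFractionModel | None = None,
    ) -> None:
        self.window = window
        self.config = config
        self.scfg = sampler_config or SamplerConfig()
        self.rng = np.random.default_rng(self.scfg.seed)
        self.hp = config.hyperparams
        self.Q, self.L = config.Q, config.L
        self.N = window.n
        self.y = window.y
        self.edges = window.edges
        self.is_alaplace = config.shape_kind == "asymmetric_laplace"
        self._larange = np.arange(config.L)
        self.constrained = config.constraint is not None and self.Q > 1
        self.offset_k = config.constraint.offset_multiple if self.constrained else 0

        priors = normalize_mass_priors(mass_prior, self.Q)
        self.eta = np.array([p[0] for p in priors])
        self.sigma_m = np.array([p[1] for p in priors])

        # ratio-prior hyperparameters, evaluated once at the prior centers
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.odds_mu = np.empty(self.Q)
            self.odds_var = np.empty(self.Q)
            self.ratio_mu = np.empty((self.Q, self.L - 2))
            self.ratio_var = np.empty((self.Q, self.L - 2))
            for q in range(self.Q):
                spec = odds_prior(self.eta[q], fraction_model)
                self.odds_mu[q], self.odds_var[q] = spec.mu, spec.sigma_sq
                for l in range(3, self.L + 1):
                    rp = reference_ratio_prior(self.eta[q], l, ratio_model)
                    self.ratio_mu[q, l - 3] = rp.mu
                    self.ratio_var[q, l - 3] = rp.sigma_sq

        if init is None:
            init = initialize_state(window, config, mass_prior, ratio_model)
        self._load_state(init)
        self._setup_blocks()
        self.refresh()

    # -- state management ---------------------------------------------------

    def _load_state(self, init: dict) -> None:
        self.M = np.array(init["M"], dtype=float)
        self.H = np.array(init["H"], dtype=float)
        self.S = float(init["S"])
        self.sigma_s = float(init["sigma_s"])
        self.kappa = float(init.get("kappa", 0.85))
        self.sigma2 = float(init["sigma2"])
        self.tau = float(init["tau"])
        self.tau_s = float(init["tau_s"])
        self.odds = np.array(init["odds"], dtype=float)
        self.Rfull = np.ones((self.Q, self.L))
        self.Rfull[:, 1] = np.array(init["R2"], dtype=float)
        if self.L > 2:
            self.Rfull[:, 2:] = np.array(init["Rtail"], dtype=float)
        if self.constrained:
            self.M = self.M[0] + self.offset_k * self.S * np.arange(self.Q)

    def _setup_blocks(self) -> None:
        scales = self.scfg.proposal_scales
        blocks: list[tuple[str, str, tuple]] = []  # (name, category, args)
        blocks.append(("H", "H", ()))
        blocks.append(("sigma2", "sigma2", ()))
        blocks.append(("tau", "tau", ()))
        blocks.append(("tau_s", "tau_s", ()))
        blocks.append(("S", "S", ()))
        blocks.append(("sigma_s", "sigma_s", ()))
        if self.is_alaplace:
            blocks.append(("kappa", "kappa", ()))
        n_free_masses = 1 if self.constrained else self.Q
        for q in range(n_free_masses):
            blocks.append((f"M{q + 1}", "M", (q,)))
        for q in range(self.Q):
            blocks.append((f"odds{q + 1}", "odds", (q,)))
        for q in range(self.Q):
            for l in range(3, self.L + 1):
                blocks.append((f"R{l}_{q + 1}", "R", (q, l)))
        keep = self.scfg.update_blocks
        if keep is not None:
            blocks = [b for b in blocks if b[0] in keep or b[1] in keep]
        if self.scfg.reverse_blocks:
            blocks = blocks[::-1]
        self.blocks = blocks
        self.log_scale = {}
        for name, cat, _ in blocks:
            if cat == "M":
                self.log_scale[name] = math.log(scales["M"])
            elif cat in ("S", "sigma_s", "kappa"):
                self.log_scale[name] = math.log(scales[cat])
            elif cat == "odds":
                self.log_scale[name] = math.log(scales["log_odds"])
            elif cat == "R":
                self.log_scale[name] = math.log(scales["log_ratio"])
        self._accepts = {n: 0 for n in self.log_scale}
        self._proposals = {n: 0 for n in self.log_scale}

    def _psi_one(self, mass: float, S=None, sigma_s=None, kappa=None) -> np.ndarray:
        """Peak bin masses for one peptide.

        For the normal shape the CDF is evaluated only within +/- 10 sigma_s
        of each peak (the omitted tail mass is ~1e-23); bins outside are
        exactly the CDF-difference of two numerically equal values, i.e. 0.
        """
        S = self.S if S is None else S
        sigma_s = self.sigma_s if sigma_s is None else sigma_s
        centers = mass + S * self._larange
        if self.is_alaplace:
            kappa = self.kappa if kappa is None else kappa
            shape = ShapeParams("asymmetric_laplace", sigma_s, kappa)
            return bin_masses(self.edges, centers, shape)
        edges = self.edges
        n_edges = self.N + 1
        halfw = 10.0 * sigma_s
        a = np.searchsorted(edges, centers - halfw)
        b = np.searchsorted(edges, centers + halfw)
        a = np.maximum(a - 1, 0)
        b = np.minimum(b + 1, n_edges)
        k = int(np.max(b - a))
        if k >= n_edges - 1 or k * self.L > 2 * n_edges:
            cdf = ndtr((edges[None, :] - centers[:, None]) / sigma_s)
            return cdf[:, 1:] - cdf[:, :-1]
        out = np.zeros((self.L, self.N))
        if k < 2:
            return out
        a = np.minimum(a, n_edges - k)
        idx = a[:, None] + np.arange(k)[None, :]
        seg = ndtr((edges[idx] - centers[:, None]) / sigma_s)
        dseg = seg[:, 1:] - seg[:, :-1]
        for l in range(self.L):
            out[l, a[l] : a[l] + k - 1] = dseg[l]
        return out

    def refresh(self) -> None:
        """Recompute all cached quantities from the raw parameter state."""
        self.psi = np.empty((self.Q, self.L, self.N))
        for q in range(self.Q):
            self.psi[q] = self._psi_one(self.M[q])
        self.b = np.einsum("ql,qlj->qj", self.Rfull, self.psi)
        self.mean = self.H @ self.b
        d = self.y - self.mean
        self.ssr = float(d @ d)

    def log_likelihood(self) -> float:
        return -0.5 * self.N * (_LOG_2PI + math.log(self.sigma2)) - 0.5 * self.ssr / self.sigma2

    def current_state(self) -> tuple[list[PeptideState], SharedState]:
        """Export the raw state as model_core objects (for cross-checks)."""
        if self.is_alaplace:
            shape = ShapeParams("asymmetric_laplace", self.sigma_s, self.kappa)
        else:
            shape = ShapeParams("normal", self.sigma_s)
        shared = SharedState(
            S=self.S, sigma=math.sqrt(self.sigma2), shape=shape, tau=self.tau, tau_s=self.tau_s
        )
        peptides = [
            PeptideState(M=self.M[q], H=self.H[q], R=self.Rfull[q].copy(), odds=self.odds[q])
            for q in range(self.Q)
        ]
        return peptides, shared

    # -- Gibbs updates --------------------------------------------------------

    def update_H(self) -> None:
        """Draw each H_q from its truncated-normal full conditional."""
        for q in range(self.Q):
            bq = self.b[q]
            btb = float(bq @ bq)
            if btb < 1e-300:
                warnings.warn(f"all-zero basis for peptide {q + 1}; H update skipped")
                continue
            r = self.y - self.mean + self.H[q] * bq
            v = 1.0 / (btb / self.sigma2 + self.tau)
            mu = v * float(bq @ r) / self.sigma2
            h_new = _sample_trunc_normal_lower(self.rng, mu, math.sqrt(v), 0.0)
            self.mean = self.mean + (h_new - self.H[q]) * bq
            self.H[q] = h_new
        d = self.y - self.mean
        self.ssr = float(d @ d)

    def update_sigma2(self) -> None:
        """sigma^-2 ~ Gamma(alpha + N/2, beta + SSR/2)."""
        shape = self.hp.alpha + 0.5 * self.N
        rate = self.hp.beta + 0.5 * self.ssr
        self.sigma2 = rate / self.rng.gamma(shape)

    def update_tau(self) -> None:
        """tau ~ Gamma(alpha* + Q/2, beta* + sum H^2 / 2)."""
        shape = self.hp.alpha_star + 0.5 * self.Q
        rate = self.hp.beta_star + 0.5 * float(self.H @ self.H)
        self.tau = self.rng.gamma(shape) / rate

    def update_tau_s(self) -> None:
        """tau_s ~ Gamma(alpha** + 1/2, beta** + (S-1)^2/2) truncated at tau_s_min."""
        shape = self.hp.alpha_2star + 0.5
        rate = self.hp.beta_2star + 0.5 * (self.S - 1.0) ** 2
        self.tau_s = _sample_trunc_gamma(self.rng, shape, rate, self.hp.tau_s_min)

    # -- Metropolis-Hastings updates ------------------------------------------

    def _accept(self, name: str, log_ratio: float, it: int) -> bool:
        self._proposals[name] += 1
        if log_ratio >= 0.0:
            accepted = True
        else:
            accepted = math.log(self.rng.uniform()) < log_ratio
        if accepted:
            self._accepts[name] += 1
        if self.scfg.adapt and it < self.scfg.burn_in:
            alpha = min(1.0, math.exp(min(log_ratio, 0.0)))
            gamma = min(0.25, (it + 1.0) ** -0.6)
            self.log_scale[name] = float(
                np.clip(self.log_scale[name] + gamma * (alpha - self.scfg.target_accept), -14.0, 5.0)
            )
        return accepted

    def _reject(self, name: str, it: int) -> None:
        self._accept(name, -math.inf, it)

    def mh_mass(self, q: int, it: int) -> None:
        name = f"M{q + 1}"
        delta = math.exp(self.log_scale[name]) * self.rng.standard_normal()
        if self.constrained:
            masses_new = self.M + delta
        else:
            m_new = self.M[q] + delta
            lo = self.M[q - 1] if q > 0 else -math.inf
            hi = self.M[q + 1] if q < self.Q - 1 else math.inf
            if not (lo < m_new < hi):
                self._reject(name, it)
                return
        lp_old = -0.5 * (self.M[q] - self.eta[q]) ** 2 / self.sigma_m[q] ** 2
        if self.constrained:
            psi_new = np.empty_like(self.psi)
            for qq in range(self.Q):
                psi_new[qq] = self._psi_one(masses_new[qq])
            b_new = np.einsum("ql,qlj->qj", self.Rfull, psi_new)
            mean_new = self.H @ b_new
            lp_new = -0.5 * (masses_new[0] - self.eta[0]) ** 2 / self.sigma_m[0] ** 2
        else:
            psi_q = self._psi_one(m_new)
            b_q = self.Rfull[q] @ psi_q
            mean_new = self.mean + self.H[q] * (b_q - self.b[q])
            lp_new = -0.5 * (m_new - self.eta[q]) ** 2 / self.sigma_m[q] ** 2
        d = self.y - mean_new
        ssr_new = float(d @ d)
        log_ratio = 0.5 * (self.ssr - ssr_new) / self.sigma2 + lp_new - lp_old
        if self._accept(name, log_ratio, it):
            if self.constrained:
                self.M, self.psi, self.b = masses_new, psi_new, b_new
            else:
                self.M[q] = m_new
                self.psi[q], self.b[q] = psi_q, b_q
            self.mean, self.ssr = mean_new, ssr_new

    def _mh_shared_shape(self, name: str, it: int) -> None:
        scale = math.exp(self.log_scale[name])
        delta = scale * self.rng.standard_normal()
        S_new, sig_new, kap_new = self.S, self.sigma_s, self.kappa
        lp_diff = 0.0
        if name == "S":
            S_new = self.S + delta
            if S_new <= 0:
                self._reject(name, it)
                return
            lp_diff = 0.5 * self.tau_s * ((self.S - 1.0) ** 2 - (S_new - 1.0) ** 2)
        elif name == "sigma_s":
            sig_new = self.sigma_s + delta
            if not (0.0 < sig_new <= self.hp.sigma_s_max):
                self._reject(name, it)
                return
            lp_diff = 0.5 * (self.sigma_s**2 - sig_new**2) / 1e6
        else:  # kappa
            kap_new = self.kappa + delta
            if not (self.hp.kappa_min <= kap_new <= self.hp.kappa_max):
                self._reject(name, it)
                return
        masses_new = self.M
        if name == "S" and self.constrained:
            masses_new = self.M[0] + self.offset_k * S_new * np.arange(self.Q)
        psi_new = np.empty_like(self.psi)
        for q in range(self.Q):
            psi_new[q] = self._psi_one(masses_new[q], S=S_new, sigma_s=sig_new, kappa=kap_new)
        b_new = np.einsum("ql,qlj->qj", self.Rfull, psi_new)
        mean_new = self.H @ b_new
        d = self.y - mean_new
        ssr_new = float(d @ d)
        log_ratio = 0.5 * (self.ssr - ssr_new) / self.sigma2 + lp_diff
        if self._accept(name, log_ratio, it):
            self.S, self.sigma_s, self.kappa = S_new, sig_new, kap_new
            self.M = masses_new
            self.psi, self.b, self.mean, self.ssr = psi_new, b_new, mean_new, ssr_new

    def mh_odds(self, q: int, it: int) -> None:
        name = f"odds{q + 1}"
        xi = math.log(self.odds[q])
        xi_new = xi + math.exp(self.log_scale[name]) * self.rng.standard_normal()
        odds_new = math.exp(xi_new)
        tail = float(self.Rfull[q, 2:].sum())
        r2_new = odds_new - tail
        if r2_new <= 0.0:
            self._reject(name, it)
            return
        lp_diff = 0.5 * ((xi - self.odds_mu[q]) ** 2 - (xi_new - self.odds_mu[q]) ** 2) / self.odds_var[q]
        b_q = self.b[q] + (r2_new - self.Rfull[q, 1]) * self.psi[q, 1]
        mean_new = self.mean + self.H[q] * (b_q - self.b[q])
        d = self.y - mean_new
        ssr_new = float(d @ d)
        log_ratio = 0.5 * (self.ssr - ssr_new) / self.sigma2 + lp_diff
        if self._accept(name, log_ratio, it):
            self.odds[q] = odds_new
            self.Rfull[q, 1] = r2_new
            self.b[q], self.mean, self.ssr = b_q, mean_new, ssr_new

    def mh_ratio(self, q: int, l: int, it: int) -> None:
        name = f"R{l}_{q + 1}"
        j = l - 1  # column in Rfull
        r_old = self.Rfull[q, j]
        xi = math.log(r_old)
        xi_new = xi + math.exp(self.log_scale[name]) * self.rng.standard_normal()
        r_new = math.exp(xi_new)
        r2_new = self.Rfull[q, 1] + (r_old - r_new)  # odds fixed: R2 absorbs the change
        if r2_new <= 0.0:
            self._reject(name, it)
            return
        mu, var = self.ratio_mu[q, l - 3], self.ratio_var[q, l - 3]
        lp_diff = 0.5 * ((xi - mu) ** 2 - (xi_new - mu) ** 2) / var
        b_q = (
            self.b[q]
            + (r2_new - self.Rfull[q, 1]) * self.psi[q, 1]
            + (r_new - r_old) * self.psi[q, j]
        )
        mean_new = self.mean + self.H[q] * (b_q - self.b[q])
        d = self.y - mean_new
        ssr_new = float(d @ d)
        log_ratio = 0.5 * (self.ssr - ssr_new) / self.sigma2 + lp_diff
        if self._accept(name, log_ratio, it):
            self.Rfull[q, j] = r_new
            self.Rfull[q, 1] = r2_new
            self.b[q], self.mean, self.ssr = b_q, mean_new, ssr_new

    # -- main loop ------------------------------------------------------------

    def _sweep(self, it: int) -> None:
        for name, cat, args in self.blocks:
            if cat == "H":
                self.update_H()
            elif cat == "sigma2":
                self.update_sigma2()
            elif cat == "tau":
                self.update_tau()
            elif cat == "tau_s":
                self.update_tau_s()
            elif cat in ("S", "sigma_s", "kappa"):
                self._mh_shared_shape(name, it)
            elif cat == "M":
                self.mh_mass(args[0], it)
            elif cat == "odds":
                self.mh_odds(args[0], it)
            else:
                self.mh_ratio(args[0], args[1], it)

    def column_names(self) -> list[str]:
        names = [f"M{q + 1}" for q in range(self.Q)]
        names += [f"H{q + 1}" for q in range(self.Q)]
        names += ["S", "sigma_s"]
        if self.is_alaplace:
            names += ["kappa"]
        names += ["sigma", "tau", "tau_s"]
        for q in range(self.Q):
            names += [f"odds{q + 1}", f"R2_{q + 1}"]
            names += [f"R{l}_{q + 1}" for l in range(3, self.L + 1)]
        names += [f"relH{q + 1}" for q in range(1, self.Q)]
        names += ["loglik"]
        return names

    def _record(self, out: np.ndarray, row: int) -> None:
        k = 0
        out[row, k : k + self.Q] = self.M
        k += self.Q
        out[row, k : k + self.Q] = self.H
        k += self.Q
        out[row, k] = self.S
        out[row, k + 1] = self.sigma_s
        k += 2
        if self.is_alaplace:
            out[row, k] = self.kappa
            k += 1
        out[row, k] = math.sqrt(self.sigma2)
        out[row, k + 1] = self.tau
        out[row, k + 2] = self.tau_s
        k += 3
        for q in range(self.Q):
            out[row, k] = self.odds[q]
            out[row, k + 1 : k + self.L] = self.Rfull[q, 1:]
            k += self.L
        h1 = self.H[0] if self.H[0] > 0 else np.nan
        for q in range(1, self.Q):
            out[row, k] = self.H[q] / h1
            k += 1
        out[row, k] = self.log_likelihood()

    def run(self) -> ChainResult:
        scfg = self.scfg
        n_keep = (scfg.n_iter - scfg.burn_in + scfg.thin - 1) // scfg.thin
        cols = self.column_names()
        out = np.empty((n_keep, len(cols)))
        row = 0
        for it in range(scfg.n_iter):
            self._sweep(it)
            if it == scfg.burn_in:
                # post-burn-in acceptance bookkeeping starts clean
                for nm in self._accepts:
                    self._accepts[nm] = 0
                    self._proposals[nm] = 0
            if it >= scfg.burn_in and (it - scfg.burn_in) % scfg.thin == 0:
                self._record(out, row)
                row += 1
        draws = pd.DataFrame(out[:row], columns=cols)
        return self._finalize(draws)

    def _finalize(self, draws: pd.DataFrame) -> ChainResult:
        acc = {
            nm: (self._accepts[nm] / self._proposals[nm]) if self._proposals[nm] else 0.0
            for nm in self._accepts
        }
        means = draws.mean()
        summaries = pd.DataFrame(
            {
                "mean": means,
                "sd": draws.std(ddof=1),
                "q2.5": draws.quantile(0.025),
                "q97.5": draws.quantile(0.975),
            }
        )
        # deviance at the posterior mean (plug-in)
        peptides = []
        for q in range(self.Q):
            R = np.ones(self.L)
            R[1] = means[f"R2_{q + 1}"]
            for l in range(3, self.L + 1):
                R[l - 1] = means[f"R{l}_{q + 1}"]
            peptides.append(
                PeptideState(
                    M=float(means[f"M{q + 1}"]),
                    H=float(means[f"H{q + 1}"]),
                    R=R,
                    odds=float(means[f"odds{q + 1}"]),
                )
            )
        sig_s = float(np.clip(means["sigma_s"], 1e-6, self.hp.sigma_s_max))
        if self.is_alaplace:
            kap = float(np.clip(means["kappa"], self.hp.kappa_min, self.hp.kappa_max))
            shape = ShapeParams("asymmetric_laplace", sig_s, kap)
        else:
            shape = ShapeParams("normal", sig_s)
        shared = SharedState(
            S=float(means["S"]),
            sigma=float(means["sigma"]),
            shape=shape,
            tau=float(means["tau"]),
            tau_s=float(means["tau_s"]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dev_at_mean = -2.0 * model_core.log_likelihood(self.window, peptides, shared)
        deviances = -2.0 * draws["loglik"].to_numpy()
        dic, p_d = compute_dic(deviances, dev_at_mean)
        if p_d < 0:
            warnings.warn(
                f"negative effective parameter count p_D = {p_d:.2f} "
                "(poorly identified model); DIC retained as-is"
            )
        n_free_masses = 1 if self.constrained else self.Q
        n_params = (
            self.Q + n_free_masses + 2 + (1 if self.is_alaplace else 0) + 1 + self.Q * (self.L - 1)
        )
        bic = compute_bic(dev_at_mean, n_params, self.N)
        return ChainResult(
            draws=draws,
            acceptance_rates=acc,
            summaries=summaries,
            dic=float(dic),
            bic=float(bic),
            p_d=float(p_d),
            mean_deviance=float(np.mean(deviances)),
            deviance_at_mean=float(dev_at_mean),
            n_params=n_params,
            n_obs=self.N,
            seed=self.scfg.seed,
        )


def run_chain(
    window: SpectrumWindow,
    config: ModelConfig,
    mass_prior,
    sampler_config: SamplerConfig | None = None,
    init: dict | None = None,
    ratio_model: PolynomialRatioModel | None = None,
    fraction_model: MonoisotopicFractionModel | None = None,
) -> ChainResult:
    """Fit one candidate model by MH-within-Gibbs and return its chain.

    Deterministic given ``sampler_config.seed``: two calls with identical
    arguments produce bit-identical draws.
    """
    chain = Chain(
        window,
        config,
        mass_prior,
        sampler_config=sampler_config,
        init=init,
        ratio_model=ratio_model,
        fraction_model=fraction_model,
    )
    return chain.run()
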