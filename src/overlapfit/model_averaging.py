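"""Candidate mass-cluster priors, DIC-weighted model averaging, BIC selection.

Peptide monoisotopic masses are not uniform: across large proteome digests
they concentrate in narrow bell-shaped "clusters" around near-integer
values (average spacing ~1.000495 Da).  Each cluster supplies one candidate
normal prior ``M_q ~ N(eta_g, sigma_m^2)`` for a peptide mass; one chain is
fitted per candidate model and the results are combined by Bayesian model
averaging with DIC-based weights:

    w_g = exp(-Delta_DIC_g / 2) / sum_g' exp(-Delta_DIC_g' / 2)

point estimates are weighted means across candidates, and the standard
error combines within-model spread and between-model disagreement:

    se(theta) = sum_g w_g sqrt(se_g^2 + (theta_g - theta)^2)

The number of peptides Q, when unknown, is chosen by fitting a range of Q
values and comparing BIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_core import ModelConfig, PeptideState, SharedState, SpectrumWindow
from .peak_shape import ShapeParams
from .sampler import (
    ChainResult,
    SamplerConfig,
    greedy_mass_estimates,
    initialize_state,
    run_chain,
)

__all__ = [
    "MassClusterPrior",
    "CandidateModel",
    "AveragedResult",
    "build_mass_clusters",
    "default_candidate_clusters",
    "dic_weights",
    "average_estimates",
    "fit_bma",
    "select_n_peptides",
    "averaged_mean_spectrum",
]

#: Average spacing of peptide mass clusters (Da per nominal mass unit).
CLUSTER_SPACING = 1.000495

#: Default prior SD when cluster spreads are unavailable (singleton clusters).
DEFAULT_SIGMA_M = 0.1


@dataclass(frozen=True)
class MassClusterPrior:
    """One candidate mass cluster: center ``eta`` and prior SD ``sigma_m`` (Da)."""

    eta: float
    sigma_m: float

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")


@dataclass
class CandidateModel:
    """One fitted candidate: its per-peptide mass priors, chain, and weight."""

    mass_priors: list[tuple[float, float]]
    chain: ChainResult
    dic: float
    bic: float
    weight: float = math.nan


@dataclass
class AveragedResult:
    """Model-averaged estimates across candidates.

    ``estimates`` has one row per parameter with columns ``mean``, ``se``,
    ``lo`` and ``hi`` (95% interval from the normal approximation
    ``mean +/- 1.96 se``).
    """

    weights: np.ndarray
    estimates: pd.DataFrame
    per_candidate: list[CandidateModel]
    config: ModelConfig
    seed: int

    @property
    def best_candidate(self) -> CandidateModel:
        return self.per_candidate[int(np.argmax(self.weights))]

    @property
    def bic(self) -> float:
        """Smallest BIC across candidates (used for model-size comparison)."""
        return min(c.bic for c in self.per_candidate)


def build_mass_clusters(
    candidate_masses,
    window_range: tuple[float, float] | None = None,
    gap: float = 0.25,
    bin_width: float = 0.01,
) -> list[MassClusterPrior]:
    """Group candidate masses into cluster priors.

    Sorted masses are split into contiguous clusters wherever consecutive
    masses are more than ``gap`` Da apart.  Each cluster's center is the mode
    of its ``bin_width``-Da histogram; its spread parameter is
    ``max(left spread, right spread) / 3``; and all clusters share the
    largest such spread as the common ``sigma_m`` (falling back to
    ``DEFAULT_SIGMA_M`` when every cluster is a point mass).  An empty
    candidate list falls back to the integer-spaced default rule over
    ``window_range``.
    """
    masses = np.sort(np.asarray(list(candidate_masses), dtype=float))
    if masses.size == 0:
        if window_range is None:
            raise ValueError("empty candidate list and no window range for the fallback")
        return default_candidate_clusters(window_range)
    splits = np.nonzero(np.diff(masses) > gap)[0] + 1
    groups = np.split(masses, splits)
    etas, spreads = [], []
    for grp in groups:
        lo, hi = float(grp[0]), float(grp[-1])
        if grp.size == 1:
            eta = lo
        else:
            nbins = max(int(math.ceil((hi - lo) / bin_width)), 1)
            counts, edges = np.histogram(grp, bins=nbins, range=(lo, hi + 1e-12))
            centers = 0.5 * (edges[:-1] + edges[1:])
            med = float(np.median(grp))
            # modal bin; ties broken toward the cluster median
            best = max(
                range(nbins), key=lambda k: (counts[k], -abs(centers[k] - med))
            )
            members = grp[(grp >= edges[best]) & (grp <= edges[best + 1])]
            eta = float(members.mean()) if members.size else float(centers[best])
        etas.append(eta)
        spreads.append(max(eta - lo, hi - eta) / 3.0)
    sigma_m = max(spreads)
    if sigma_m <= 0:
        sigma_m = DEFAULT_SIGMA_M
    return [MassClusterPrior(eta=e, sigma_m=sigma_m) for e in etas]


def default_candidate_clusters(
    window_range: tuple[float, float],
    spacing: float = CLUSTER_SPACING,
    sigma_m: float = DEFAULT_SIGMA_M,
) -> list[MassClusterPrior]:
    """Integer-rule clusters: centers at ``k * spacing`` inside the window."""
    lo, hi = window_range
    k_lo = int(math.ceil(lo / spacing))
    k_hi = int(math.floor(hi / spacing))
    if k_hi < k_lo:
        raise ValueError("window too narrow for any default mass cluster")
    return [MassClusterPrior(eta=k * spacing, sigma_m=sigma_m) for k in range(k_lo, k_hi + 1)]


def dic_weights(dics) -> np.ndarray:
    """Akaike-style DIC weights; invariant to adding a constant to all DICs."""
    dics = np.asarray(dics, dtype=float)
    if dics.size == 0:
        raise ValueError("need at least one DIC")
    delta = dics - np.min(dics)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def average_estimates(estimates, ses, weights) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-candidate estimates and SEs into model-averaged ones.

    ``theta = sum_g w_g theta_g`` and
    ``se = sum_g w_g sqrt(se_g^2 + (theta_g - theta)^2)``.
    Accepts arrays of shape ``(G,)`` or ``(G, P)``.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    one_d = est.ndim == 1
    if one_d:
        est = est[:, None]
        se = se[:, None]
    if est.shape != se.shape or est.shape[0] != w.size:
        raise ValueError("estimates, ses and weights have inconsistent shapes")
    theta = w @ est
    se_avg = np.einsum("g,gp->p", w, np.sqrt(se**2 + (est - theta[None, :]) ** 2))
    if one_d:
        return float(theta[0]), float(se_avg[0])
    return theta, se_avg


def _candidate_assignments(
    clusters: list[MassClusterPrior],
    prelim_masses: np.ndarray,
    halfwidth: float,
    per_peptide_cap: int,
    max_candidates: int,
) -> list[tuple[MassClusterPrior, ...]]:
    """Per-peptide cluster shortlists -> ordered tuples of candidate priors."""
    shortlists = []
    etas = np.array([c.eta for c in clusters])
    for m in prelim_masses:
        dist = np.abs(etas - m)
        near = np.nonzero(dist <= halfwidth)[0]
        if near.size == 0:
            near = np.array([int(np.argmin(dist))])
        order = near[np.argsort(dist[near])][:per_peptide_cap]
        shortlists.append([clusters[i] for i in order])
    combos = []
    for combo in itertools.product(*shortlists):
        cs = [c.eta for c in combo]
        if all(b >= a for a, b in zip(cs, cs[1:])):
            cost = sum(abs(c.eta - m) for c, m in zip(combo, prelim_masses))
            combos.append((cost, combo))
    combos.sort(key=lambda t: t[0])
    if not combos:  # ordering filtered everything out: fall back to nearest-per-peptide
        combos = [(0.0, tuple(s[0] for s in shortlists))]
    return [c for _, c in combos[:max_candidates]]


def fit_bma(
    window: SpectrumWindow,
    config: ModelConfig,
    clusters: list[MassClusterPrior] | None = None,
    sampler_config: SamplerConfig | None = None,
    candidate_masses=None,
    halfwidth: float = 0.6,
    per_peptide_cap: int = 2,
    max_candidates: int = 4,
    ratio_model=None,
    fraction_model=None,
) -> AveragedResult:
    """Fit all candidate mass-prior models and combine them by DIC weights.

    Candidate models are tuples of one cluster prior per (free) peptide,
    shortlisted near preliminary greedy mass estimates.  Candidate ``g``
    runs with seed ``master_seed + g`` so the whole procedure is
    reproducible from the master seed.
    """
    scfg = sampler_config or SamplerConfig()
    if clusters is None:
        rng_range = (float(window.x[0]), float(window.x[-1]))
        if candidate_masses is not None:
            clusters = build_mass_clusters(candidate_masses, rng_range)
        else:
            clusters = default_candidate_clusters(rng_range)
    prelim = greedy_mass_estimates(window, config.Q, config.L, ratio_model=ratio_model)
    if config.constraint is not None and config.Q > 1:
        assign_masses = prelim[:1]
    else:
        assign_masses = prelim
    assignments = _candidate_assignments(
        clusters, assign_masses, halfwidth, per_peptide_cap, max_candidates
    )

    candidates: list[CandidateModel] = []
    for g, combo in enumerate(assignments):
        if config.constraint is not None and config.Q > 1:
            priors = [(combo[0].eta, combo[0].sigma_m)] * config.Q
        else:
            priors = [(c.eta, c.sigma_m) for c in combo]
        init = initialize_state(
            window, config, priors, ratio_model=ratio_model, prelim_masses=prelim
        )
        chain = run_chain(
            window,
            config,
            priors,
            sampler_config=replace(scfg, seed=scfg.seed + g),
            init=init,
            ratio_model=ratio_model,
            fraction_model=fraction_model,
        )
        candidates.append(
            CandidateModel(mass_priors=priors, chain=chain, dic=chain.dic, bic=chain.bic)
        )

    weights = dic_weights([c.dic for c in candidates])
    for c, w in zip(candidates, weights):
        c.weight = float(w)
    params = candidates[0].chain.summaries.index
    est = np.vstack([c.chain.summaries["mean"].to_numpy() for c in candidates])
    se = np.vstack([c.chain.summaries["sd"].to_numpy() for c in candidates])
    theta, se_avg = average_estimates(est, se, weights)
    theta = np.atleast_1d(theta)
    se_avg = np.atleast_1d(se_avg)
    estimates = pd.DataFrame(
        {
            "mean": theta,
            "se": se_avg,
            "lo": theta - 1.96 * se_avg,
            "hi": theta + 1.96 * se_avg,
        },
        index=params,
    )
    return AveragedResult(
        weights=np.asarray(weights),
        estimates=estimates,
        per_candidate=candidates,
        config=config,
        seed=scfg.seed,
    )


def select_n_peptides(
    window: SpectrumWindow,
    q_range: tuple[int, int],
    config: ModelConfig,
    sampler_config: SamplerConfig | None = None,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, AveragedResult]]:
    """Fit Q = q_min..q_max and pick the Q with the smallest BIC.

    Returns ``(chosen_q, bic_table, fits)``; the table reports one row per Q
    even when the selection is flat.  Each Q uses seed
    ``master_seed + 1000 * Q`` so runs are independent but reproducible.
    """
    scfg = sampler_config or SamplerConfig()
    q_min, q_max = q_range
    if q_min < 1 or q_max < q_min:
        raise ValueError("invalid q_range")
    rows = []
    fits: dict[int, AveragedResult] = {}
    for q in range(q_min, q_max + 1):
        cfg_q = replace(config, Q=q)
        fit = fit_bma(
            window,
            cfg_q,
            sampler_config=replace(scfg, seed=scfg.seed + 1000 * q),
            **fit_kwargs,
        )
        fits[q] = fit
        best = fit.best_candidate
        rows.append(
            {
                "Q": q,
                "bic": fit.bic,
                "dic": best.dic,
                "n_candidates": len(fit.per_candidate),
            }
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["bic"].idxmin(), "Q"])
    return chosen, table, fits


def averaged_mean_spectrum(result: AveragedResult, window: SpectrumWindow) -> np.ndarray:
    """Model mean over the window at the averaged point estimates (fit overlay)."""
    from .model_core import mean_intensity

    cfg = result.config
    est = result.estimates["mean"]
    peptides = []
    for q in range(1, cfg.Q + 1):
        R = np.ones(cfg.L)
        R[1] = est[f"R2_{q}"]
        for l in range(3, cfg.L + 1):
            R[l - 1] = est[f"R{l}_{q}"]
        peptides.append(
            PeptideState(M=float(est[f"M{q}"]), H=float(est[f"H{q}"]), R=R, odds=float(est[f"odds{q}"]))
        )
    hp = cfg.hyperparams
    sig_s = float(np.clip(est["sigma_s"], 1e-6, hp.sigma_s_max))
    if cfg.shape_kind == "asymmetric_laplace":
        shape = ShapeParams(
            "asymmetric_laplace",
            sig_s,
            float(np.clip(est["kappa"], hp.kappa_min, hp.kappa_max)),
        )
    else:
        shape = ShapeParams("normal", sig_s)
    shared = SharedState(S=float(est["S"]), sigma=float(est["sigma"]), shape=shape)
    return mean_intensity(peptides, shared, window)
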