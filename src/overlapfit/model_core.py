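"""Forward model, likelihood and joint log-prior for one peak cluster.

The observed window is a vector of intensities ``y_j`` on an ascending mass
grid ``x_j``.  Each of ``Q`` overlapping peptides contributes an isotope
envelope of ``L`` peaks at ``M_q + (l-1) S`` with heights ``H_q R_{l,q}``,
spread over the grid by a bin-mass shape function:

    E(y_j) = sum_q sum_l H_q R_{l,q} psi(x_j; M_q + (l-1) S)

and ``y_j ~ N(E(y_j), sigma^2)`` independently.

Grid convention: the ``x_j`` are bin right-edges; bin ``j`` covers
``(x_{j-1}, x_j]`` with ``x_0 = 0`` for the first bin (for realistic windows
the shape CDF at 0 is numerically zero).

An optional constraint mode ties the masses to a fixed spacing,
``M_q = M_1 + k (q-1) S`` — with ``k = 4`` this is the 18O-labeling design,
where the labeled partner sits four isotope spacings above the unlabeled one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, gammaincc, ndtr

from .isotopic_prior import (
    MonoisotopicFractionModel,
    PolynomialRatioModel,
    odds_prior,
    reference_ratio_prior,
)
from .peak_shape import ShapeParams, bin_masses

__all__ = [
    "SpectrumWindow",
    "PeptideState",
    "Constraint",
    "Hyperparams",
    "ModelConfig",
    "SharedState",
    "mean_intensity",
    "log_likelihood",
    "log_prior",
    "apply_constraint",
    "normalize_mass_priors",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SpectrumWindow:
    """One peak-cluster window: ascending mass grid ``x`` (Da) and intensities ``y``."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("a spectrum window needs at least two points")
        if np.any(np.diff(x) <= 0):
            raise ValueError("mass coordinates must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("mass coordinates and intensities must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def edges(self) -> np.ndarray:
        """Bin edges ``[0, x_1, ..., x_N]`` (x values are bin right-edges)."""
        return np.concatenate(([0.0], self.x))


@dataclass
class PeptideState:
    """Per-peptide parameters: mass ``M``, abundance ``H``, reference ratios ``R``.

    ``R`` has length L with ``R[0] = 1`` fixed; ``odds`` is ``(1-p_1)/p_1``
    backing the reparameterization ``R_2 = odds - sum_{l>=3} R_l``.
    """

    M: float
    H: float
    R: np.ndarray
    odds: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)

    def is_feasible(self) -> bool:
        if self.H < 0 or self.odds <= 0:
            return False
        if self.R.size < 1 or self.R[0] != 1.0:
            return False
        if np.any(self.R <= 0):
            return False
        if self.R.size >= 2:
            r2 = self.odds - self.R[2:].sum()
            if r2 <= 0:
                return False
        return True


@dataclass(frozen=True)
class Constraint:
    """Fixed-offset mass constraint ``M_q = M_1 + offset_multiple * (q-1) * S``."""

    offset_multiple: int


@dataclass(frozen=True)
class Hyperparams:
    """Constants of the weak priors (all gamma shapes/rates close to zero)."""

    alpha: float = 0.001        # sigma^-2 ~ Gamma(alpha, beta)
    beta: float = 0.001
    alpha_star: float = 0.001   # tau ~ Gamma(alpha*, beta*)
    beta_star: float = 0.001
    alpha_2star: float = 0.001  # tau_s ~ Gamma(alpha**, beta**) I(tau_s >= tau_s_min)
    beta_2star: float = 0.001
    tau_s_min: float = 1600.0
    sigma_s_max: float = 0.5
    kappa_min: float = 0.01
    kappa_max: float = 0.99

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alpha_star", "beta_star", "alpha_2star", "beta_2star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")


@dataclass(frozen=True)
class ModelConfig:
    """Structural configuration: Q peptides, L isotopic variants, shape, constraint."""

    Q: int
    L: int
    shape_kind: str = "normal"
    constraint: Constraint | None = None
    hyperparams: Hyperparams = field(default_factory=Hyperparams)

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.L < 2:
            raise ValueError("L must be >= 2")
        if self.shape_kind not in ("normal", "asymmetric_laplace"):
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")


@dataclass
class SharedState:
    """Parameters shared across peptides: spacing S, noise SD, shape, hyperprior precisions."""

    S: float
    sigma: float
    shape: ShapeParams
    tau: float = 1e-8
    tau_s: float = 3200.0


def normalize_mass_priors(mass_prior, Q: int) -> list[tuple[float, float]]:
    """Accept a single ``(eta, sigma_m)`` or a per-peptide sequence; return a list of Q."""
    if mass_prior is None:
        raise ValueError("a mass prior (eta, sigma_m) is required")
    first = mass_prior[0]
    if np.isscalar(first):
        eta, sigma_m = mass_prior
        priors = [(float(eta), float(sigma_m))] * Q
    else:
        priors = [(float(e), float(s)) for e, s in mass_prior]
        if len(priors) != Q:
            raise ValueError(f"expected {Q} mass priors, got {len(priors)}")
    for eta, sigma_m in priors:
        if sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
    return priors


def mean_intensity(
    peptides: list[PeptideState], shared: SharedState, window: SpectrumWindow
) -> np.ndarray:
    """Model mean ``E(y)`` over the window grid (linear in each H_q and R_lq)."""
    edges = window.edges
    mean = np.zeros(window.n)
    for pep in peptides:
        centers = pep.M + shared.S * np.arange(pep.R.size)
        psi = bin_masses(edges, centers, shared.shape)
        mean += pep.H * (pep.R @ psi)
    if peptides and not np.any(mean > 0):
        warnings.warn(
            "window does not cover any peak support; model mean is all zero",
            stacklevel=2,
        )
    return mean


def log_likelihood(
    window: SpectrumWindow, peptides: list[PeptideState], shared: SharedState
) -> float:
    """Gaussian log-likelihood ``sum_j log N(y_j; E(y_j), sigma^2)``."""
    if shared.sigma <= 0:
        raise ValueError("sigma must be positive")
    resid = window.y - mean_intensity(peptides, shared, window)
    n = window.n
    return float(
        -0.5 * n * (_LOG_2PI + 2.0 * math.log(shared.sigma))
        - 0.5 * float(resid @ resid) / (shared.sigma**2)
    )


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return shape * math.log(rate) - gammaln(shape) + (shape - 1.0) * math.log(x) - rate * x


def _log_normal_pdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + math.log(var)) - 0.5 * (x - mean) ** 2 / var


def _log_lognormal_pdf(x: float, mu: float, sigma_sq: float) -> float:
    if x <= 0:
        return -math.inf
    lx = math.log(x)
    return -lx - 0.5 * (_LOG_2PI + math.log(sigma_sq)) - 0.5 * (lx - mu) ** 2 / sigma_sq


def log_prior(
    peptides: list[PeptideState],
    shared: SharedState,
    config: ModelConfig,
    mass_prior,
    ratio_model: PolynomialRatioModel | None = None,
    fraction_model: MonoisotopicFractionModel | None = None,
) -> float:
    """Joint log-prior density; ``-inf`` encodes any constraint violation.

    Terms: half-normal (precision tau) for each H_q; Gamma for sigma^-2, tau
    and the truncated tau_s; truncated normal for sigma_s; N(1, 1/tau_s) for
    S; uniform for kappa; N(eta_g, sigma_m^2) for each free mass; log-normal
    ratio priors for each odds_q and each R_lq with l >= 3.  Mass ordering
    M_1 < ... < M_Q is enforced in unconstrained mode.  The ratio-prior
    hyperparameters are evaluated at the peptide's prior center eta.
    """
    hp = config.hyperparams
    priors = normalize_mass_priors(mass_prior, config.Q)
    if len(peptides) != config.Q:
        raise ValueError(f"expected {config.Q} peptides, got {len(peptides)}")

    # --- feasibility gates (rejection region) -------------------------------
    for pep in peptides:
        if not pep.is_feasible():
            return -math.inf
    masses = np.array([p.M for p in peptides])
    if config.constraint is None and np.any(np.diff(masses) <= 0):
        return -math.inf
    shape = shared.shape
    if not (0.0 < shape.sigma_s <= hp.sigma_s_max):
        return -math.inf
    if config.shape_kind == "asymmetric_laplace":
        if shape.kappa is None or not (hp.kappa_min <= shape.kappa <= hp.kappa_max):
            return -math.inf
    if shared.sigma <= 0 or shared.tau <= 0 or shared.tau_s < hp.tau_s_min:
        return -math.inf

    lp = 0.0
    # abundances: H_q ~ N(0, 1/tau) truncated to [0, inf)
    for pep in peptides:
        lp += 0.5 * math.log(2.0 * shared.tau / math.pi) - 0.5 * shared.tau * pep.H**2
    # noise precision
    lp += _log_gamma_pdf(shared.sigma**-2, hp.alpha, hp.beta)
    # peak width: N(0, 1e6) truncated to [0, sigma_s_max]
    z = ndtr(hp.sigma_s_max / 1000.0) - 0.5
    lp += _log_normal_pdf(shape.sigma_s, 0.0, 1e6) - math.log(z)
    # isotope spacing and its precision
    lp += _log_normal_pdf(shared.S, 1.0, 1.0 / shared.tau_s)
    lp += _log_gamma_pdf(shared.tau, hp.alpha_star, hp.beta_star)
    tail = float(gammaincc(hp.alpha_2star, hp.beta_2star * hp.tau_s_min))
    lp += _log_gamma_pdf(shared.tau_s, hp.alpha_2star, hp.beta_2star) - math.log(tail)
    # skewness
    if config.shape_kind == "asymmetric_laplace":
        lp += -math.log(hp.kappa_max - hp.kappa_min)
    # masses (free peptides only) and isotopic-ratio priors
    for q, (pep, (eta, sigma_m)) in enumerate(zip(peptides, priors)):
        if config.constraint is None or q == 0:
            lp += _log_normal_pdf(pep.M, eta, sigma_m**2)
        ref_mass = eta
        spec = odds_prior(ref_mass, fraction_model)
        lp += _log_lognormal_pdf(pep.odds, spec.mu, spec.sigma_sq)
        for l in range(3, pep.R.size + 1):
            rp = reference_ratio_prior(ref_mass, l, ratio_model)
            lp += _log_lognormal_pdf(pep.R[l - 1], rp.mu, rp.sigma_sq)
    return float(lp)


def apply_constraint(
    peptides: list[PeptideState], shared: SharedState, config: ModelConfig
) -> list[PeptideState]:
    """Return peptides with ``M_q = M_1 + offset_multiple * (q-1) * S`` enforced."""
    if config.constraint is None:
        raise ValueError("no constraint configured")
    if len(peptides) == 1:
        warnings.warn("constraint with a single peptide is a no-op", stacklevel=2)
        return list(peptides)
    k = config.constraint.offset_multiple
    out = [peptides[0]]
    for q in range(1, len(peptides)):
        pep = peptides[q]
        out.append(
            PeptideState(M=peptides[0].M + k * q * shared.S, H=pep.H, R=pep.R, odds=pep.odds)
        )
    return out


def read_spectrum(path) -> SpectrumWindow:
    """Read a two-column (mass, intensity) TSV/CSV window.

    Lines starting with ``#`` are comments; a single header line is allowed.
    Raises a ``ValueError`` naming the offending line on parse failure.
    """
    xs: list[float] = []
    ys: list[float] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            for sep in ("\t", ",", ";"):
                if sep in text:
                    parts = [p for p in text.split(sep) if p.strip()]
                    break
            else:
                parts = text.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}, line {lineno}: expected two columns, got {len(parts)}"
                )
            try:
                xv, yv = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 or (not xs and lineno <= 2):
                    continue  # tolerated header line
                raise ValueError(
                    f"{path}, line {lineno}: could not parse {text!r} as numbers"
                ) from None
            xs.append(xv)
            ys.append(yv)
    if len(xs) < 2:
        raise ValueError(f"{path}: no numeric spectrum rows found")
    return SpectrumWindow(x=np.array(xs), y=np.array(ys))


def write_spectrum(window: SpectrumWindow, path, header: bool = True) -> None:
    """Write a window as a two-column TSV readable by :func:`read_spectrum`."""
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write("mass\tintensity\n")
        for xv, yv in zip(window.x, window.y):
            fh.write(f"{float(xv)!r}\t{float(yv)!r}\n")
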