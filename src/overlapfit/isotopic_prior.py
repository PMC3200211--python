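"""Informative priors for peptide isotopic ratios.

A peptide of monoisotopic mass ``m`` produces an envelope of isotopic peaks
roughly 1 Da apart whose relative heights follow the peptide's isotopic
distribution ``p_1, p_2, ...``.  Two equivalent parameterizations are used
throughout the package:

* *consecutive ratios* ``C_l = p_l / p_{l-1}`` (with ``C_1 = 1``), and
* *common reference ratios* ``R_l = p_l / p_1 = C_1 C_2 ... C_l``.

Although the exact isotopic distribution requires the (unknown) elemental
composition, peptides of similar mass have similar distributions.  This is
exploited by a population model: a fourth-order polynomial in ``m/1000``
predicts ``log C_l`` for ``l = 2..8``, with a residual variance per ratio
index.  The default coefficients were estimated from a large tryptic digest
of the human proteome (masses 400-4000 Da) and are shipped as a CSV resource
so they can be audited.

From the polynomial model this module builds

* log-normal priors for the reference ratios ``R_l`` (``l >= 3``) whose
  log-scale location/scale are cumulative sums of the per-step predictions,
* a log-normal prior for the odds ``(1 - p_1)/p_1`` via a linear model for
  ``log p_1`` in ``m``, and
* the reparameterization ``R_2 = (1 - p_1)/p_1 - sum_{l>=3} R_l``, which
  acts as a *virtual constraint*: inflating the tail ratios shrinks ``R_2``,
  preventing a joint overestimation of the whole envelope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "MASS_RANGE",
    "MAX_RATIO_INDEX",
    "ExtrapolationWarning",
    "UnsupportedRatioError",
    "DegeneratePriorError",
    "RatioConstraintError",
    "PolynomialRatioModel",
    "MonoisotopicFractionModel",
    "RatioPriorSpec",
    "OddsPriorSpec",
    "predict_log_consecutive_ratio",
    "consecutive_to_reference",
    "reference_ratio_prior",
    "odds_prior",
    "reparameterized_R2",
    "default_n_isotopes",
    "prior_median_reference_ratios",
]

#: Mass range (Da) over which the polynomial ratio model was estimated.
MASS_RANGE = (400.0, 4000.0)

#: Largest isotope index l for which polynomial coefficients are available.
MAX_RATIO_INDEX = 8


class ExtrapolationWarning(UserWarning):
    """Mass outside the supported 400-4000 Da range; polynomial extrapolated."""


class UnsupportedRatioError(ValueError):
    """Isotope index outside the modeled range l = 2..8."""


class DegeneratePriorError(ValueError):
    """A prior with zero (or negative) variance was requested."""


class RatioConstraintError(ValueError):
    """The virtual constraint R2 = odds - sum(R_tail) produced R2 <= 0.

    The sampler treats this as a rejected proposal rather than an error.
    """


@dataclass(frozen=True)
class PolynomialRatioModel:
    """Fourth-order polynomial model for log consecutive isotopic ratios.

    Attributes
    ----------
    coefficients
        Array of shape ``(7, 5)``; row ``l - 2`` holds ``beta_0..beta_4``
        for ``log C_l``, applied to powers of ``m/1000``.
    residual_variances
        Array of shape ``(7,)``; ``sigma_l^2``, the residual variance of
        ``log C_l`` around the polynomial prediction.
    """

    coefficients: np.ndarray
    residual_variances: np.ndarray

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        var = np.asarray(self.residual_variances, dtype=float)
        if coef.shape != (7, 5):
            raise ValueError(f"expected 7x5 coefficient matrix, got {coef.shape}")
        if var.shape != (7,):
            raise ValueError(f"expected 7 residual variances, got {var.shape}")
        if not np.all(var > 0):
            raise DegeneratePriorError("all residual variances must be positive")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "residual_variances", var)

    @classmethod
    def default(cls) -> "PolynomialRatioModel":
        """The shipped coefficient table (see ``data/isotope_ratio_poly.csv``)."""
        return _default_ratio_model()


@lru_cache(maxsize=1)
def _default_ratio_model() -> PolynomialRatioModel:
    ref = resources.files("overlapfit.data").joinpath("isotope_ratio_poly.csv")
    with ref.open("rb") as fh:
        raw = np.loadtxt(fh, delimiter=",", skiprows=1)
    if raw.shape != (7, 7):
        raise ValueError("corrupt isotope_ratio_poly.csv resource")
    return PolynomialRatioModel(coefficients=raw[:, 1:6], residual_variances=raw[:, 6])


def _check_mass(m: float) -> None:
    if not (MASS_RANGE[0] <= m <= MASS_RANGE[1]):
        warnings.warn(
            f"mass {m:.2f} Da outside the supported range "
            f"{MASS_RANGE[0]:.0f}-{MASS_RANGE[1]:.0f} Da; extrapolating",
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_log_consecutive_ratio(
    m: float, l: int, model: PolynomialRatioModel | None = None
) -> tuple[float, float]:
    """Predictive mean and variance of ``log C_l`` at monoisotopic mass ``m``.

    Returns ``(mean, variance)`` where ``mean = sum_k beta_k (m/1000)^k`` and
    ``variance`` is the residual variance ``sigma_l^2`` of the population model.
    """
    if model is None:
        model = PolynomialRatioModel.default()
    if not 2 <= l <= MAX_RATIO_INDEX:
        raise UnsupportedRatioError(f"isotope index l={l} outside supported range 2..8")
    _check_mass(m)
    x = m / 1000.0
    beta = model.coefficients[l - 2]
    mean = beta[0] + x * (beta[1] + x * (beta[2] + x * (beta[3] + x * beta[4])))
    return float(mean), float(model.residual_variances[l - 2])


def consecutive_to_reference(C: np.ndarray) -> np.ndarray:
    """Convert consecutive ratios ``C_1..C_L`` to reference ratios ``R_1..R_L``.

    ``R_l = C_1 C_2 ... C_l``; requires ``C_1 = 1`` and all ``C_l > 0``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 1 or C.size < 1:
        raise ValueError("C must be a non-empty 1-D vector")
    if C[0] != 1.0:
        raise ValueError("C_1 must equal 1")
    if not np.all(C > 0):
        raise ValueError("all consecutive ratios must be positive")
    return np.cumprod(C)


@dataclass(frozen=True)
class RatioPriorSpec:
    """Log-normal prior for a reference ratio ``R_l``: ``log R_l ~ N(mu, sigma_sq)``."""

    l: int
    mu: float
    sigma_sq: float

    def __post_init__(self) -> None:
        if self.sigma_sq <= 0:
            raise DegeneratePriorError(f"sigma_sq must be positive, got {self.sigma_sq}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


@dataclass(frozen=True)
class OddsPriorSpec:
    """Log-normal prior for the odds ``(1 - p_1)/p_1``."""

    mu: float
    sigma_sq: float

    def __post_init__(self) -> None:
        if self.sigma_sq <= 0:
            raise DegeneratePriorError(f"sigma_sq must be positive, got {self.sigma_sq}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)


def reference_ratio_prior(
    m: float, l: int, model: PolynomialRatioModel | None = None
) -> RatioPriorSpec:
    """Log-normal prior for the reference ratio ``R_l`` (``l >= 3``).

    Because ``log R_l = sum_{i<=l} log C_i`` and ``log C_1 = 0``, the prior
    location is the cumulative sum of predicted per-step means and the scale
    the cumulative sum of per-step variances.
    """
    if l < 3:
        raise UnsupportedRatioError("reference-ratio priors are defined for l >= 3")
    if l > MAX_RATIO_INDEX:
        raise UnsupportedRatioError(f"isotope index l={l} outside supported range 3..8")
    mu = 0.0
    var = 0.0
    for i in range(2, l + 1):
        mi, vi = predict_log_consecutive_ratio(m, i, model)
        mu += mi
        var += vi
    return RatioPriorSpec(l=l, mu=mu, sigma_sq=var)


@dataclass(frozen=True)
class MonoisotopicFractionModel:
    """Linear model ``log p_1 = alpha + beta m`` for the monoisotopic fraction.

    Supplies the log-normal prior for the odds ``(1 - p_1)/p_1``.  The default
    is *self-consistent* with the polynomial ratio model: it is a least-squares
    fit of ``log p_1(m)`` over a 400-4000 Da grid, where
    ``p_1(m) = 1 / (1 + sum_{l=2..8} exp(predicted mean log R_l))``, with
    residual variance taken conservatively as the largest per-ratio residual
    variance of the polynomial model.
    """

    alpha: float
    beta: float
    sigma_p1_sq: float

    def __post_init__(self) -> None:
        if self.sigma_p1_sq <= 0:
            raise DegeneratePriorError("sigma_p1_sq must be positive")

    @classmethod
    def default(cls) -> "MonoisotopicFractionModel":
        return _default_fraction_model()

    @classmethod
    def from_ratio_model(
        cls,
        model: PolynomialRatioModel | None = None,
        masses: np.ndarray | None = None,
    ) -> "MonoisotopicFractionModel":
        if model is None:
            model = PolynomialRatioModel.default()
        if masses is None:
            masses = np.arange(MASS_RANGE[0], MASS_RANGE[1] + 1.0, 100.0)
        masses = np.asarray(masses, dtype=float)
        log_p1 = np.empty_like(masses)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            for i, m in enumerate(masses):
                total = 0.0
                mu = 0.0
                for l in range(2, MAX_RATIO_INDEX + 1):
                    mi, _ = predict_log_consecutive_ratio(float(m), l, model)
                    mu += mi
                    total += math.exp(mu)
                log_p1[i] = -math.log1p(total)
        design = np.column_stack([np.ones_like(masses), masses])
        (alpha, beta), *_ = np.linalg.lstsq(design, log_p1, rcond=None)
        sigma_sq = float(np.max(model.residual_variances))
        return cls(alpha=float(alpha), beta=float(beta), sigma_p1_sq=sigma_sq)


@lru_cache(maxsize=1)
def _default_fraction_model() -> MonoisotopicFractionModel:
    return MonoisotopicFractionModel.from_ratio_model()


def odds_prior(
    m: float, model: MonoisotopicFractionModel | None = None
) -> OddsPriorSpec:
    """Log-normal prior for the odds ``(1 - p_1)/p_1`` at mass ``m``.

    ``mu = log[1 - exp(alpha + beta m)] - (alpha + beta m)``; requires
    ``exp(alpha + beta m) < 1`` (i.e. a valid monoisotopic fraction).
    """
    if model is None:
        model = MonoisotopicFractionModel.default()
    lin = model.alpha + model.beta * m
    if lin >= 0.0:
        raise ValueError(
            f"exp(alpha + beta*m) >= 1 at m={m:.2f}; model invalid at this mass"
        )
    mu = math.log(-math.expm1(lin)) - lin
    return OddsPriorSpec(mu=mu, sigma_sq=model.sigma_p1_sq)


def reparameterized_R2(odds: float, R_tail: np.ndarray) -> float:
    """Second reference ratio implied by the virtual constraint.

    ``R_2 = (1 - p_1)/p_1 - sum_{l>=3} R_l``.  Raises
    :class:`RatioConstraintError` when the implied ``R_2`` is non-positive;
    callers inside the sampler treat that as a rejected proposal.
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    R_tail = np.asarray(R_tail, dtype=float)
    if R_tail.size and np.any(R_tail < 0):
        raise ValueError("tail reference ratios must be non-negative")
    r2 = float(odds - R_tail.sum())
    if r2 <= 0:
        raise RatioConstraintError(
            f"implied R2 = {r2:.6g} <= 0 (odds {odds:.6g}, tail sum {R_tail.sum():.6g})"
        )
    return r2


def default_n_isotopes(
    m: float,
    model: PolynomialRatioModel | None = None,
    threshold: float = 0.02,
) -> int:
    """Default number of isotopic variants L to model at mass ``m``.

    The smallest ``l <= 8`` for which the predicted ``R_{l+1}`` falls below
    ``threshold`` (i.e. the next peak would be negligible); 8 if none does.
    Reproduces L = 5 near 1.5 kDa.
    """
    if model is None:
        model = PolynomialRatioModel.default()
    mu = 0.0
    for l in range(2, MAX_RATIO_INDEX + 1):
        mi, _ = predict_log_consecutive_ratio(m, l, model)
        mu += mi
        if math.exp(mu) < threshold:
            return l - 1
    return MAX_RATIO_INDEX


def prior_median_reference_ratios(
    m: float, L: int, model: PolynomialRatioModel | None = None
) -> np.ndarray:
    """Prior-median reference ratios ``(R_1=1, R_2, ..., R_L)`` at mass ``m``."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L > MAX_RATIO_INDEX:
        raise UnsupportedRatioError(f"L={L} exceeds the supported maximum of 8")
    out = np.ones(L)
    mu = 0.0
    for l in range(2, L + 1):
        mi, _ = predict_log_consecutive_ratio(m, l, model)
        mu += mi
        out[l - 1] = math.exp(mu)
    return out
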