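"""Independent test oracles.

Everything here is deliberately written as brute force (loops, quadrature,
dense grids, polynomial convolution) and kept free of the package's own
computational paths, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np

# Averagine: average elemental composition per 111.1254 Da of peptide.
AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_MASS = 111.1254

# Isotope abundances per element, indexed by extra-neutron count.
ISOTOPE_ABUNDANCES = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0001],
}


def averagine_reference_ratios(mass: float, L: int) -> np.ndarray:
    """Reference isotopic ratios R_1..R_L of an averagine peptide of given mass.

    Builds the aggregated isotopic distribution (probability by extra-neutron
    count) by convolving per-element distributions for the rounded averagine
    atom counts, then divides by the monoisotopic probability.
    """
    dist = np.array([1.0])
    scale = mass / AVERAGINE_MASS
    for elem, per_unit in AVERAGINE.items():
        n_atoms = int(round(per_unit * scale))
        single = np.asarray(ISOTOPE_ABUNDANCES[elem])
        for _ in range(n_atoms):
            dist = np.convolve(dist, single)
            if dist.size > 4 * L:
                dist = dist[: 4 * L]
    dist = dist[:L] if dist.size >= L else np.pad(dist, (0, L - dist.size))
    return dist / dist[0]


def naive_polynomial(coefs, x: float) -> float:
    """Power-sum polynomial evaluation (oracle for the Horner-form path)."""
    return sum(c * x**k for k, c in enumerate(coefs))


def loop_mean_intensity(peptides, shared, window) -> np.ndarray:
    """Triple-loop forward-model mean using scalar CDF differences."""
    from scipy.stats import norm

    out = np.zeros(window.n)
    edges = [0.0] + list(window.x)
    for j in range(window.n):
        lo, hi = edges[j], edges[j + 1]
        for pep in peptides:
            for l in range(pep.R.size):
                c = pep.M + l * shared.S
                if shared.shape.kind == "normal":
                    mass = norm.cdf(hi, c, shared.shape.sigma_s) - norm.cdf(
                        lo, c, shared.shape.sigma_s
                    )
                else:
                    mass = alaplace_cdf_scalar(
                        hi, c, shared.shape.sigma_s, shared.shape.kappa
                    ) - alaplace_cdf_scalar(lo, c, shared.shape.sigma_s, shared.shape.kappa)
                out[j] += pep.H * pep.R[l] * mass
    return out


def alaplace_cdf_scalar(x: float, center: float, sigma_s: float, kappa: float) -> float:
    """Independent scalar evaluation of the asymmetric Laplace CDF branches."""
    import math

    d = x - center
    if d < 0:
        return (kappa**2 / (1 + kappa**2)) * math.exp(-(math.sqrt(2) / (sigma_s * kappa)) * abs(d))
    return 1.0 - (1.0 / (1 + kappa**2)) * math.exp(-(math.sqrt(2) * kappa / sigma_s) * abs(d))


def alaplace_pdf_scalar(x: float, center: float, sigma_s: float, kappa: float) -> float:
    """Density of the asymmetric Laplace shape (for quadrature oracles)."""
    import math

    pref = math.sqrt(2) * kappa / (sigma_s * (1 + kappa**2))
    d = x - center
    if d < 0:
        return pref * math.exp(-(math.sqrt(2) / (sigma_s * kappa)) * abs(d))
    return pref * math.exp(-(math.sqrt(2) * kappa / sigma_s) * abs(d))


def grid_posterior_probs(log_density, grid: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Normalized probabilities of ``bin_edges`` intervals for a log-density on a grid."""
    ld = np.array([log_density(g) for g in grid])
    ld -= ld.max()
    w = np.exp(ld)
    w /= w.sum()
    cdf = np.concatenate(([0.0], np.cumsum(w)))
    probs = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        i0 = np.searchsorted(grid, lo, side="left")
        i1 = np.searchsorted(grid, hi, side="left")
        probs.append(cdf[i1] - cdf[i0])
    probs = np.asarray(probs)
    return probs / probs.sum()


def total_variation(draws: np.ndarray, log_density, lo: float, hi: float, n_bins: int = 20):
    """TV distance between MCMC draws and a grid-integrated density on [lo, hi].

    Uses equal-probability bins of the grid posterior so every bin carries
    comparable Monte-Carlo error.
    """
    grid = np.linspace(lo, hi, 4001)
    ld = np.array([log_density(g) for g in grid])
    ld -= ld.max()
    w = np.exp(ld)
    w /= w.sum()
    cdf = np.cumsum(w)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.concatenate(([lo], np.interp(qs, cdf, grid), [hi]))
    target = grid_posterior_probs(log_density, grid, edges)
    counts, _ = np.histogram(draws, bins=edges)
    empirical = counts / counts.sum()
    return 0.5 * float(np.abs(empirical - target).sum())
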