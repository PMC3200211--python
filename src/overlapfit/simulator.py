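"""Synthetic joint-spectrum generator for the two-peptide simulation study.

Each simulated window contains two overlapping peptides whose mass
difference decomposes into an integer part (*shift*) and a fractional part
(*tilt*): ``M_2 = M_1 + shift + tilt``.  The study design crosses 30
combinations of shift, tilt, relative abundance ``H_2/H_1`` and isotopic
ratio sets; the base generative parameters are

    M_1 = 2000.90, H_1 = 10000, sigma = 10, sigma_s = 0.08, S = 1.0015

with a symmetric normal peak shape and i.i.d. Gaussian intensity noise.

Three isotopic-ratio sets are used.  Set ``A`` is the average pattern from
the Poisson approximation ``R_l = lambda(m)^(l-1) / (l-1)!`` with the
linear rate rule ``lambda(m) = 0.000594 m - 0.03091`` (an external default
from the literature on peptide isotope patterns, not a quantity estimated
by this package).  Sets ``E1``/``E2`` emulate peptides whose second isotopic
variant is extremely small/large for their mass.  No reference tabulation
of such peptides is available, so the defaults are *synthetic stand-ins*
built from the population ratio model itself: the second consecutive ratio
is placed at its -3 / +3 population-SD quantile and the higher consecutive
ratios at their population medians, which is as extreme as the modeled
peptide population plausibly gets (the extremity ``z`` is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import PeptideState, SharedState, SpectrumWindow, mean_intensity
from .peak_shape import ShapeParams

__all__ = [
    "RatioSet",
    "BaseParams",
    "SimulationSetting",
    "poisson_lambda",
    "poisson_ratio_set",
    "ratio_set",
    "generate_spectrum",
    "spectrum_from_manifest",
    "settings_catalog",
    "replicate_study",
]

#: population-SD quantile of the second consecutive ratio per extreme code.
EXTREME_Z = {"E1": -3.0, "E2": 3.0}


def poisson_lambda(m: float) -> float:
    """Linear Poisson-rate rule for the average isotope pattern at mass ``m``."""
    return 0.000594 * m - 0.03091


@dataclass(frozen=True)
class RatioSet:
    """A named vector of reference ratios ``R_1..R_L`` (``R_1 = 1``)."""

    code: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size < 1 or vals[0] != 1.0 or np.any(vals <= 0):
            raise ValueError("ratio set must start at 1 and be positive")
        object.__setattr__(self, "values", vals)


def poisson_ratio_set(m: float, L: int = 8, scale: float = 1.0, code: str = "A") -> RatioSet:
    """Poisson-approximation ratio set: ``R_l = lam^(l-1) / (l-1)!``."""
    if m <= 0:
        raise ValueError("mass must be positive")
    if L < 1:
        raise ValueError("L must be >= 1")
    lam = scale * poisson_lambda(m)
    if lam <= 0:
        raise ValueError(f"Poisson rate non-positive at m={m}")
    ls = np.arange(L)
    vals = np.exp(ls * math.log(lam) - np.cumsum(np.log(np.maximum(ls, 1))))
    return RatioSet(code=code, values=vals)


def extreme_ratio_set(m: float, L: int = 8, z: float = 3.0, code: str = "E2") -> RatioSet:
    """Synthetic population-extreme ratio set (stand-in, see module docstring).

    The second consecutive ratio sits at its ``z``-SD quantile under the
    population ratio model; all higher consecutive ratios sit at their
    population medians.  ``z < 0`` gives a small-second-variant pattern
    (E1-like), ``z > 0`` a large one (E2-like).
    """
    from .isotopic_prior import predict_log_consecutive_ratio

    if L < 1:
        raise ValueError("L must be >= 1")
    vals = np.ones(L)
    log_r = 0.0
    for l in range(2, L + 1):
        mu, var = predict_log_consecutive_ratio(m, min(l, 8))
        log_r += mu + (z * math.sqrt(var) if l == 2 else 0.0)
        vals[l - 1] = math.exp(log_r)
    return RatioSet(code=code, values=vals)


def ratio_set(code: str, m: float, L: int = 8) -> RatioSet:
    """Ratio set by code (``A``, ``E1`` or ``E2``) at mass ``m``."""
    if code == "A":
        return poisson_ratio_set(m, L=L, code=code)
    if code in EXTREME_Z:
        return extreme_ratio_set(m, L=L, z=EXTREME_Z[code], code=code)
    raise ValueError(f"unknown ratio-set code {code!r}")


@dataclass(frozen=True)
class BaseParams:
    """Shared generative parameters of the study."""

    M1: float = 2000.90
    H1: float = 10000.0
    sigma: float = 10.0
    sigma_s: float = 0.08
    S: float = 1.0015


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the simulation design."""

    shift: int
    tilt: float
    rel_abundance: float
    ratio_codes: tuple[str, str]
    base: BaseParams = field(default_factory=BaseParams)
    grid_spacing: float = 0.01
    window_pad: float = 1.0
    L: int = 8
    seed: int = 0
    shape_kind: str = "normal"
    setting_id: int | None = None

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if not 0.0 < self.tilt < 1.0:
            raise ValueError("tilt must lie in (0, 1)")
        if self.rel_abundance <= 0:
            raise ValueError("rel_abundance must be positive")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def mass_difference(self) -> float:
        return self.shift + self.tilt

    @property
    def M2(self) -> float:
        return self.base.M1 + self.mass_difference


def _grid(setting: SimulationSetting) -> np.ndarray:
    b = setting.base
    lo = b.M1 - setting.window_pad
    hi = setting.M2 + (setting.L - 1) * b.S + setting.window_pad
    n = int(math.floor((hi - lo) / setting.grid_spacing)) + 1
    if n < 2:
        raise ValueError("window too narrow to cover both envelopes")
    return lo + setting.grid_spacing * np.arange(n)


def _states(setting: SimulationSetting) -> tuple[list[PeptideState], SharedState]:
    b = setting.base
    r1 = ratio_set(setting.ratio_codes[0], b.M1, setting.L).values
    r2 = ratio_set(setting.ratio_codes[1], setting.M2, setting.L).values
    peptides = [
        PeptideState(M=b.M1, H=b.H1, R=r1, odds=float(r1[1:].sum())),
        PeptideState(
            M=setting.M2,
            H=setting.rel_abundance * b.H1,
            R=r2,
            odds=float(r2[1:].sum()),
        ),
    ]
    if setting.shape_kind == "asymmetric_laplace":
        shape = ShapeParams("asymmetric_laplace", b.sigma_s, 0.85)
    else:
        shape = ShapeParams("normal", b.sigma_s)
    shared = SharedState(S=b.S, sigma=b.sigma, shape=shape)
    return peptides, shared


def generate_spectrum(setting: SimulationSetting) -> tuple[SpectrumWindow, dict]:
    """Simulate one window plus a ground-truth manifest.

    The manifest records every generative parameter (including the realized
    ratio vectors and the noise seed), so :func:`spectrum_from_manifest`
    reproduces the spectrum bit-exactly.
    """
    x = _grid(setting)
    peptides, shared = _states(setting)
    window0 = SpectrumWindow(x=x, y=np.zeros_like(x))
    mean = mean_intensity(peptides, shared, window0)
    rng = np.random.default_rng(setting.seed)
    noise = rng.normal(0.0, setting.base.sigma, x.size) if setting.base.sigma > 0 else 0.0
    window = SpectrumWindow(x=x, y=mean + noise)
    b = setting.base
    manifest = {
        "setting_id": setting.setting_id,
        "shift": setting.shift,
        "tilt": setting.tilt,
        "rel_abundance": setting.rel_abundance,
        "ratio_codes": list(setting.ratio_codes),
        "M1": b.M1,
        "M2": setting.M2,
        "H1": b.H1,
        "H2": setting.rel_abundance * b.H1,
        "sigma": b.sigma,
        "sigma_s": b.sigma_s,
        "S": b.S,
        "shape_kind": setting.shape_kind,
        "L": setting.L,
        "grid_spacing": setting.grid_spacing,
        "window_pad": setting.window_pad,
        "seed": setting.seed,
        "n_points": int(x.size),
        "x_start": float(x[0]),
        "R1": [float(v) for v in peptides[0].R],
        "R2": [float(v) for v in peptides[1].R],
    }
    return window, manifest


def spectrum_from_manifest(manifest: dict) -> SpectrumWindow:
    """Regenerate a simulated spectrum bit-exactly from its manifest."""
    setting = SimulationSetting(
        shift=manifest["shift"],
        tilt=manifest["tilt"],
        rel_abundance=manifest["rel_abundance"],
        ratio_codes=tuple(manifest["ratio_codes"]),
        base=BaseParams(
            M1=manifest["M1"],
            H1=manifest["H1"],
            sigma=manifest["sigma"],
            sigma_s=manifest["sigma_s"],
            S=manifest["S"],
        ),
        grid_spacing=manifest["grid_spacing"],
        window_pad=manifest["window_pad"],
        L=manifest["L"],
        seed=manifest["seed"],
        shape_kind=manifest["shape_kind"],
        setting_id=manifest.get("setting_id"),
    )
    window, _ = generate_spectrum(setting)
    return window


# (shift, tilt, H2/H1, ratio code peptide 1, ratio code peptide 2) per setting
_CATALOG = [
    (0, 0.04, 0.2, "E1", "E2"),
    (0, 0.04, 5.0, "E1", "E2"),
    (1, 0.04, 0.2, "A", "A"),
    (1, 0.04, 5.0, "A", "A"),
    (0, 0.16, 0.5, "E2", "A"),
    (0, 0.16, 2.0, "E2", "A"),
    (1, 0.16, 0.5, "A", "E1"),
    (1, 0.16, 2.0, "A", "E1"),
    (0, 0.24, 1.0, "E2", "E1"),
    (1, 0.24, 1.0, "E1", "E1"),
    (0, 0.24, 2.0, "E2", "A"),
    (0, 0.16, 0.2, "E1", "E2"),
    (0, 0.16, 5.0, "E1", "E2"),
    (1, 0.16, 0.2, "A", "A"),
    (0, 0.04, 0.5, "E2", "A"),
    (1, 0.04, 0.5, "A", "E1"),
    (1, 0.04, 2.0, "A", "E1"),
    (0, 0.04, 1.0, "E2", "E1"),
    (0, 0.16, 1.0, "E2", "E1"),
    (1, 0.04, 1.0, "E1", "E1"),
    (4, 0.04, 0.2, "A", "A"),
    (4, 0.04, 5.0, "A", "A"),
    (6, 0.04, 0.2, "E1", "E2"),
    (6, 0.04, 5.0, "E1", "E2"),
    (4, 0.16, 0.5, "A", "E1"),
    (4, 0.16, 2.0, "A", "E1"),
    (6, 0.16, 0.5, "E2", "A"),
    (6, 0.16, 2.0, "E2", "A"),
    (4, 0.24, 1.0, "E2", "E2"),
    (6, 0.24, 1.0, "E2", "E1"),
]


def settings_catalog(seed: int = 0) -> list[SimulationSetting]:
    """The 30 settings of the simulation study (ids 1..30)."""
    return [
        SimulationSetting(
            shift=shift,
            tilt=tilt,
            rel_abundance=rel,
            ratio_codes=(c1, c2),
            seed=seed,
            setting_id=i + 1,
        )
        for i, (shift, tilt, rel, c1, c2) in enumerate(_CATALOG)
    ]


def get_setting(setting_id: int, seed: int = 0) -> SimulationSetting:
    """Setting by catalog id (1-based)."""
    if not 1 <= setting_id <= len(_CATALOG):
        raise ValueError(f"setting id must be in 1..{len(_CATALOG)}, got {setting_id}")
    return settings_catalog(seed=seed)[setting_id - 1]


def replicate_study(
    setting_ids,
    n_reps: int,
    sampler_config=None,
    seed: int = 0,
    fit_L: int | None = None,
    **fit_kwargs,
):
    """Simulate ``n_reps`` spectra per setting, fit each by BMA, and report recovery.

    Returns a long-format DataFrame with one row per (setting, replicate,
    parameter) giving truth, model-averaged estimate, standard error, 95%
    interval and whether the interval covers the truth.  ``n_reps = 0``
    yields an empty report.
    """
    import pandas as pd

    from .isotopic_prior import default_n_isotopes
    from .model_averaging import fit_bma
    from .model_core import ModelConfig
    from .sampler import SamplerConfig

    scfg = sampler_config or SamplerConfig()
    rows = []
    for si, sid in enumerate(setting_ids):
        setting = get_setting(sid) if isinstance(sid, (int, np.integer)) else sid
        sid_label = setting.setting_id if setting.setting_id is not None else f"custom{si}"
        L = fit_L or default_n_isotopes(setting.base.M1)
        config = ModelConfig(Q=2, L=L, shape_kind="normal")
        for rep in range(n_reps):
            sim_seed = (seed + 7919 * si + 104729 * rep + 1) % (2**31 - 1)
            window, manifest = generate_spectrum(replace(setting, seed=sim_seed))
            fit = fit_bma(
                window,
                config,
                sampler_config=replace(scfg, seed=(sim_seed + 7) % (2**31 - 1)),
                **fit_kwargs,
            )
            truths = {
                "M1": manifest["M1"],
                "M2": manifest["M2"],
                "S": manifest["S"],
                "sigma_s": manifest["sigma_s"],
                "sigma": manifest["sigma"],
                "H1": manifest["H1"],
                "H2": manifest["H2"],
                "relH2": manifest["rel_abundance"],
            }
            est = fit.estimates
            for param, truth in truths.items():
                if param not in est.index:
                    continue
                row = est.loc[param]
                rows.append(
                    {
                        "setting": sid_label,
                        "rep": rep,
                        "param": param,
                        "truth": truth,
                        "estimate": float(row["mean"]),
                        "se": float(row["se"]),
                        "lo": float(row["lo"]),
                        "hi": float(row["hi"]),
                        "covered": bool(row["lo"] <= truth <= row["hi"]),
                    }
                )
    columns = ["setting", "rep", "param", "truth", "estimate", "se", "lo", "hi", "covered"]
    return pd.DataFrame(rows, columns=columns)
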