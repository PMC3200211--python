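"""Desk-scale replications of the simulation study.

These workflows regenerate the study's key experiments end to end —
simulate, fit by model averaging, aggregate — at sizes a single CPU handles
in minutes.  Replicate counts and chain lengths are deliberately modest
(10 replicates / 20k iterations for the parameter-recovery experiment,
5-10 replicates / 10k iterations elsewhere); they are this package's
desk-scale defaults, configurable per call.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .model_averaging import fit_bma
from .model_core import ModelConfig
from .isotopic_prior import default_n_isotopes
from .sampler import SamplerConfig
from .simulator import SimulationSetting, generate_spectrum, get_setting, replicate_study

__all__ = [
    "FULL_MCMC",
    "DESK_MCMC",
    "recovery_experiment",
    "tilt_threshold_experiment",
    "bic_selection_experiment",
    "uncertainty_experiment",
]

#: Chain length for the parameter-recovery experiment.
FULL_MCMC = SamplerConfig(n_iter=20000, burn_in=5000, thin=5)

#: Shorter chains for the larger experiment grids.
DESK_MCMC = SamplerConfig(n_iter=10000, burn_in=2500, thin=5)


def recovery_experiment(
    setting_id: int = 22,
    n_reps: int = 10,
    sampler_config: SamplerConfig | None = None,
    seed: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Parameter recovery on replicates of one study setting.

    Returns the per-replicate recovery table and a summary dict mapping each
    parameter to its replicate-averaged model-averaged posterior mean, the
    generative truth, and the 95%-interval coverage fraction.
    """
    scfg = sampler_config or FULL_MCMC
    table = replicate_study([setting_id], n_reps, sampler_config=scfg, seed=seed)
    summary = {}
    for param, grp in table.groupby("param"):
        summary[param] = {
            "mean_estimate": float(grp["estimate"].mean()),
            "truth": float(grp["truth"].iloc[0]),
            "coverage": float(grp["covered"].mean()),
            "mean_ci_width": float((grp["hi"] - grp["lo"]).mean()),
            "n_reps": int(len(grp)),
        }
    return table, summary


def _grid_setting(tilt: float, rel: float) -> SimulationSetting:
    # complete-overlap grid (shift 0); E1/E2 codes follow the neighbouring
    # catalog cells with the same layout
    return SimulationSetting(shift=0, tilt=tilt, rel_abundance=rel, ratio_codes=("E1", "E2"))


def tilt_threshold_experiment(
    tilts=(0.04, 0.16, 0.24),
    rel_abundances=(0.2, 5.0),
    n_reps: int = 5,
    sampler_config: SamplerConfig | None = None,
    seed: int = 1,
    recovery_tol: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Separability of two completely overlapping peptides as tilt grows.

    For each (tilt, relative abundance) cell, ``n_reps`` replicates are
    simulated at integer shift 0 and fitted; a replicate *recovers* the
    relative abundance when the model-averaged estimate is within
    ``recovery_tol`` of the truth and its 95% interval excludes zero.  A
    cell passes when at least 60% of replicates recover.  Returns the
    per-replicate table, the per-cell summary, and the smallest tilt from
    which every cell (at that tilt and above) passes (NaN if none).
    """
    scfg = sampler_config or DESK_MCMC
    settings = [
        _grid_setting(tilt, rel) for tilt in sorted(tilts) for rel in rel_abundances
    ]
    table = replicate_study(settings, n_reps, sampler_config=scfg, seed=seed)
    need = math.ceil(0.6 * n_reps)
    cells = []
    for i, setting in enumerate(settings):
        grp = table[(table["setting"] == f"custom{i}") & (table["param"] == "relH2")]
        truth = setting.rel_abundance
        ok = (np.abs(grp["estimate"] - truth) <= recovery_tol * truth) & (grp["lo"] > 0)
        cells.append(
            {
                "tilt": setting.tilt,
                "rel_abundance": truth,
                "n_recovered": int(ok.sum()),
                "n_reps": int(len(grp)),
                "passed": bool(ok.sum() >= need),
            }
        )
    cell_df = pd.DataFrame(cells)
    threshold = math.nan
    for tilt in sorted(tilts, reverse=True):
        sub = cell_df[cell_df["tilt"] >= tilt - 1e-12]
        if bool(sub["passed"].all()):
            threshold = float(tilt)
        else:
            break
    return table, cell_df, threshold


def bic_selection_experiment(
    setting_id: int = 26,
    n_reps: int = 10,
    sampler_config: SamplerConfig | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Model-size check: does BIC prefer the true Q = 2 over Q = 3?

    Each replicate of a two-peptide setting is fitted assuming two and three
    peptides.  Reports both BICs, whether Q = 2 is preferred, and the
    abundance of the spurious third peptide (the fitted peptide left over
    after matching the two true masses by proximity) as a fraction of the
    abundance matched to the second true peptide.
    """
    scfg = sampler_config or DESK_MCMC
    setting = get_setting(setting_id)
    L = default_n_isotopes(setting.base.M1)
    rows = []
    for rep in range(n_reps):
        sim_seed = (seed + 104729 * rep + 11) % (2**31 - 1)
        window, manifest = generate_spectrum(replace(setting, seed=sim_seed))
        fits = {}
        for q in (2, 3):
            cfg = ModelConfig(Q=q, L=L, shape_kind="normal")
            fits[q] = fit_bma(
                window,
                cfg,
                sampler_config=replace(scfg, seed=(sim_seed + 7 + 1000 * q) % (2**31 - 1)),
            )
        est3 = fits[3].estimates["mean"]
        masses3 = np.array([est3[f"M{q}"] for q in (1, 2, 3)])
        hs3 = np.array([est3[f"H{q}"] for q in (1, 2, 3)])
        match1 = int(np.argmin(np.abs(masses3 - manifest["M1"])))
        remaining = [i for i in range(3) if i != match1]
        match2 = remaining[int(np.argmin(np.abs(masses3[remaining] - manifest["M2"])))]
        spurious = next(i for i in range(3) if i not in (match1, match2))
        frac = float(hs3[spurious] / hs3[match2]) if hs3[match2] > 0 else math.inf
        rows.append(
            {
                "rep": rep,
                "bic_q2": fits[2].bic,
                "bic_q3": fits[3].bic,
                "prefers_q2": bool(fits[2].bic < fits[3].bic),
                "spurious_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def uncertainty_experiment(
    difficult_id: int = 3,
    easy_id: int = 30,
    n_reps: int = 5,
    sampler_config: SamplerConfig | None = None,
    seed: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Interval width as a difficulty indicator.

    Compares the model-averaged 95% interval for the relative abundance
    between a difficult setting (near-complete overlap) and an easy one
    (well-separated envelopes).  Wide intervals reaching down to small
    values flag windows where the second peptide is not reliably
    quantifiable.
    """
    scfg = sampler_config or DESK_MCMC
    table = replicate_study([difficult_id, easy_id], n_reps, sampler_config=scfg, seed=seed)
    rel = table[table["param"] == "relH2"]
    out = {}
    for sid, label in ((difficult_id, "difficult"), (easy_id, "easy")):
        grp = rel[rel["setting"] == sid]
        out[label] = {
            "setting": sid,
            "mean_ci_width": float((grp["hi"] - grp["lo"]).mean()),
            "min_ci_lo": float(grp["lo"].min()),
            "truth": float(grp["truth"].iloc[0]),
        }
    return table, out
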