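"""Result serialization: fit reports, overlays, chain exports.

The fit report is a single JSON document with a ``method`` block describing
in plain words how each quantity was obtained, one block per candidate
model (mass prior, DIC, BIC, weight, posterior summaries), and the
model-averaged estimates with standard errors and 95% intervals.  Numbers
are serialized at full double precision.
"""

from __future__ import annotations

import json

import numpy as np

from .model_averaging import AveragedResult, averaged_mean_spectrum
from .model_core import SpectrumWindow

__all__ = ["report_dict", "write_report", "validate_report", "write_fit_overlay"]

#: Keys every fit report must carry (shipped schema, checked by validate_report).
REPORT_REQUIRED_KEYS = ("package", "version", "seed", "model", "method", "candidates", "averaged")

_METHOD_BLOCK = {
    "estimates": "model-averaged posterior means: weighted average of the "
    "per-candidate posterior means with DIC-based weights",
    "weights": "w_g proportional to exp(-DIC_g / 2), normalized over candidates",
    "standard_errors": "weighted combination of within-candidate posterior SDs "
    "and between-candidate disagreement",
    "intervals": "95% normal approximation: estimate +/- 1.96 standard errors",
    "dic": "posterior mean deviance plus effective parameter count "
    "(mean deviance minus deviance at the posterior mean)",
    "bic": "deviance at the posterior mean plus (number of free parameters) "
    "times log(number of grid points)",
}


def report_dict(result: AveragedResult) -> dict:
    """Serializable report for one model-averaged fit."""
    from . import __version__

    cfg = result.config
    candidates = []
    for cand in result.per_candidate:
        candidates.append(
            {
                "mass_priors": [{"eta": e, "sigma_m": s} for e, s in cand.mass_priors],
                "dic": cand.dic,
                "bic": cand.bic,
                "weight": cand.weight,
                "p_d": cand.chain.p_d,
                "seed": cand.chain.seed,
                "acceptance_rates": {
                    k: float(v) for k, v in cand.chain.acceptance_rates.items()
                },
                "summaries": cand.chain.summary_dict(),
            }
        )
    averaged = {
        name: {
            "mean": float(row["mean"]),
            "se": float(row["se"]),
            "ci95": [float(row["lo"]), float(row["hi"])],
        }
        for name, row in result.estimates.iterrows()
    }
    return {
        "package": "overlapfit",
        "version": __version__,
        "seed": int(result.seed),
        "model": {
            "Q": cfg.Q,
            "L": cfg.L,
            "shape": cfg.shape_kind,
            "constraint": (
                None
                if cfg.constraint is None
                else {"offset_multiple": cfg.constraint.offset_multiple}
            ),
        },
        "method": dict(_METHOD_BLOCK),
        "candidates": candidates,
        "averaged": averaged,
    }


def write_report(result: AveragedResult, path) -> dict:
    d = report_dict(result)
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")
    return d


def validate_report(d: dict) -> None:
    """Raise ``ValueError`` if a report is missing required structure."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in d:
            raise ValueError(f"report missing required key {key!r}")
    if not d["candidates"]:
        raise ValueError("report has no candidate models")
    for cand in d["candidates"]:
        for key in ("mass_priors", "dic", "weight", "summaries"):
            if key not in cand:
                raise ValueError(f"candidate block missing {key!r}")
    for name, block in d["averaged"].items():
        if set(block) != {"mean", "se", "ci95"}:
            raise ValueError(f"averaged block for {name!r} malformed")


def write_fit_overlay(result: AveragedResult, window: SpectrumWindow, path) -> None:
    """Write mass / observed / fitted columns (observed-vs-predicted overlay)."""
    fitted = averaged_mean_spectrum(result, window)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("mass\tobserved\tfitted\n")
        for xv, yv, fv in zip(window.x, window.y, np.asarray(fitted)):
            fh.write(f"{float(xv)!r}\t{float(yv)!r}\t{float(fv)!r}\n")
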