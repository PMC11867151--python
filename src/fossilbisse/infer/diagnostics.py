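"""MCMC convergence diagnostics.

The effective sample size uses arviz's rank-normalised bulk estimator
(recorded in the convergence report); analyses with any parameter below
the ESS threshold (default 200, the study's inclusion rule) are flagged
rather than silently included.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import arviz as az
import numpy as np

from .mcmc import PosteriorTrace

__all__ = ["effective_sample_size", "convergence_report"]

ESS_ESTIMATOR = "arviz.ess (bulk, rank-normalised)"


def effective_sample_size(series) -> float:
    """Autocorrelation-adjusted effective sample size of one trace series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 10:
        raise ValueError("series too short for an ESS estimate (need >= 10)")
    if np.allclose(x, x[0]):
        warnings.warn("constant series: ESS reported as series length", stacklevel=2)
        return float(x.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(x[None, :]))
    return ess


def convergence_report(
    trace: PosteriorTrace, threshold: float = 200.0, path: Path | None = None
) -> dict:
    """ESS per parameter plus acceptance rates; flags ESS below threshold."""
    ess = {p: effective_sample_size(trace.df[p].to_numpy()) for p in trace.parameters}
    flagged = sorted(p for p, e in ess.items() if e < threshold)
    report = {
        "estimator": ESS_ESTIMATOR,
        "threshold": threshold,
        "ess": ess,
        "flagged": flagged,
        "converged": not flagged,
        "acceptance": trace.meta.get("acceptance", {}),
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
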