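"""Posterior summaries across replicate analyses.

An *analysis set* is a group of replicate analyses sharing identical
simulation and inference settings. From each trace we take posterior
means and equal-tailed 95% credible intervals; across a set we compute
coverage proportions, relative errors (signed and absolute), posterior
probabilities of rate inequalities, the turnover/extinction-fraction
reparameterisation, and ROC curves for the trait-association tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infer.mcmc import PosteriorTrace

__all__ = [
    "summarize_trace",
    "coverage_proportion",
    "relative_error",
    "prob_greater",
    "derived_transforms",
    "roc_points",
    "AnalysisSetSummary",
    "summarize_analysis_set",
]


def summarize_trace(trace: PosteriorTrace | pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval per parameter.

    Equal-tailed (2.5%/97.5% quantile) intervals are used rather than
    HPD; the interval rule is recorded in the output for downstream
    schema stability.
    """
    df = trace.df if isinstance(trace, PosteriorTrace) else trace
    params = (
        trace.parameters
        if isinstance(trace, PosteriorTrace)
        else [c for c in df.columns if c not in ("iteration", "logprior", "loglik", "logpost")]
    )
    if len(df) == 0:
        raise ValueError("empty trace")
    rows = []
    for p in params:
        x = df[p].to_numpy(dtype=float)
        lo, hi = np.quantile(x, [0.025, 0.975])
        rows.append((p, float(x.mean()), float(lo), float(hi)))
    out = pd.DataFrame(rows, columns=["parameter", "mean", "lower95", "upper95"])
    out.attrs["interval"] = "equal-tailed"
    return out


def coverage_proportion(intervals, truth: float) -> float:
    """Fraction of (lower, upper) intervals containing the truth.

    Endpoints are closed: truth exactly on a bound counts as covered.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("need at least one interval")
    hit = sum(1 for lo, hi in intervals if lo <= truth <= hi)
    return hit / len(intervals)


def relative_error(posterior_mean: float, truth: float) -> tuple[float, float]:
    """(absolute, signed) relative error of a posterior mean.

    The absolute form |mean - truth| / truth is the study's headline
    statistic; the signed form (mean - truth) / truth preserves the
    direction (under- vs over-estimation) and is reported alongside.
    """
    if truth <= 0:
        raise ValueError("truth must be > 0")
    signed = (posterior_mean - truth) / truth
    return abs(signed), signed


def prob_greater(trace: PosteriorTrace | pd.DataFrame, a: str, b: str) -> float:
    """Posterior probability P(a > b); exact ties count 1/2 each."""
    df = trace.df if isinstance(trace, PosteriorTrace) else trace
    for p in (a, b):
        if p not in df.columns:
            raise KeyError(f"parameter {p!r} not in trace")
    xa = df[a].to_numpy(dtype=float)
    xb = df[b].to_numpy(dtype=float)
    return float((np.sum(xa > xb) + 0.5 * np.sum(xa == xb)) / xa.size)


def derived_transforms(trace: PosteriorTrace | pd.DataFrame) -> pd.DataFrame:
    """Samplewise turnover tau_i = lambda_i + mu_i and extinction fraction
    eps_i = mu_i / lambda_i.

    Samples with lambda_i = 0 leave eps undefined and are dropped for
    that column (count recorded in ``attrs['eps_dropped']``). The
    samplewise transform is primary; summarising the transformed trace
    differs in general from transforming summaries.
    """
    df = trace.df if isinstance(trace, PosteriorTrace) else trace
    out = pd.DataFrame(index=df.index)
    dropped = 0
    for i in (0, 1):
        lam = df[f"lambda{i}"].to_numpy(dtype=float)
        mu = df[f"mu{i}"].to_numpy(dtype=float)
        out[f"tau{i}"] = lam + mu
        eps = np.full_like(lam, np.nan)
        ok = lam > 0
        dropped += int(np.sum(~ok))
        eps[ok] = mu[ok] / lam[ok]
        out[f"eps{i}"] = eps
    out.attrs["eps_dropped"] = dropped
    return out


def roc_points(effect_probs, null_probs) -> pd.DataFrame:
    """ROC curve for the trait-association test statistic.

    ``effect_probs`` are posterior inequality probabilities from analyses
    where the association is real (positives); ``null_probs`` from
    neutral-trait or equal-rate analyses (negatives). Thresholds sweep the
    union of observed values; the curve runs from (0, 0) to (1, 1) and
    the trapezoid area is stored in ``attrs['auc']``.
    """
    pos = np.asarray(list(effect_probs), dtype=float)
    neg = np.asarray(list(null_probs), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both probability sets must be non-empty")
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1], [-np.inf]))
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    df = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    df.attrs["auc"] = float(np.trapezoid(df["tpr"], df["fpr"]))
    return df


@dataclass
class AnalysisSetSummary:
    """Per-parameter roll-up of one analysis set."""

    table: pd.DataFrame  # one row per analysis x parameter
    truth: dict[str, float]
    inequality: str | None = None
    inequality_probs: list[float] = field(default_factory=list)

    def coverage(self, parameter: str) -> float:
        sub = self.table[self.table["parameter"] == parameter]
        return coverage_proportion(
            zip(sub["lower95"], sub["upper95"]), self.truth[parameter]
        )

    def relative_errors(self, parameter: str, signed: bool = True) -> np.ndarray:
        sub = self.table[self.table["parameter"] == parameter]
        col = "rel_error_signed" if signed else "rel_error_abs"
        return sub[col].to_numpy(dtype=float)

    def rollup(self) -> pd.DataFrame:
        rows = []
        for p in self.table["parameter"].unique():
            if p not in self.truth or self.truth[p] <= 0:
                continue
            rows.append(
                {
                    "parameter": p,
                    "truth": self.truth[p],
                    "coverage": self.coverage(p),
                    "median_rel_error_signed": float(np.median(self.relative_errors(p))),
                    "median_rel_error_abs": float(
                        np.median(self.relative_errors(p, signed=False))
                    ),
                }
            )
        return pd.DataFrame(rows)


def summarize_analysis_set(
    traces: list[PosteriorTrace],
    truth: dict[str, float],
    inequality: tuple[str, str] | None = None,
) -> AnalysisSetSummary:
    """Summarise a group of replicate analyses against their true rates."""
    rows = []
    probs = []
    for i, tr in enumerate(traces):
        s = summarize_trace(tr)
        for _, r in s.iterrows():
            p = r["parameter"]
            row = {
                "analysis": i,
                "parameter": p,
                "mean": r["mean"],
                "lower95": r["lower95"],
                "upper95": r["upper95"],
            }
            if p in truth and truth[p] > 0:
                abs_e, signed_e = relative_error(r["mean"], truth[p])
                row["rel_error_abs"] = abs_e
                row["rel_error_signed"] = signed_e
                row["covered"] = bool(r["lower95"] <= truth[p] <= r["upper95"])
            rows.append(row)
        if inequality is not None:
            probs.append(prob_greater(tr, *inequality))
    return AnalysisSetSummary(
        table=pd.DataFrame(rows),
        truth=dict(truth),
        inequality=None if inequality is None else f"{inequality[0]}>{inequality[1]}",
        inequality_probs=probs,
    )
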