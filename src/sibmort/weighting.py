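"""Post-stratification weighting by capped raking.

Iterative proportional fitting (raking) rescales respondent weights until
the weighted marginal share of each category of each weighting variable
matches an external target distribution. Phone-survey samples are raked to
a reference population (a recent census, DHS or MICS); to bound the
variance cost, weights are capped (default 2) after each full cycle and
iteration continues — margins then match as closely as the cap allows, and
the residual deviation is reported rather than hidden.

Weights are normalised to mean 1; with a binding cap the final
normalisation solves for the scale at which the capped weights average 1,
so the cap and the mean-1 convention hold simultaneously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WeightSolution", "rake", "combine_strata", "composition_report",
           "validate_targets"]


@dataclass
class WeightSolution:
    """Result of a raking run."""

    weights: pd.Series
    iterations: int
    max_deviation: float
    n_capped: int
    converged: bool
    messages: list = field(default_factory=list)


def validate_targets(sample: pd.DataFrame, targets: dict) -> None:
    """Check target proportions sum to 1 and cover every sample category."""
    for var, cats in targets.items():
        if var not in sample.columns:
            raise ValueError(f"weighting variable {var!r} not in sample")
        total = sum(cats.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target proportions for {var!r} sum to {total}, not 1")
        sample_cats = set(sample[var].unique())
        missing = sample_cats - set(cats)
        if missing:
            raise ValueError(f"no target proportion for {var!r} categories {sorted(missing)}")
        for cat, prop in cats.items():
            if prop > 0 and cat not in sample_cats:
                raise ValueError(
                    f"target category {var!r}={cat!r} has proportion {prop} "
                    "but no sample member")


def _max_margin_deviation(w, sample, targets):
    dev = 0.0
    total = w.sum()
    for var, cats in targets.items():
        shares = w.groupby(sample[var], observed=True).sum() / total
        for cat, target in cats.items():
            dev = max(dev, abs(shares.get(cat, 0.0) - target))
    return dev


def _normalise_capped(w: np.ndarray, cap: float) -> np.ndarray:
    """Scale s so that mean(min(s*w, cap)) = 1, then clip; bisection."""
    if np.mean(w) == 0:
        raise ValueError("degenerate zero weights")
    lo, hi = 0.0, cap / np.min(w) if np.min(w) > 0 else 1e12
    for _ in range(200):
        s = 0.5 * (lo + hi)
        m = np.minimum(s * w, cap).mean()
        if m < 1.0:
            lo = s
        else:
            hi = s
    return np.minimum(0.5 * (lo + hi) * w, cap)


def rake(respondents: pd.DataFrame, targets: dict, cap: float = 2.0,
         tol: float = 1e-6, max_iter: int = 100,
         initial: str | None = "design_weight") -> WeightSolution:
    """Rake respondent weights to marginal targets with a hard cap.

    Parameters
    ----------
    respondents : DataFrame
        Must carry every weighting variable in ``targets`` as a column.
    targets : dict
        ``{variable: {category: target proportion}}``.
    cap : float
        Maximum weight (on the mean-1 scale). ``np.inf`` disables capping.
    tol, max_iter
        Stop when the largest absolute deviation of a weighted category
        share from its target falls below ``tol``, or after ``max_iter``
        full cycles (a warning is issued and the residual reported — with a
        binding cap some residual is expected behaviour).
    initial : column name or None
        Starting weights (design weights); None starts from 1.
    """
    validate_targets(respondents, targets)
    if np.isfinite(cap) and cap <= 1.0:
        raise ValueError("cap must exceed 1 (weights are normalised to mean 1)")
    n = len(respondents)
    if initial is not None and initial in respondents.columns:
        w = respondents[initial].to_numpy(float).copy()
    else:
        w = np.ones(n)
    w /= w.mean()
    messages = []
    dev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for var, cats in targets.items():
            col = respondents[var]
            shares = pd.Series(w).groupby(col.reset_index(drop=True),
                                          observed=True).sum() / w.sum()
            factor = col.map({c: t / shares.get(c, np.nan)
                              for c, t in cats.items()}).to_numpy(float)
            w *= np.where(np.isfinite(factor), factor, 1.0)
        w /= w.mean()
        if np.isfinite(cap):
            w = np.minimum(w, cap)
        dev = _max_margin_deviation(pd.Series(w), respondents.reset_index(drop=True),
                                    targets)
        if dev < tol:
            break
    w = _normalise_capped(w, cap) if np.isfinite(cap) else w / w.mean()
    dev = _max_margin_deviation(pd.Series(w), respondents.reset_index(drop=True), targets)
    converged = bool(dev < tol)
    if not converged:
        msg = (f"raking stopped after {it} cycle(s) with residual margin "
               f"deviation {dev:.3g} (cap={cap}); with a binding cap residual "
               "deviations are expected")
        warnings.warn(msg)
        messages.append(msg)
    return WeightSolution(
        weights=pd.Series(w, index=respondents.index, name="ps_weight"),
        iterations=it,
        max_deviation=float(dev),
        n_capped=int(np.sum(w >= cap * (1 - 1e-12))) if np.isfinite(cap) else 0,
        converged=converged,
        messages=messages,
    )


def combine_strata(solutions: dict, shares: dict) -> pd.Series:
    """Combine per-stratum weights using population stratum shares.

    Each stratum's weights are rescaled so its share of the total weight
    equals its population share; the result has mean 1 overall.
    """
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("stratum shares must sum to 1")
    missing = set(shares) - set(solutions)
    if missing:
        raise ValueError(f"missing weight solutions for strata: {sorted(missing)}")
    parts = []
    n_total = sum(len(s.weights if isinstance(s, WeightSolution) else s)
                  for s in solutions.values())
    for stratum, share in shares.items():
        sol = solutions[stratum]
        w = sol.weights if isinstance(sol, WeightSolution) else sol
        scaled = w * (share * n_total / w.sum())
        parts.append(scaled)
    combined = pd.concat(parts)
    return combined / combined.mean()


def composition_report(sample: pd.DataFrame, targets: dict,
                       weights: pd.Series | None = None,
                       tol: float = 1e-6) -> pd.DataFrame:
    """Category shares before/after weighting vs targets.

    Returns one row per (variable, category) with unweighted and weighted
    shares, the gaps to target, and a ``residual`` flag for categories whose
    weighted share still deviates by more than ``tol`` (a capped raking run
    leaves such categories).
    """
    if weights is None:
        weights = pd.Series(1.0, index=sample.index)
    rows = []
    for var, cats in targets.items():
        unw = sample[var].value_counts(normalize=True)
        wsh = weights.groupby(sample[var], observed=True).sum() / weights.sum()
        for cat, target in cats.items():
            u = float(unw.get(cat, 0.0))
            ww = float(wsh.get(cat, 0.0))
            rows.append({
                "variable": var, "category": cat, "target": target,
                "share_unweighted": u, "share_weighted": ww,
                "gap_unweighted": u - target, "gap_weighted": ww - target,
                "residual": abs(ww - target) > tol,
            })
    return pd.DataFrame(rows)
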