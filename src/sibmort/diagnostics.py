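"""Data-quality diagnostics for sibling histories.

Three families of checks flag the distortions that shortened phone
interviews introduce: per-age-group summaries of reported sibship size,
survival and recency of deaths (omission shows up as inflated survival
and a deficit of recent deaths); Myers' blended index of terminal-digit
preference in reported ages (age heaping); and signed relative bias
between an estimate and a reference level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import age_group_label, details_death_cmc

__all__ = ["MyersResult", "myers_index", "quality_table", "relative_bias"]


@dataclass
class MyersResult:
    """Myers' blended index on the 0-90 scale.

    0 means reported ages are uniform over terminal digits; 90 means every
    age ends in a single digit. ``blended_pct[d]`` is the blended share (%)
    of ages ending in digit d; the index is half the sum of absolute
    deviations from 10%.
    """

    index: float
    blended_pct: np.ndarray
    age_range: tuple


def myers_index(ages, age_range=(10, 89)) -> MyersResult:
    """Myers' blended method for terminal-digit preference.

    For each terminal digit d, ages are summed over all decades starting
    from two successive origins (the range start, and one decade up); the
    two sums are blended with weights (d+1) and (9-d), which makes a
    digit-uniform population contribute exactly 10% per digit.

    ``age_range`` must be decade-aligned and span at least two decades.
    """
    lo, hi = age_range
    if lo % 10 != 0 or (hi + 1) % 10 != 0 or hi - lo < 19:
        raise ValueError("age range must be decade-aligned, e.g. (10, 89)")
    ages = np.asarray(ages)
    ages = ages[(ages >= lo) & (ages <= hi)]
    if len(ages) == 0:
        raise ValueError("no ages in range")
    counts = np.bincount(ages.astype(int) - lo, minlength=hi - lo + 1)
    n_dec = (hi + 1 - lo) // 10
    by_decade = counts.reshape(n_dec, 10)
    digits = np.arange(10)
    s1 = by_decade[:-1].sum(axis=0)          # decades lo .. hi-19
    s2 = by_decade[1:].sum(axis=0)           # shifted one decade up
    blended = (digits + 1) * s1 + (9 - digits) * s2
    pct = 100.0 * blended / blended.sum()
    return MyersResult(index=float(0.5 * np.abs(pct - 10.0).sum()),
                       blended_pct=pct, age_range=(lo, hi))


def quality_table(data, respondents, recency_window_months=36,
                  weights=None, details=None) -> pd.DataFrame:
    """Reporting-quality summary by respondent 5-year age group.

    ``data`` is either a full sibling table or a summary-SSH table (then
    ``details`` supplies the recent-death rows). Returns, per age group:
    mean siblings ever born, proportion of siblings surviving, and the
    proportion of deceased siblings whose death falls within the recency
    window before the interview — each weighted and unweighted. Cells
    without deceased siblings have NaN recent-death proportions.
    """
    resp = respondents.set_index("respondent_id")
    if weights is None:
        wmap = pd.Series(1.0, index=resp.index)
    else:
        wmap = pd.Series(np.asarray(weights, float),
                         index=respondents["respondent_id"])

    if "alive" in data.columns:  # full sibling table
        s = data.copy()
        interview = s["respondent_id"].map(resp["interview_cmc"])
        recent = (~s["alive"].astype(bool)
                  & (s["death_cmc"] >= interview - recency_window_months))
        per = pd.DataFrame({
            "n_ever": s.groupby("respondent_id").size(),
            "n_alive": s.groupby("respondent_id")["alive"].sum().astype(int),
            "n_recent": recent.groupby(s["respondent_id"]).sum().astype(int),
        })
    else:  # summary form
        per = data.set_index("respondent_id")[["n_ever", "n_alive"]].copy()
        if details is not None and len(details):
            d = details.copy()
            cmc = details_death_cmc(d)
            interview = d["respondent_id"].map(resp["interview_cmc"]).to_numpy()
            rec = pd.Series(cmc >= interview - recency_window_months,
                            index=d["respondent_id"])
            per["n_recent"] = rec.groupby(level=0).sum().reindex(per.index)
        per["n_recent"] = per.get("n_recent", pd.Series(0, index=per.index)).fillna(0)

    per = per.reindex(resp.index).fillna(0).astype(int)
    per["n_dead"] = per["n_ever"] - per["n_alive"]
    per["age_group"] = age_group_label(resp["age_years"].to_numpy(int))
    per["w"] = wmap

    rows = []
    for ag, g in per.groupby("age_group"):
        w = g["w"].to_numpy()
        rows.append({
            "age_group": ag,
            "n_respondents": len(g),
            "mean_siblings": g["n_ever"].mean(),
            "mean_siblings_w": np.average(g["n_ever"], weights=w),
            "prop_surviving": g["n_alive"].sum() / g["n_ever"].sum()
            if g["n_ever"].sum() else np.nan,
            "prop_surviving_w": (w * g["n_alive"]).sum() / (w * g["n_ever"]).sum()
            if (w * g["n_ever"]).sum() else np.nan,
            "prop_recent_deaths": g["n_recent"].sum() / g["n_dead"].sum()
            if g["n_dead"].sum() else np.nan,
            "prop_recent_deaths_w": (w * g["n_recent"]).sum() / (w * g["n_dead"]).sum()
            if (w * g["n_dead"]).sum() else np.nan,
        })
    return pd.DataFrame(rows).sort_values("age_group").reset_index(drop=True)


def relative_bias(estimate, reference) -> float:
    """Signed percentage deviation of an estimate from a reference level.

    100 × (estimate − reference) / reference; summaries round to integer
    percent, full precision is returned here. Satisfies
    relative_bias(a, b) = −relative_bias(b, a) · b / a.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (estimate - reference) / reference
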