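"""Independent oracles shared across the test suite.

These deliberately re-derive quantities by the most literal method
available (month-by-month event loops, long-run IPF iteration) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_exposure(siblings, respondents, window, weights=None):
    """Month-by-month event-loop tally of deaths and person-years, 15-49.

    Walks every calendar month in the window for every sibling and adds
    1/12 of the owner's weight to the age group the sibling occupies that
    month; deaths inside the window add the weight to their age group.
    """
    start, end = window
    if weights is None:
        weights = {rid: 1.0 for rid in respondents["respondent_id"]}
    else:
        weights = dict(zip(respondents["respondent_id"], weights))
    D = np.zeros(7)
    PY = np.zeros(7)
    for row in siblings.itertuples(index=False):
        w = weights[row.respondent_id]
        b = int(row.birth_cmc)
        d = int(row.death_cmc) if not row.alive and not pd.isna(row.death_cmc) \
            else None
        for m in range(start, end):
            if m < b:
                continue
            if d is not None and m >= d:
                continue
            age = (m - b) // 12
            if 15 <= age < 50:
                PY[(age - 15) // 5] += w / 12.0
        if d is not None and start <= d < end:
            age = (d - b) // 12
            if 15 <= age < 50:
                D[(age - 15) // 5] += w
    return D, PY


def brute_force_ipf(counts: np.ndarray, row_targets, col_targets, iters=10_000):
    """Plain IPF on a contingency table; returns per-cell weights."""
    w = np.ones_like(counts, dtype=float)
    n = counts.sum()
    for _ in range(iters):
        row_share = (w * counts).sum(axis=1) / (w * counts).sum()
        w *= (np.asarray(row_targets) / row_share)[:, None]
        col_share = (w * counts).sum(axis=0) / (w * counts).sum()
        w *= (np.asarray(col_targets) / col_share)[None, :]
    # normalise to mean weight 1 over individuals
    mean_w = (w * counts).sum() / n
    return w / mean_w


def tv_distance(sample_values, ref_values, ref_probs):
    """Total-variation distance between an empirical sample and a pmf."""
    from collections import Counter
    ref = {v: p for v, p in zip(ref_values, ref_probs)}
    counts = Counter(list(sample_values))
    n = sum(counts.values())
    support = set(ref) | set(counts)
    return 0.5 * sum(abs(counts.get(v, 0) / n - ref.get(v, 0.0))
                     for v in support)


def random_sibling_table(rng, n, interview_cmc):
    """Random sibling rows (some alive, some dead) for oracle comparisons."""
    birth = rng.integers(interview_cmc - 12 * 80, interview_cmc, n)
    alive = rng.random(n) < 0.6
    lifespan = rng.integers(1, 12 * 70, n)
    death = np.minimum(birth + lifespan, interview_cmc - rng.integers(0, 240, n))
    death = np.maximum(death, birth + 1)
    rids = [f"r{i % (n // 4):05d}" for i in range(n)]
    sib = pd.DataFrame({
        "respondent_id": rids,
        "line_no": np.arange(1, n + 1),
        "sex": rng.choice(["m", "f"], n),
        "alive": alive,
        "age_now": np.where(alive, (interview_cmc - birth) // 12, np.nan),
        "age_at_death": np.where(alive, np.nan, (death - birth) // 12),
        "death_cmc": np.where(alive, np.nan, death),
        "birth_cmc": birth.astype(float),
        "imputed_fields": "",
    })
    resp_ids = sorted(set(rids))
    resp = pd.DataFrame({
        "respondent_id": resp_ids,
        "sex": "f",
        "age_years": 30,
        "interview_cmc": interview_cmc,
        "residence": "urban",
        "education": "secondary",
        "hh_size_class": "1-5",
        "design_weight": 1.0,
    })
    return sib, resp
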