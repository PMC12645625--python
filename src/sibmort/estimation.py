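"""Direct estimation of adult mortality from sibling histories.

The direct sibling method counts, within a calendar observation window,
the deaths and person-years contributed by reported siblings in each
5-year age group between 15 and 49. Age-specific rates m_a = D_a / PY_a
are converted to 5-year death probabilities with the mid-interval
actuarial form q_a = 5·m_a / (1 + 2.5·m_a) (deaths assumed to occur
halfway through the interval), chained to the probability of dying
between exact ages 15 and 50,

    35q15 = 1 - prod_a (1 - q_a),

and a delete-one-respondent jackknife supplies the standard error and a
normal-approximation confidence interval. Respondents themselves are
excluded throughout: they are alive by selection, and only their reported
siblings contribute deaths and exposure.

All accumulation is at month resolution on century-month codes, with
half-open conventions: month m counts for a sibling born at b with death
at d when b <= m < min(d, window end); ages fall in [x, x+5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmc import to_cmc

__all__ = [
    "ADULT_AGE_GROUPS", "ExposureTable", "AdultMortalityEstimate",
    "tabulate_exposure", "rates_from_exposure", "q_from_m", "chain_35q15",
    "jackknife_ci", "estimate_35q15", "annual_series", "scale_subnational",
]

#: the seven 5-year age groups spanning exact ages 15-50
ADULT_AGE_GROUPS = [f"{lo}-{lo + 4}" for lo in range(15, 50, 5)]
_N_GROUPS = 7


@dataclass
class ExposureTable:
    """Weighted and unweighted deaths and person-years by 5-year age group."""

    deaths_w: np.ndarray
    person_years_w: np.ndarray
    deaths: np.ndarray
    person_years: np.ndarray
    window: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_group": ADULT_AGE_GROUPS,
            "deaths_weighted": self.deaths_w,
            "person_years_weighted": self.person_years_w,
            "deaths": self.deaths,
            "person_years": self.person_years,
        })


@dataclass
class AdultMortalityEstimate:
    """35q15 with jackknife uncertainty and the underlying schedule."""

    q: float
    se: float
    ci_low: float
    ci_high: float
    window: tuple
    sex: str
    n_deaths: float
    person_years: float
    n_respondents: int
    rates: np.ndarray = field(repr=False, default=None)
    flags: list = field(default_factory=list)


def _resolve_weights(respondents, weights):
    if weights is None:
        return pd.Series(1.0, index=respondents["respondent_id"])
    if isinstance(weights, str):
        return pd.Series(respondents[weights].to_numpy(float),
                         index=respondents["respondent_id"])
    return pd.Series(np.asarray(weights, float), index=respondents["respondent_id"])


def _exposure_arrays(siblings, respondents, window, weights=None, sex="both"):
    """Per-sibling weighted deaths/person-years by age group.

    Returns (resp_codes, resp_ids, D, PY) where D, PY are (n_sib, 7).
    """
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed window start")
    s = siblings
    if sex != "both":
        s = s[s["sex"] == sex]
    if s["birth_cmc"].isna().any():
        raise ValueError("siblings with missing birth_cmc: impute or derive "
                         "birth dates before tabulating exposure")
    dead = ~s["alive"].astype(bool)
    if (dead & s["death_cmc"].isna()).any():
        raise ValueError("deceased siblings with missing death_cmc: impute "
                         "death dates before tabulating exposure")

    wmap = _resolve_weights(respondents, weights)
    w = s["respondent_id"].map(wmap).to_numpy(float)
    b = s["birth_cmc"].to_numpy(float)
    d = np.where(dead, s["death_cmc"].to_numpy(float), np.inf)

    eff_end = np.minimum(float(end), d)
    lo_ages = np.arange(15, 50, 5)
    # months alive in [b + 12*lo, b + 12*(lo+5)) ∩ [start, eff_end)
    a0 = b[:, None] + 12 * lo_ages[None, :]
    a1 = a0 + 60
    months = np.clip(np.minimum(a1, eff_end[:, None])
                     - np.maximum(a0, float(start)), 0, None)
    py = months / 12.0 * w[:, None]

    death_in = dead.to_numpy() & (s["death_cmc"].to_numpy(float) >= start) \
        & (s["death_cmc"].to_numpy(float) < end)
    aad = np.where(death_in, (np.nan_to_num(s["death_cmc"].to_numpy(float)) - b) // 12,
                   -1)
    gidx = ((aad - 15) // 5).astype(int)
    in_range = death_in & (aad >= 15) & (aad < 50)
    D = np.zeros_like(py)
    rows = np.flatnonzero(in_range)
    D[rows, gidx[in_range]] = w[rows]

    ids = respondents["respondent_id"]
    codes = pd.Categorical(s["respondent_id"], categories=ids).codes
    return codes, ids, D, py, w


def tabulate_exposure(siblings, respondents, window, weights=None,
                      sex="both") -> ExposureTable:
    """Weighted deaths and person-years by 5-year age group, 15-49.

    ``window`` is a half-open CMC interval ``[start, end)``. ``weights`` is
    None (all 1), a respondent column name, or an array aligned with
    ``respondents``; each sibling inherits its respondent's weight.
    """
    codes, _, D, PY, w = _exposure_arrays(siblings, respondents, window,
                                          weights, sex)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(w > 0, 1.0 / w, 0.0)
    return ExposureTable(
        deaths_w=D.sum(axis=0),
        person_years_w=PY.sum(axis=0),
        deaths=(D * unit[:, None]).sum(axis=0),
        person_years=(PY * unit[:, None]).sum(axis=0),
        window=tuple(window),
    )


def rates_from_exposure(table: ExposureTable) -> np.ndarray:
    """Age-specific rates m_a = deaths / person-years (weighted).

    Groups with zero person-years come back NaN (unestimable)."""
    PY = table.person_years_w
    if np.all(PY == 0):
        raise ValueError("no person-years in any age group")
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(PY > 0, table.deaths_w / PY, np.nan)
    return m


def q_from_m(m, n=5.0):
    """Mid-interval conversion of a rate to an n-year death probability.

    q = n·m / (1 + (n/2)·m), the actuarial form under deaths occurring
    halfway through the interval; clipped at 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m[~np.isnan(m)] < 0):
        raise ValueError("mortality rates must be non-negative")
    q = np.minimum(n * m / (1.0 + (n / 2.0) * m), 1.0)
    return float(q) if q.ndim == 0 else q


def chain_35q15(rates) -> float:
    """Chain seven 5-year probabilities into 35q15 = 1 - prod(1 - q_a)."""
    m = np.asarray(rates, dtype=float)
    if m.shape != (_N_GROUPS,):
        raise ValueError(f"expected {_N_GROUPS} age-group rates, got shape {m.shape}")
    if np.isnan(m).any():
        missing = [ADULT_AGE_GROUPS[i] for i in np.flatnonzero(np.isnan(m))]
        raise ValueError(f"unestimable age group(s): {missing}")
    return float(1.0 - np.prod(1.0 - q_from_m(m)))


def jackknife_ci(units, estimator, level=0.95, truncate=(0.0, 1.0)):
    """Delete-one jackknife SE and normal-approximation CI.

    ``units`` is a sequence of respondent-level units; ``estimator`` maps a
    list of units to a float. Replicates where the estimator fails are
    skipped with a warning (and n adjusted). The CI is truncated to
    ``truncate`` (the probability scale by default; pass None to disable).
    """
    units = list(units)
    n = len(units)
    if n < 2:
        raise ValueError("jackknife needs at least 2 units")
    theta_full = float(estimator(units))
    theta = []
    for i in range(n):
        try:
            theta.append(float(estimator(units[:i] + units[i + 1:])))
        except Exception as exc:  # noqa: BLE001 — replicate-level robustness
            warnings.warn(f"jackknife replicate {i} failed ({exc}); skipped")
    theta = np.asarray(theta)
    k = len(theta)
    if k < 2:
        raise ValueError("too few successful jackknife replicates")
    var = (k - 1) / k * np.sum((theta - theta.mean()) ** 2)
    se = float(np.sqrt(var))
    z = _z(level)
    lo, hi = theta_full - z * se, theta_full + z * se
    if truncate is not None:
        lo, hi = max(lo, truncate[0]), min(hi, truncate[1])
    return se, (lo, hi)


def _erfinv(y):
    # Winitzki initialisation refined by Newton steps on erf
    from math import erf, exp, pi, sqrt
    a = 0.147
    ln = np.log(1.0 - y * y)
    t = 2.0 / (pi * a) + ln / 2.0
    x = float(np.sign(y) * np.sqrt(np.sqrt(t * t - ln / a) - t))
    for _ in range(3):
        x -= (erf(x) - y) * sqrt(pi) / 2.0 * exp(x * x)
    return x


def _z(level):
    """Two-sided standard-normal quantile for a given confidence level."""
    return float(np.sqrt(2.0) * _erfinv(level))


def estimate_35q15(siblings, respondents, window, sex="both",
                   weights=None, level=0.95) -> AdultMortalityEstimate:
    """Full pipeline: tabulate -> rates -> chain -> jackknife CI.

    The jackknife deletes one respondent at a time (their siblings' deaths
    and exposure leave together); it is vectorised via per-respondent
    exposure sums. Leave-one-out replicates with an unestimable age group
    are skipped with a warning.
    """
    codes, ids, D, PY, _ = _exposure_arrays(siblings, respondents, window,
                                            weights, sex)
    n = len(ids)
    Dtot = D.sum(axis=0)
    PYtot = PY.sum(axis=0)
    if np.any(PYtot == 0):
        missing = [ADULT_AGE_GROUPS[i] for i in np.flatnonzero(PYtot == 0)]
        raise ValueError(f"no person-years in age group(s) {missing} "
                         f"for window {tuple(window)}")
    m = Dtot / PYtot
    q = chain_35q15(m)

    # per-respondent contributions (respondents with no siblings contribute 0)
    Di = np.zeros((n, _N_GROUPS))
    PYi = np.zeros((n, _N_GROUPS))
    np.add.at(Di, codes, D)
    np.add.at(PYi, codes, PY)
    D_loo = Dtot[None, :] - Di
    PY_loo = PYtot[None, :] - PYi
    ok = (PY_loo > 0).all(axis=1)
    flags = []
    if not ok.all():
        k = int((~ok).sum())
        warnings.warn(f"{k} jackknife replicate(s) with an empty age group "
                      "skipped")
        flags.append(f"jackknife_skipped={k}")
    m_loo = D_loo[ok] / PY_loo[ok]
    q_loo = 1.0 - np.prod(1.0 - np.minimum(5 * m_loo / (1 + 2.5 * m_loo), 1.0),
                          axis=1)
    k = len(q_loo)
    if k < 2:
        raise ValueError("too few respondents for a jackknife")
    var = (k - 1) / k * np.sum((q_loo - q_loo.mean()) ** 2)
    se = float(np.sqrt(var))
    z = _z(level)
    return AdultMortalityEstimate(
        q=q, se=se,
        ci_low=float(max(0.0, q - z * se)),
        ci_high=float(min(1.0, q + z * se)),
        window=tuple(window), sex=sex,
        n_deaths=float(Dtot.sum()), person_years=float(PYtot.sum()),
        n_respondents=n, rates=m, flags=flags,
    )


def annual_series(siblings, respondents, years, sex="both", weights=None):
    """One 35q15 estimate per calendar year window [Jan y, Jan y+1)."""
    out = []
    for y in years:
        window = (to_cmc(y, 1), to_cmc(y + 1, 1))
        try:
            out.append(estimate_35q15(siblings, respondents, window,
                                      sex=sex, weights=weights))
        except ValueError as exc:
            out.append(AdultMortalityEstimate(
                q=np.nan, se=np.nan, ci_low=np.nan, ci_high=np.nan,
                window=window, sex=sex, n_deaths=0.0, person_years=0.0,
                n_respondents=len(respondents), rates=None,
                flags=[f"unestimable: {exc}"]))
    return out


def scale_subnational(national, province_u5mr, national_u5mr) -> float:
    """Scale a national adult schedule to a province via under-five mortality.

    The province rate schedule is the national m_a multiplied by the ratio
    of province to national under-five mortality, then re-chained to 35q15.
    ``national`` is either a 7-element rate schedule or a national 35q15
    (converted to a flat schedule first).
    """
    if national_u5mr <= 0:
        raise ValueError("national_u5mr must be positive")
    ratio = province_u5mr / national_u5mr
    national = np.asarray(national, dtype=float)
    if national.ndim == 0:
        q = float(national)
        if not 0 <= q < 1:
            raise ValueError("national 35q15 must be in [0, 1)")
        q_a = 1.0 - (1.0 - q) ** (1.0 / _N_GROUPS)
        m_a = np.full(_N_GROUPS, q_a / (5.0 - 2.5 * q_a))
    else:
        m_a = national
    return chain_35q15(m_a * ratio)
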