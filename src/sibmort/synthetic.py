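"""Synthetic sibship generator.

Simulates respondents and their siblings under a stationary demographic
regime (piecewise-constant hazards by single year of age and sex), then
emits the two survey instruments used downstream: a DHS-style *full*
sibling history (ages, ages at death, death dates) and a phone-survey
style *summary* history (counts plus details for recent deaths only).

Reporting-error injectors (age heaping, backward displacement of death
dates, omission of deceased siblings) and a logistic phone-ownership
selection model emulate the distortions that shortened phone interviews
introduce relative to face-to-face collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmc import from_cmc
from .data_model import SIBLING_COLUMNS

__all__ = [
    "LifeTableRegime", "ErrorModel", "SelectionModel", "MortalityShock",
    "calibrate_regime", "simulate_sibships", "inject_errors",
    "apply_selection", "collapse_to_summary",
]

MAX_AGE = 110

# Respondent covariate distributions (population, before phone selection).
RESIDENCE_PROBS = {"urban": 0.45, "rural": 0.55}
EDUCATION_PROBS = {"primary_or_less": 0.45, "secondary": 0.40, "tertiary": 0.15}
HH_SIZE_PROBS = {"1-5": 0.50, "6+": 0.50}
RESPONDENT_AGE_RANGE = (18, 64)


def _template_hazard(sex: str) -> np.ndarray:
    """Baseline hazard shape by single year of age, 0..110.

    High-mortality profile: substantial infant/child mortality, a Gompertz
    rise from age 15. Adult levels are only a shape; :func:`calibrate_regime`
    rescales ages 15-49 to hit a target 35q15 exactly.
    """
    a = np.arange(MAX_AGE + 1, dtype=float)
    h = np.empty(MAX_AGE + 1)
    h[0] = 0.06
    h[1:5] = 0.008
    h[5:10] = 0.002
    h[10:15] = 0.0015
    h[15:] = 0.003 * np.exp(0.075 * (a[15:] - 15))
    if sex == "f":
        h[15:] *= 0.85
    return np.minimum(h, 0.7)


@dataclass
class LifeTableRegime:
    """Stationary mortality + fertility regime driving the simulator.

    ``hazards[sex]`` is the force of mortality per single year of age
    (0..110). Sibship size is negative-binomial (``fertility_mean``,
    ``fertility_dispersion``); respondent-sibling age gaps are a
    discretised normal with sd ``gap_sd`` years.
    """

    hazards: dict = field(repr=False)
    target_35q15: dict = field(default_factory=dict)
    fertility_mean: float = 6.0
    fertility_dispersion: float = 8.0
    gap_sd: float = 5.0

    def implied_35q15(self, sex: str) -> float:
        """Closed-form probability of dying between exact ages 15 and 50."""
        return 1.0 - float(np.exp(-self.hazards[sex][15:50].sum()))


@dataclass
class ErrorModel:
    """Reporting-error injectors for the full sibling history.

    heap_prob
        Probability that a reported age (current age or age at death) is
        rounded to the nearest multiple of 5.
    displace_prob, displace_mean_months
        Probability that a death date is shifted backward in time, by a
        geometric number of months with the given mean; the recorded age at
        death is preserved (the whole lifespan slides back), which is the
        mechanism that transfers recent deaths out of the reference period.
    omit_death_prob
        Probability that a deceased sibling is not reported at all.
    """

    heap_prob: float = 0.0
    displace_prob: float = 0.0
    displace_mean_months: float = 12.0
    omit_death_prob: float = 0.0

    def __post_init__(self):
        for name in ("heap_prob", "displace_prob", "omit_death_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class SelectionModel:
    """Logistic phone-ownership/response model on respondent covariates.

    ``coefs`` maps covariate name -> {category: coefficient}; missing
    categories contribute 0. Response probability is
    ``expit(intercept + sum of matched coefficients)``.
    """

    intercept: float = 0.0
    coefs: dict = field(default_factory=dict)

    def response_prob(self, respondents: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(respondents), float(self.intercept))
        for var, cats in self.coefs.items():
            eta += respondents[var].map(cats).fillna(0.0).to_numpy(float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class MortalityShock:
    """Period effect: hazards multiplied by ``multiplier`` from ``start_cmc`` on."""

    start_cmc: int
    multiplier: float


def calibrate_regime(target_35q15, fertility_mean=6.0, fertility_dispersion=8.0,
                     gap_sd=5.0) -> LifeTableRegime:
    """Scale the adult (15-49) hazards so each sex hits its target 35q15.

    Under piecewise-constant hazards, 35q15 = 1 - exp(-sum of the 35 single
    year hazards), so the scaling factor k solving
    ``1 - exp(-k * sum(h[15:50])) = target`` is closed form. The returned
    regime satisfies ``implied_35q15(sex) == target`` to ~1e-12.
    """
    if not isinstance(target_35q15, dict):
        target_35q15 = {"m": float(target_35q15), "f": float(target_35q15)}
    hazards = {}
    for sex, target in target_35q15.items():
        if not 0.0 <= target < 1.0:
            raise ValueError(f"target 35q15 must be in [0, 1), got {target}")
        h = _template_hazard(sex)
        k = -np.log1p(-target) / h[15:50].sum()
        h[15:50] *= k
        hazards[sex] = h
    return LifeTableRegime(hazards=hazards, target_35q15=dict(target_35q15),
                           fertility_mean=fertility_mean,
                           fertility_dispersion=fertility_dispersion,
                           gap_sd=gap_sd)


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=p / p.sum())]


def simulate_sibships(regime: LifeTableRegime, n_respondents: int,
                      interview_cmc: int, seed,
                      shock: MortalityShock | None = None):
    """Simulate a survey: respondents (alive by construction) + full SSH.

    Returns ``(respondents, siblings)`` DataFrames. Siblings draw a birth
    date from the age-gap law around the respondent's birth, then a
    lifetime from the regime hazards (optionally modified by a period
    ``shock``); deaths after the interview are censored to 'alive'.
    Deterministic under a fixed seed.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    rng = np.random.default_rng(seed)

    lo, hi = RESPONDENT_AGE_RANGE
    ages = np.arange(lo, hi + 1)
    age_w = np.linspace(1.0, 0.4, len(ages))
    resp_age = rng.choice(ages, size=n_respondents, p=age_w / age_w.sum())
    resp = pd.DataFrame({
        "respondent_id": [f"r{i:06d}" for i in range(n_respondents)],
        "sex": rng.choice(["m", "f"], size=n_respondents),
        "age_years": resp_age,
        "interview_cmc": interview_cmc,
        "residence": _draw_categorical(rng, RESIDENCE_PROBS, n_respondents),
        "education": _draw_categorical(rng, EDUCATION_PROBS, n_respondents),
        "hh_size_class": _draw_categorical(rng, HH_SIZE_PROBS, n_respondents),
        "design_weight": 1.0,
    })
    resp_birth = interview_cmc - 12 * resp_age - rng.integers(0, 12, n_respondents)

    r = regime.fertility_dispersion
    mu = regime.fertility_mean
    sizes = rng.negative_binomial(r, r / (r + mu), size=n_respondents)
    owner = np.repeat(np.arange(n_respondents), sizes)
    n_sib = len(owner)

    sex = rng.choice(["m", "f"], size=n_sib)
    # age gap (respondent - sibling, years): discretised normal; redraw gaps
    # that would put the sibling's birth after the interview
    gap = np.rint(rng.normal(0.0, regime.gap_sd, n_sib)).astype(int)
    month_noise = rng.integers(0, 12, n_sib) - 6
    birth = resp_birth[owner] + 12 * gap + month_noise
    for _ in range(100):
        bad = birth > interview_cmc
        if not bad.any():
            break
        gap[bad] = np.rint(rng.normal(0.0, regime.gap_sd, int(bad.sum()))).astype(int)
        birth[bad] = resp_birth[owner[bad]] + 12 * gap[bad] + month_noise[bad]
    birth = np.minimum(birth, interview_cmc)

    # lifetimes: year-by-year survival under the (possibly period-shocked)
    # hazards; only years starting before the interview can matter
    haz = np.stack([regime.hazards["m"], regime.hazards["f"]])
    sex_idx = (sex == "f").astype(int)
    death_cmc = np.full(n_sib, -1, dtype=np.int64)
    undead = np.ones(n_sib, dtype=bool)
    max_a = min(MAX_AGE, int(np.ceil((interview_cmc - birth.min()) / 12)))
    for a in range(max_a + 1):
        year_start = birth + 12 * a
        at_risk = undead & (year_start < interview_cmc)
        if not at_risk.any():
            break
        h = haz[sex_idx, a]
        if shock is not None:
            h = np.where(year_start + 6 >= shock.start_cmc, h * shock.multiplier, h)
        die = at_risk & (rng.random(n_sib) < -np.expm1(-h))
        if die.any():
            death_cmc[die] = birth[die] + 12 * a + rng.integers(0, 12, int(die.sum()))
            undead[die] = False

    dead = (death_cmc >= 0) & (death_cmc < interview_cmc)
    sib = pd.DataFrame({
        "respondent_id": resp["respondent_id"].to_numpy()[owner],
        "line_no": np.concatenate([np.arange(1, k + 1) for k in sizes]) if n_sib
        else np.array([], dtype=int),
        "sex": sex,
        "alive": ~dead,
        "age_now": np.where(dead, np.nan, (interview_cmc - birth) // 12),
        "age_at_death": np.where(dead, (death_cmc - birth) // 12, np.nan),
        "death_cmc": np.where(dead, death_cmc, np.nan),
        "birth_cmc": birth.astype(float),
        "imputed_fields": "",
    })
    return resp, sib[SIBLING_COLUMNS]


def inject_errors(siblings: pd.DataFrame, respondents: pd.DataFrame,
                  model: ErrorModel, seed) -> pd.DataFrame:
    """Apply reporting errors to a full sibling history.

    Heaping rewrites the reported age and rederives the birth date keeping
    the within-year month offset; displacement slides the whole lifespan of
    a deceased sibling backward so the recorded age at death is unchanged;
    omission drops deceased-sibling rows.
    """
    rng = np.random.default_rng(seed)
    s = siblings.copy().reset_index(drop=True)
    interview = s["respondent_id"].map(
        respondents.set_index("respondent_id")["interview_cmc"]).to_numpy(float)
    alive = s["alive"].to_numpy(bool)

    if model.heap_prob > 0:
        heap = rng.random(len(s)) < model.heap_prob
        ha = heap & alive
        if ha.any():
            age = s.loc[ha, "age_now"].to_numpy(float)
            heaped = np.rint(age / 5) * 5
            off = (interview[ha] - s.loc[ha, "birth_cmc"].to_numpy(float)) % 12
            s.loc[ha, "age_now"] = heaped
            s.loc[ha, "birth_cmc"] = interview[ha] - 12 * heaped - off
        hd = heap & ~alive
        if hd.any():
            aad = s.loc[hd, "age_at_death"].to_numpy(float)
            heaped = np.rint(aad / 5) * 5
            death = s.loc[hd, "death_cmc"].to_numpy(float)
            off = (death - s.loc[hd, "birth_cmc"].to_numpy(float)) % 12
            s.loc[hd, "age_at_death"] = heaped
            s.loc[hd, "birth_cmc"] = death - 12 * heaped - off

    if model.displace_prob > 0:
        disp = (rng.random(len(s)) < model.displace_prob) & ~alive
        if disp.any():
            delta = rng.geometric(1.0 / model.displace_mean_months, int(disp.sum()))
            s.loc[disp, "death_cmc"] -= delta
            s.loc[disp, "birth_cmc"] -= delta

    if model.omit_death_prob > 0:
        omit = (rng.random(len(s)) < model.omit_death_prob) & ~alive
        s = s[~omit].reset_index(drop=True)
    return s


def apply_selection(respondents: pd.DataFrame, siblings: pd.DataFrame,
                    model: SelectionModel, seed):
    """Bernoulli-thin respondents by phone-ownership probability.

    Sibling rows of dropped respondents are removed. Raises if the selected
    sample is empty.
    """
    rng = np.random.default_rng(seed)
    p = model.response_prob(respondents)
    keep = rng.random(len(respondents)) < p
    if not keep.any():
        raise ValueError("selection model removed every respondent; "
                         "relax the intercept or coefficients")
    resp = respondents[keep].reset_index(drop=True)
    sib = siblings[siblings["respondent_id"].isin(resp["respondent_id"])]
    return resp, sib.reset_index(drop=True)


def collapse_to_summary(siblings: pd.DataFrame, respondents: pd.DataFrame,
                        cutoff_cmc: int, variant: str = "burkina"):
    """Collapse a full SSH to the shortened phone-survey instrument.

    Returns ``(summary, details)``: per-respondent sibling counts (by sex
    except in the combined-sexes 'malawi' variant) and one detail row per
    death at ``death_cmc >= cutoff_cmc``. The 'drc' variant masks age at
    death in the details; 'malawi' masks sex everywhere.
    """
    if variant not in ("burkina", "drc", "malawi"):
        raise ValueError(f"unknown variant {variant!r}")
    s = siblings
    dead = ~s["alive"].astype(bool)

    grp = s.groupby("respondent_id")
    summary = pd.DataFrame({
        "n_ever": grp.size(),
        "n_alive": grp["alive"].sum().astype(int),
    })
    summary["n_dead"] = summary["n_ever"] - summary["n_alive"]
    if variant != "malawi":
        for sx in sorted(s["sex"].unique()):
            m = s[s["sex"] == sx]
            g = m.groupby("respondent_id")
            summary[f"n_ever_{sx}"] = g.size().reindex(summary.index).fillna(0).astype(int)
            summary[f"n_alive_{sx}"] = (
                g["alive"].sum().reindex(summary.index).fillna(0).astype(int))
            summary[f"n_dead_{sx}"] = summary[f"n_ever_{sx}"] - summary[f"n_alive_{sx}"]
    summary = (summary.reindex(respondents["respondent_id"]).fillna(0).astype(int)
               .reset_index())

    recent = s[dead & (s["death_cmc"] >= cutoff_cmc)]
    year, month = from_cmc(recent["death_cmc"].to_numpy(int)) if len(recent) \
        else (np.array([], dtype=int), np.array([], dtype=int))
    details = pd.DataFrame({
        "respondent_id": recent["respondent_id"].to_numpy(),
        "sex": np.nan if variant == "malawi" else recent["sex"].to_numpy(),
        "age_at_death": np.nan if variant == "drc"
        else recent["age_at_death"].to_numpy(float),
        "death_year": year,
        "death_month": month,
    })
    return summary, details.reset_index(drop=True)
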