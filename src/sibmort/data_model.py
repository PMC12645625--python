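"""Tabular schemas and CSV I/O for sibling survival histories.

Three tables are used throughout:

* **respondents** — one row per survey respondent: ``respondent_id``, ``sex``
  (``m``/``f``/``u``), ``age_years``, ``interview_cmc``, the categorical
  weighting covariates (``residence``, ``education``, ``hh_size_class``),
  ``design_weight`` and, once raking has run, ``ps_weight``.
* **full SSH (siblings)** — one row per reported sibling: ``respondent_id``,
  ``line_no``, ``sex``, ``alive``, ``age_now`` (alive only), ``age_at_death``
  and ``death_cmc`` (dead only), ``birth_cmc``, and ``imputed_fields`` — a
  ``;``-joined list of field names that were imputed rather than reported.
* **summary SSH** — the shortened phone-survey instrument: per-respondent
  counts of siblings ever born / alive / dead (by sex where the country
  variant collects it), plus a detail table with one row per *recent* death
  (sex, age at death and date, each optional by variant).

Unknown sibling sex (``u``) is a first-class category so that country
variants without sex disaggregation flow through every downstream stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cmc import to_cmc

__all__ = [
    "SchemaError",
    "AGE_GROUP_LABELS",
    "age_group_label",
    "validate_respondents",
    "validate_full_ssh",
    "validate_summary_ssh",
    "derive_birth_cmc",
    "load_respondents",
    "write_respondents",
    "load_full_ssh",
    "write_full_ssh",
    "load_summary_ssh",
    "write_summary_ssh",
]

SEX_CODES = ("m", "f", "u")

#: 5-year respondent age groups used to key imputation reference tables.
AGE_GROUP_LABELS = [f"{lo}-{lo + 4}" for lo in range(15, 95, 5)]

SIBLING_COLUMNS = [
    "respondent_id", "line_no", "sex", "alive",
    "age_now", "age_at_death", "death_cmc", "birth_cmc", "imputed_fields",
]
RESPONDENT_COLUMNS = [
    "respondent_id", "sex", "age_years", "interview_cmc",
    "residence", "education", "hh_size_class", "design_weight",
]


class SchemaError(ValueError):
    """Raised when a table violates its schema; carries a per-row report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report or []


def age_group_label(age):
    """5-year age-group label ('15-19', '20-24', ...) for integer ages."""
    age = np.asarray(age)
    lo = np.clip(age // 5 * 5, 15, 90).astype(int)
    labels = np.char.add(np.char.add(lo.astype(str), "-"), (lo + 4).astype(str))
    return str(labels) if labels.ndim == 0 else labels


# ---------------------------------------------------------------------------
# validation


def validate_respondents(respondents: pd.DataFrame) -> list:
    """Return a list of (row, message) hard violations."""
    report = []
    r = respondents
    if r["respondent_id"].duplicated().any():
        for i in r.index[r["respondent_id"].duplicated()]:
            report.append((i, "duplicate respondent_id"))
    for i in r.index[~r["sex"].isin(SEX_CODES)]:
        report.append((i, f"sex must be one of {SEX_CODES}"))
    for i in r.index[(r["age_years"] < 15) | (r["age_years"] > 95)]:
        report.append((i, "age_years outside [15, 95]"))
    for i in r.index[r["interview_cmc"] <= 0]:
        report.append((i, "interview_cmc must be positive"))
    for i in r.index[r["design_weight"] <= 0]:
        report.append((i, "design_weight must be positive"))
    return report


def validate_full_ssh(siblings: pd.DataFrame, respondents: pd.DataFrame | None = None) -> list:
    """Per-row invariant check for a full sibling table.

    Hard violations: alive rows carrying death fields; dead rows carrying a
    current age; internally inconsistent (birth, death, age-at-death)
    triples; death after the owner's interview.
    """
    report = []
    s = siblings
    alive = s["alive"].astype(bool)
    for i in s.index[~s["sex"].isin(SEX_CODES)]:
        report.append((i, f"sex must be one of {SEX_CODES}"))
    for i in s.index[s["line_no"] < 1]:
        report.append((i, "line_no must be >= 1"))
    bad = alive & (s["age_at_death"].notna() | s["death_cmc"].notna())
    for i in s.index[bad]:
        report.append((i, "alive sibling has death fields set"))
    bad = ~alive & s["age_now"].notna()
    for i in s.index[bad]:
        report.append((i, "deceased sibling has age_now set"))
    full = s["birth_cmc"].notna() & s["death_cmc"].notna() & s["age_at_death"].notna()
    if full.any():
        derived = (s.loc[full, "death_cmc"] - s.loc[full, "birth_cmc"]) // 12
        for i in derived.index[derived != s.loc[full, "age_at_death"]]:
            report.append((i, "age_at_death inconsistent with birth_cmc/death_cmc"))
    if respondents is not None:
        interview = s["respondent_id"].map(
            respondents.set_index("respondent_id")["interview_cmc"])
        bad = s["death_cmc"].notna() & (s["death_cmc"] > interview)
        for i in s.index[bad]:
            report.append((i, "death_cmc after owner's interview"))
        missing = ~s["respondent_id"].isin(respondents["respondent_id"])
        for i in s.index[missing]:
            report.append((i, "respondent_id not in respondents table"))
    return report


def validate_summary_ssh(summary: pd.DataFrame, details: pd.DataFrame | None = None) -> list:
    report = []
    m = summary
    for i in m.index[(m[["n_ever", "n_alive", "n_dead"]] < 0).any(axis=1)]:
        report.append((i, "negative sibling count"))
    bad = m["n_alive"] + m["n_dead"] != m["n_ever"]
    for i in m.index[bad]:
        report.append((i, "n_alive + n_dead != n_ever"))
    if details is not None and len(details):
        ndet = details.groupby("respondent_id").size()
        ndead = m.set_index("respondent_id")["n_dead"]
        over = ndet[ndet > ndead.reindex(ndet.index).fillna(0)]
        for rid in over.index:
            report.append((rid, "more recent-death detail rows than n_dead"))
    return report


def _raise_if_hard(report, what):
    if report:
        lines = "; ".join(f"row {i}: {msg}" for i, msg in report[:10])
        raise SchemaError(f"{what}: {len(report)} invalid row(s): {lines}", report)


# ---------------------------------------------------------------------------
# derived fields


def derive_birth_cmc(siblings, respondents, j="mid", rng=None):
    """Fill missing ``birth_cmc`` from age and the relevant anchor date.

    For living siblings ``birth = interview − 12·age_now − j``; for deceased
    siblings ``birth = death_cmc − 12·age_at_death − j``, where ``j`` is a
    within-year month offset: the deterministic mid-year value 6 by default,
    or drawn uniform on 0..11 when ``j='uniform'`` (requires ``rng``). Either
    choice leaves the completed-years age consistent with the derived date.
    Derived fields are flagged in ``imputed_fields``.
    """
    s = siblings.copy()
    missing = s["birth_cmc"].isna()
    if not missing.any():
        return s
    interview = s["respondent_id"].map(
        respondents.set_index("respondent_id")["interview_cmc"])
    alive = s["alive"].astype(bool)
    no_source = missing & ~((alive & s["age_now"].notna())
                            | (~alive & s["death_cmc"].notna() & s["age_at_death"].notna()))
    if no_source.any():
        raise SchemaError(
            f"{int(no_source.sum())} sibling row(s) have neither a current age nor "
            "death date + age at death; run imputation before deriving birth dates")
    if j == "mid":
        offs = np.full(len(s), 6)
    elif j == "uniform":
        if rng is None:
            raise ValueError("j='uniform' requires an rng")
        offs = rng.integers(0, 12, size=len(s))
    else:
        offs = np.full(len(s), int(j))
    anchor = np.where(alive, interview, s["death_cmc"])
    years = np.where(alive, s["age_now"], s["age_at_death"])
    derived = anchor - 12 * years - offs
    s.loc[missing, "birth_cmc"] = derived[missing.to_numpy()]
    s.loc[missing, "imputed_fields"] = (
        s.loc[missing, "imputed_fields"].fillna("").apply(
            lambda f: "birth_cmc" if not f else f"{f};birth_cmc"))
    return s


# ---------------------------------------------------------------------------
# CSV I/O


def _canonical_siblings(df):
    out = pd.DataFrame({
        "respondent_id": df["respondent_id"].astype(str),
        "line_no": df["line_no"].astype(int),
        "sex": df["sex"].astype(str),
        "alive": df["alive"].astype(bool),
        "age_now": pd.to_numeric(df.get("age_now"), errors="coerce"),
        "age_at_death": pd.to_numeric(df.get("age_at_death"), errors="coerce"),
        "death_cmc": pd.to_numeric(df.get("death_cmc"), errors="coerce"),
        "birth_cmc": pd.to_numeric(df.get("birth_cmc"), errors="coerce"),
        "imputed_fields": df.get("imputed_fields", pd.Series("", index=df.index)).fillna(""),
    })
    return out.reset_index(drop=True)


def load_full_ssh(path, respondents=None):
    """Read a full-SSH CSV; raise :class:`SchemaError` on hard violations."""
    df = pd.read_csv(path, dtype={"respondent_id": str, "sex": str})
    required = {"respondent_id", "line_no", "sex", "alive"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"full SSH file missing columns: {sorted(missing)}")
    df["alive"] = df["alive"].astype(int).astype(bool)
    out = _canonical_siblings(df)
    _raise_if_hard(validate_full_ssh(out, respondents), "full SSH")
    return out


def write_full_ssh(siblings, path, respondents=None):
    """Write a full-SSH CSV (adds derived ``years_since_death`` when the
    respondents table is supplied)."""
    out = _canonical_siblings(siblings)
    cols = list(out.columns)
    if respondents is not None:
        interview = out["respondent_id"].map(
            respondents.set_index("respondent_id")["interview_cmc"])
        out["years_since_death"] = (interview - out["death_cmc"]) // 12
        cols = cols[:5] + ["age_at_death", "years_since_death", "death_cmc",
                           "birth_cmc", "imputed_fields"]
        out = out[list(dict.fromkeys(cols))]
    out.to_csv(path, index=False, float_format="%.0f")


def load_respondents(path):
    df = pd.read_csv(path, dtype={"respondent_id": str, "sex": str})
    missing = set(RESPONDENT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"respondents file missing columns: {sorted(missing)}")
    _raise_if_hard(validate_respondents(df), "respondents")
    return df


def write_respondents(respondents, path):
    respondents.to_csv(path, index=False)


def load_summary_ssh(summary_path, details_path=None):
    """Read summary counts (+ optional recent-death details).

    Files without per-sex count columns (the combined-sexes country variant)
    load into combined counts; detail files may omit ``sex``,
    ``age_at_death`` or ``death_month`` columns, which load as missing.
    """
    summary = pd.read_csv(summary_path, dtype={"respondent_id": str})
    required = {"respondent_id", "n_ever", "n_alive", "n_dead"}
    missing = required - set(summary.columns)
    if missing:
        raise SchemaError(f"summary SSH file missing columns: {sorted(missing)}")
    details = None
    if details_path is not None:
        details = pd.read_csv(details_path, dtype={"respondent_id": str, "sex": str})
        if "death_year" not in details.columns:
            raise SchemaError("recent-death detail file missing column: death_year")
        for col in ("sex", "age_at_death", "death_month"):
            if col not in details.columns:
                details[col] = np.nan
    _raise_if_hard(validate_summary_ssh(summary, details), "summary SSH")
    return summary, details


def write_summary_ssh(summary, details, summary_path, details_path):
    summary.to_csv(summary_path, index=False)
    details.to_csv(details_path, index=False, float_format="%.0f")


def details_death_cmc(details, default_month=6):
    """Death CMC for recent-death detail rows (missing months -> mid-year)."""
    month = pd.to_numeric(details["death_month"], errors="coerce").fillna(default_month)
    return to_cmc(details["death_year"].to_numpy(int), month.to_numpy(int))
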