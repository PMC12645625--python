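"""Hot-deck reconstruction of full sibling histories from summary counts.

A shortened phone interview records, per respondent, only the numbers of
siblings ever born / alive / dead plus dates (and, variant permitting, sex
and age at death) for *recent* deaths. To estimate mortality from
person-years, the missing ages and dates are imputed from the empirical
distributions of an earlier full-history survey:

* an **age-difference table** — the distribution of (respondent age −
  sibling age) among surviving siblings, per 5-year respondent age group
  and sibling sex — supplies current ages for surviving siblings;
* a **death-schedule table** — the joint distribution of (age at death,
  time since death) among deceased siblings, with the same keys — supplies
  ages and timing for deaths.

*Partial* imputation keeps everything the respondent reported about recent
deaths and imputes only what was never asked (survivors' ages, and death
schedules for the non-recent deaths, truncated to predate the recency
cutoff). *Complete* imputation discards the reported death details too and
redraws every death from the reference joint distribution. Draws are
proportional (categorical on the weighted reference frequencies), with an
RNG sub-stream per respondent so results do not depend on row order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmc import to_cmc
from .data_model import SIBLING_COLUMNS, age_group_label

__all__ = ["ReferenceTables", "build_reference_tables", "fallback_key",
           "impute_partial", "impute_complete"]

GAP_RANGE = (-40, 40)
AAD_RANGE = (0, 94)
TSD_RANGE = (0, 49)


def _entry(values, weights):
    """Normalised categorical distribution over the rows of ``values``."""
    w = np.asarray(weights, dtype=float)
    p = w / w.sum()
    return {"values": values, "probs": p, "cum": np.cumsum(p)}


@dataclass
class ReferenceTables:
    """Reference distributions keyed by (respondent age group, sibling sex).

    ``age_diff[key]`` is a categorical over integer age differences;
    ``death_sched[key]`` over (age at death, time since death) pairs.
    ``'all'`` in either key position is the pooled margin, used by the
    fallback chain for sparse cells.
    """

    age_diff: dict = field(default_factory=dict)
    death_sched: dict = field(default_factory=dict)
    age_groups: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Serialise both tables to a long DataFrame (CSV-friendly)."""
        rows = []
        for (ag, sex), e in self.age_diff.items():
            for v, p in zip(e["values"], e["probs"]):
                rows.append(("age_diff", ag, sex, int(v), np.nan, p))
        for (ag, sex), e in self.death_sched.items():
            for (aad, tsd), p in zip(e["values"], e["probs"]):
                rows.append(("death_sched", ag, sex, int(aad), int(tsd), p))
        return pd.DataFrame(rows, columns=["table", "age_group", "sex",
                                           "value1", "value2", "mass"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTables":
        tables = cls()
        for (ag, sex), g in df[df["table"] == "age_diff"].groupby(["age_group", "sex"]):
            tables.age_diff[(ag, sex)] = _entry(g["value1"].to_numpy(int),
                                                g["mass"].to_numpy())
        for (ag, sex), g in df[df["table"] == "death_sched"].groupby(["age_group", "sex"]):
            vals = list(zip(g["value1"].astype(int), g["value2"].astype(int)))
            tables.death_sched[(ag, sex)] = _entry(vals, g["mass"].to_numpy())
        tables.age_groups = sorted({k[0] for k in tables.age_diff} - {"all"})
        return tables


def _accumulate(keys_ag, keys_sex, values, weights, out: dict):
    df = pd.DataFrame({"ag": keys_ag, "sex": keys_sex, "v": values, "w": weights})
    for ag_key in ("exact", "all"):
        for sex_key in ("exact", "all"):
            g = df.copy()
            g["ag"] = g["ag"] if ag_key == "exact" else "all"
            g["sex"] = g["sex"] if sex_key == "exact" else "all"
            agg = g.groupby(["ag", "sex", "v"], observed=True)["w"].sum().reset_index()
            for (ag, sex), sub in agg.groupby(["ag", "sex"], observed=True):
                if (ag, sex) in out:
                    continue
                out[(ag, sex)] = _entry(sub["v"].to_list(), sub["w"].to_numpy())


def build_reference_tables(siblings: pd.DataFrame, respondents: pd.DataFrame,
                           weights: pd.Series | None = None) -> ReferenceTables:
    """Tabulate weighted age-difference and death-schedule histograms.

    ``weights`` is a per-respondent series (indexed like ``respondents``);
    siblings inherit their respondent's weight. Pooled ('all') cells are
    always built so the fallback chain can resolve any key.
    """
    resp = respondents.set_index("respondent_id")
    if weights is None:
        wmap = pd.Series(1.0, index=resp.index)
    else:
        wmap = pd.Series(np.asarray(weights, float), index=respondents["respondent_id"])
    s = siblings.copy()
    s["_w"] = s["respondent_id"].map(wmap)
    s["_resp_age"] = s["respondent_id"].map(resp["age_years"])
    s["_interview"] = s["respondent_id"].map(resp["interview_cmc"])
    s["_ag"] = age_group_label(s["_resp_age"].to_numpy(int))

    tables = ReferenceTables(age_groups=sorted(set(s["_ag"])))

    alive = s["alive"].astype(bool) & s["age_now"].notna()
    a = s[alive]
    gap = np.clip((a["_resp_age"] - a["age_now"]).astype(int), *GAP_RANGE)
    _accumulate(a["_ag"], a["sex"], gap, a["_w"], tables.age_diff)

    dead = ~s["alive"].astype(bool) & s["age_at_death"].notna() & s["death_cmc"].notna()
    d = s[dead]
    if len(d):
        tsd = np.clip(((d["_interview"] - d["death_cmc"]) // 12).astype(int), *TSD_RANGE)
        aad = np.clip(d["age_at_death"].astype(int), *AAD_RANGE)
        pairs = list(zip(aad, tsd))
        _accumulate(d["_ag"], d["sex"], pairs, d["_w"], tables.death_sched)
    return tables


def fallback_key(key, table: dict, age_groups: list):
    """Resolve a (age group, sex) key against a sparse table.

    Chain: exact key -> collapse sibling sex -> nearest adjacent respondent
    age group (sex-specific, then collapsed) -> global pooled. A warning is
    emitted when the chain reaches the global pool.
    """
    ag, sex = key
    if key in table:
        return key
    if (ag, "all") in table:
        return (ag, "all")
    if ag in age_groups:
        i = age_groups.index(ag)
        for dist in range(1, len(age_groups)):
            for j in (i - dist, i + dist):
                if 0 <= j < len(age_groups):
                    for sx in (sex, "all"):
                        if (age_groups[j], sx) in table:
                            return (age_groups[j], sx)
    for k in (("all", sex), ("all", "all")):
        if k in table:
            warnings.warn(f"imputation key {key} resolved to global pool {k}")
            return k
    raise ValueError(f"no usable reference-table cell for key {key}")


def _resp_rng(seed: int, respondent_id: str):
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(str(respondent_id).encode())]))


def _draw(entry, k, rng):
    idx = np.searchsorted(entry["cum"], rng.random(k), side="right")
    idx = np.minimum(idx, len(entry["probs"]) - 1)
    vals = entry["values"]
    return [vals[i] for i in idx]


def _conditional_entry(entry, predicate):
    """Restrict a joint (aad, tsd) entry to pairs satisfying ``predicate``."""
    keep = [i for i, v in enumerate(entry["values"]) if predicate(v)]
    if not keep:
        return None
    vals = [entry["values"][i] for i in keep]
    return _entry(vals, entry["probs"][np.array(keep)])


def _jitter(rng, k, jitter):
    return rng.integers(0, 12, k) if jitter == "uniform" else np.zeros(k, dtype=int)


def _sex_groups(row, summary_columns):
    """Per-sex (sex, n_alive, n_dead) triples for one summary row."""
    sexes = sorted({c.rsplit("_", 1)[1] for c in summary_columns
                    if c.startswith("n_ever_")})
    if sexes:
        groups = [(sx, int(row[f"n_alive_{sx}"]), int(row[f"n_dead_{sx}"]))
                  for sx in sexes]
        if (sum(g[1] for g in groups) == row["n_alive"]
                and sum(g[2] for g in groups) == row["n_dead"]):
            return groups
    return [("u", int(row["n_alive"]), int(row["n_dead"]))]


def _impute(summary, details, respondents, tables, seed, recency_cutoff_cmc,
            mode, jitter="uniform"):
    resp = respondents.set_index("respondent_id")
    det_by_rid = ({} if details is None or not len(details)
                  else {rid: g for rid, g in details.groupby("respondent_id")})
    trunc_cache: dict = {}
    cond_cache: dict = {}
    out: dict = {c: [] for c in SIBLING_COLUMNS}

    def emit(rid, line, sex, alive, age_now, aad, death, birth, flags):
        out["respondent_id"].append(rid)
        out["line_no"].append(line)
        out["sex"].append(sex)
        out["alive"].append(alive)
        out["age_now"].append(age_now)
        out["age_at_death"].append(aad)
        out["death_cmc"].append(death)
        out["birth_cmc"].append(birth)
        out["imputed_fields"].append(flags)

    for row in summary.itertuples(index=False):
        rid = row.respondent_id
        if rid not in resp.index:
            raise ValueError(f"summary respondent {rid!r} missing from respondents table")
        r = resp.loc[rid]
        interview = int(r["interview_cmc"])
        resp_age = int(r["age_years"])
        ag = age_group_label(resp_age)
        min_tsd = int(np.ceil((interview - recency_cutoff_cmc) / 12))
        rng = _resp_rng(seed, rid)
        line = 1
        rowd = row._asdict()

        for sex, n_alive_s, n_dead_s in _sex_groups(rowd, summary.columns):
            # surviving siblings: draw an age difference, derive current age
            if n_alive_s:
                key = fallback_key((ag, sex), tables.age_diff, tables.age_groups)
                entry = tables.age_diff[key]
                gaps = np.array(_draw(entry, n_alive_s, rng))
                age_now = resp_age - gaps
                for _ in range(10):
                    bad = (age_now < 0) | (age_now > 95)
                    if not bad.any():
                        break
                    age_now[bad] = resp_age - np.array(_draw(entry, int(bad.sum()), rng))
                age_now = np.clip(age_now, 0, 95)
                births = interview - 12 * age_now - _jitter(rng, n_alive_s, jitter)
                for an, b in zip(age_now, births):
                    emit(rid, line, sex, True, float(an), np.nan, np.nan,
                         float(b), "age_now;birth_cmc")
                    line += 1

            # deceased siblings
            dets = det_by_rid.get(rid)
            if dets is not None:
                if sex == "u":
                    dets_s = dets
                else:
                    dets_s = dets[dets["sex"] == sex]
            else:
                dets_s = None
            n_recent = 0 if dets_s is None else len(dets_s)
            n_recent = min(n_recent, n_dead_s)

            if mode == "partial" and n_recent:
                dkey = fallback_key((ag, sex), tables.death_sched, tables.age_groups)
                dentry = tables.death_sched[dkey]
                for det in dets_s.head(n_recent).itertuples(index=False):
                    flags = ["birth_cmc"]
                    year = int(det.death_year)
                    if pd.notna(det.death_month):
                        death = to_cmc(year, int(det.death_month))
                    else:
                        months = [m for m in range(1, 13)
                                  if recency_cutoff_cmc <= to_cmc(year, m) <= interview]
                        death = to_cmc(year, int(rng.choice(months or [6])))
                        flags.append("death_month")
                    death = int(np.clip(death, recency_cutoff_cmc, interview))
                    if pd.notna(det.age_at_death):
                        aad = int(det.age_at_death)
                    else:
                        # country variant without ages at death: draw the age
                        # conditional on the reported time since death
                        t = (interview - death) // 12
                        ck = (dkey, "tsd", t)
                        if ck not in cond_cache:
                            ce = None
                            for width in range(0, TSD_RANGE[1] + 1):
                                ce = _conditional_entry(
                                    dentry, lambda v: abs(v[1] - t) <= width)
                                if ce is not None:
                                    break
                            cond_cache[ck] = ce
                        aad = int(_draw(cond_cache[ck], 1, rng)[0][0])
                        flags.append("age_at_death")
                    birth = death - 12 * aad - int(_jitter(rng, 1, jitter)[0])
                    emit(rid, line, sex, False, np.nan, float(aad), float(death),
                         float(birth), ";".join(flags))
                    line += 1

            if mode == "partial":
                n_draw = n_dead_s - n_recent
                condition = ("trunc", min_tsd)
            else:
                n_draw = n_dead_s
                condition = None
            if n_draw:
                dkey = fallback_key((ag, sex), tables.death_sched, tables.age_groups)
                dentry = tables.death_sched[dkey]
                if condition is not None:
                    # the respondent asserted these deaths predate the
                    # recency cutoff: truncate the schedule accordingly
                    ck = (dkey, condition)
                    if ck not in trunc_cache:
                        trunc_cache[ck] = _conditional_entry(
                            dentry, lambda v: v[1] >= min_tsd)
                    use = trunc_cache[ck]
                    if use is None:
                        warnings.warn(
                            f"death schedule for {dkey} has no mass beyond the "
                            "recency cutoff; drawing unconditionally")
                        use = dentry
                else:
                    use = dentry
                pairs = _draw(use, n_draw, rng)
                j1 = _jitter(rng, n_draw, jitter)
                j2 = _jitter(rng, n_draw, jitter)
                for (aad, tsd), a_, b_ in zip(pairs, j1, j2):
                    death = interview - 12 * int(tsd) - int(a_)
                    if condition is not None and death >= recency_cutoff_cmc:
                        death = recency_cutoff_cmc - 1
                    birth = death - 12 * int(aad) - int(b_)
                    emit(rid, line, sex, False, np.nan, float(aad), float(death),
                         float(birth), "age_at_death;death_cmc;birth_cmc")
                    line += 1

    return pd.DataFrame(out)[SIBLING_COLUMNS]


def impute_partial(summary, details, respondents, tables: ReferenceTables,
                   seed, recency_cutoff_cmc, jitter="uniform") -> pd.DataFrame:
    """Partial imputation: keep all reported recent-death detail, impute the rest.

    Surviving siblings get a current age via the age-difference table; recent
    deaths keep their reported sex/age/date (only genuinely missing fields are
    filled, conditioning on what was reported); the remaining deaths —
    asserted by the respondent to predate the recency cutoff — draw (age at
    death, time since death) from the schedule truncated beyond the cutoff.
    """
    return _impute(summary, details, respondents, tables, seed,
                   recency_cutoff_cmc, "partial", jitter)


def impute_complete(summary, details, respondents, tables: ReferenceTables,
                    seed, recency_cutoff_cmc, jitter="uniform") -> pd.DataFrame:
    """Complete imputation: redraw every death from the reference schedule.

    Reported ages and dates of recent deaths are discarded; only the
    counts of siblings ever born / alive / dead (by sex where collected)
    are used. Every death field in the output is flagged imputed.
    """
    return _impute(summary, details, respondents, tables, seed,
                   recency_cutoff_cmc, "complete", jitter)
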