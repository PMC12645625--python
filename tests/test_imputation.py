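import numpy as np
import pandas as pd
import pytest

from conftest import CUTOFF, INTERVIEW, make_respondents, make_siblings
from sibmort.imputation import (ReferenceTables, build_reference_tables,
                                fallback_key, impute_complete, impute_partial)
from sibmort.synthetic import collapse_to_summary


def degenerate_tables(gap=2, aad=40, tsd=2, groups=("15-19", "30-34", "50-54")):
    """Reference tables with unit mass on a single gap and (aad, tsd) pair."""
    tables = ReferenceTables(age_groups=list(groups))
    from sibmort.imputation import _entry
    for ag in tables.age_groups + ["all"]:
        for sex in ("m", "f", "all"):
            tables.age_diff[(ag, sex)] = _entry([gap], [1.0])
            tables.death_sched[(ag, sex)] = _entry([(aad, tsd)], [1.0])
    return tables


class TestBuildTables:
    def test_constant_gap_reference_gives_unit_mass(self):
        resp = make_respondents([20, 30, 40, 52])
        rows = []
        for rid, age in zip(resp["respondent_id"], resp["age_years"]):
            rows.append({"respondent_id": rid, "alive": True,
                         "age_now": age - 2,
                         "birth_cmc": INTERVIEW - 12 * (age - 2) - 6})
        tables = build_reference_tables(make_siblings(rows), resp)
        for key, entry in tables.age_diff.items():
            assert entry["values"] == [2]
            assert entry["probs"][0] == pytest.approx(1.0)

    def test_histograms_normalised(self, survey):
        resp, sib = survey
        tables = build_reference_tables(sib, resp)
        for entry in list(tables.age_diff.values()) + list(tables.death_sched.values()):
            assert entry["probs"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_weights_shift_the_histogram(self):
        resp = make_respondents([30, 30])
        sib = make_siblings([
            {"respondent_id": "p0000", "alive": True, "age_now": 28,
             "birth_cmc": 1140},
            {"respondent_id": "p0001", "alive": True, "age_now": 25,
             "birth_cmc": 1176},
        ])
        tables = build_reference_tables(sib, resp, weights=[1.0, 3.0])
        entry = tables.age_diff[("30-34", "f")]
        assert dict(zip(entry["values"], entry["probs"])) == pytest.approx(
            {2: 0.25, 5: 0.75})

    def test_serialisation_round_trip(self, survey):
        resp, sib = survey
        tables = build_reference_tables(sib, resp)
        back = ReferenceTables.from_frame(tables.to_frame())
        key = ("30-34", "f")
        assert np.allclose(back.age_diff[key]["probs"],
                           tables.age_diff[key]["probs"])


class TestFallback:
    def test_exact_key_wins(self):
        t = degenerate_tables()
        assert fallback_key(("30-34", "m"), t.age_diff, t.age_groups) == ("30-34", "m")

    def test_sex_collapse(self):
        t = degenerate_tables()
        del t.age_diff[("30-34", "m")]
        assert fallback_key(("30-34", "m"), t.age_diff, t.age_groups) == ("30-34", "all")

    def test_adjacent_age_group(self):
        t = degenerate_tables()
        for sex in ("m", "f", "all"):
            del t.age_diff[("30-34", sex)]
        assert fallback_key(("30-34", "m"), t.age_diff,
                            t.age_groups)[0] in ("15-19", "50-54")

    def test_global_pool_warns(self):
        t = degenerate_tables()
        keep = {("all", "all"): t.age_diff[("all", "all")]}
        with pytest.warns(UserWarning, match="global"):
            assert fallback_key(("30-34", "m"), keep, t.age_groups) == ("all", "all")

    def test_empty_tables_raise(self):
        with pytest.raises(ValueError, match="no usable"):
            fallback_key(("30-34", "m"), {}, ["30-34"])


class TestImputePartial:
    def test_degenerate_gap_sets_every_survivor_age(self):
        resp = make_respondents([30])
        summary = pd.DataFrame({"respondent_id": ["p0000"], "n_ever": [3],
                                "n_alive": [3], "n_dead": [0]})
        out = impute_partial(summary, None, resp, degenerate_tables(gap=2),
                             seed=1, recency_cutoff_cmc=CUTOFF)
        assert (out["age_now"] == 28).all()
        assert out["alive"].all() and len(out) == 3

    def test_reported_recent_details_preserved(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF)
        out = impute_partial(summary, details, resp,
                             build_reference_tables(sib, resp),
                             seed=2, recency_cutoff_cmc=CUTOFF)
        from sibmort.data_model import details_death_cmc
        reported = details.assign(death_cmc=details_death_cmc(details))
        dead = out[~out["alive"]]
        for rid, g in reported.groupby("respondent_id"):
            mine = dead[dead["respondent_id"] == rid]
            got = set(zip(mine["sex"], mine["age_at_death"], mine["death_cmc"]))
            for det in g.itertuples(index=False):
                assert (det.sex, det.age_at_death, float(det.death_cmc)) in got

    def test_count_conservation(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF)
        for fn in (impute_partial, impute_complete):
            out = fn(summary, details, resp, build_reference_tables(sib, resp),
                     seed=3, recency_cutoff_cmc=CUTOFF)
            counts = out.groupby("respondent_id").agg(
                n_ever=("line_no", "size"), n_alive=("alive", "sum"))
            merged = summary.merge(counts, on="respondent_id",
                                   suffixes=("", "_out"))
            assert (merged["n_ever"] == merged["n_ever_out"]).all()
            assert (merged["n_alive"] == merged["n_alive_out"]).all()

    def test_non_recent_deaths_predate_cutoff(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF)
        out = impute_partial(summary, details, resp,
                             build_reference_tables(sib, resp),
                             seed=4, recency_cutoff_cmc=CUTOFF)
        imputed_deaths = out[~out["alive"]
                             & out["imputed_fields"].str.contains("death_cmc")]
        assert (imputed_deaths["death_cmc"] < CUTOFF).all()

    def test_drc_variant_imputes_missing_age_at_death(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF, variant="drc")
        out = impute_partial(summary, details, resp,
                             build_reference_tables(sib, resp),
                             seed=5, recency_cutoff_cmc=CUTOFF)
        recent = out[~out["alive"] & (out["death_cmc"] >= CUTOFF)]
        assert recent["age_at_death"].notna().all()
        assert recent["imputed_fields"].str.contains("age_at_death").all()

    def test_respondent_order_does_not_change_draws(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF)
        tables = build_reference_tables(sib, resp)
        fwd = impute_partial(summary.head(50), details, resp, tables,
                             seed=6, recency_cutoff_cmc=CUTOFF)
        rev = impute_partial(summary.head(50).iloc[::-1], details, resp, tables,
                             seed=6, recency_cutoff_cmc=CUTOFF)
        key = ["respondent_id", "line_no"]
        pd.testing.assert_frame_equal(
            fwd.sort_values(key).reset_index(drop=True),
            rev.sort_values(key).reset_index(drop=True))


class TestImputeComplete:
    def test_degenerate_joint_table_fixes_all_dates(self):
        resp = make_respondents([30])
        summary = pd.DataFrame({"respondent_id": ["p0000"], "n_ever": [2],
                                "n_alive": [0], "n_dead": [2]})
        out = impute_complete(summary, None, resp,
                              degenerate_tables(aad=40, tsd=2),
                              seed=1, recency_cutoff_cmc=CUTOFF, jitter="none")
        assert (out["death_cmc"] == INTERVIEW - 24).all()
        assert (out["birth_cmc"] == INTERVIEW - 24 - 480).all()

    def test_reported_details_discarded_and_flagged(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF)
        out = impute_complete(summary, details, resp,
                              build_reference_tables(sib, resp),
                              seed=2, recency_cutoff_cmc=CUTOFF)
        dead = out[~out["alive"]]
        for f in ("age_at_death", "death_cmc", "birth_cmc"):
            assert dead["imputed_fields"].str.contains(f).all()

    def test_malawi_variant_keeps_sex_unknown(self, survey):
        resp, sib = survey
        summary, details = collapse_to_summary(sib, resp, CUTOFF,
                                               variant="malawi")
        out = impute_complete(summary, details, resp,
                              build_reference_tables(sib, resp),
                              seed=7, recency_cutoff_cmc=CUTOFF)
        assert (out["sex"] == "u").all()
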