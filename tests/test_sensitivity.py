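"""Re-inclusion scenarios, coverage-gap exclusion, stratified agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from claimsagree.agreement import build_table, cohen_kappa, table_from_cells
from claimsagree.design import compute_weights
from claimsagree.sensitivity import (
    ScenarioSpec,
    exclude_coverage_gaps,
    reinclusion_scenario,
    stratified_agreement,
)


@pytest.fixture()
def design():
    return compute_weights(
        {"BCG+/Asthma+": 1000, "BCG+/Asthma-": 9000,
         "BCG-/Asthma+": 1000, "BCG-/Asthma-": 9000},
        {"BCG+/Asthma+": 400, "BCG+/Asthma-": 410,
         "BCG-/Asthma+": 405, "BCG-/Asthma-": 395},
    )


def weighted_table(rng, design, n=1600):
    strata = rng.choice(design.table.index, n)
    w = design.person_weights(pd.Series(strata))
    admin = rng.random(n) < np.where(pd.Series(strata).str.contains(r"Asthma\+"), 0.9, 0.08)
    self_ = admin ^ (rng.random(n) < 0.1)
    return build_table(admin, self_, w), float(w.sum())


class TestReinclusionScenario:
    def test_noop_when_nothing_excluded(self, rng, design):
        table, W = weighted_table(rng, design)
        base = cohen_kappa(table).estimate
        kap = reinclusion_scenario(table, design, ScenarioSpec(0.0, 1.0), total_weight=W)
        assert kap.estimate == pytest.approx(base)

    def test_zero_report_fraction_mass_lands_in_cell_d(self, rng, design):
        table, W = weighted_table(rng, design)
        spec = ScenarioSpec(0.059, 0.0)
        non_asthma_n = int(design.table.loc[
            design.table.index.str.contains("Asthma-"), "n_survey"
        ].sum())
        m_add = round(0.059 / (1 - 0.059) * non_asthma_n)
        # reconstruct the rebuilt table via the module, check cell routing
        kap = reinclusion_scenario(table, design, spec, total_weight=W)
        assert kap.estimate == pytest.approx(
            cohen_kappa(_manual_reinclude(table, design, spec, W)).estimate
        )
        manual = _manual_reinclude(table, design, spec, W)
        assert manual.c == table.c and manual.d == table.d + m_add

    def test_worst_not_above_intermediate_not_above_silent(self, rng, design):
        table, W = weighted_table(rng, design)
        k = {
            rf: reinclusion_scenario(
                table, design, ScenarioSpec(0.059, rf), total_weight=W
            ).estimate
            for rf in (1.0, 0.5, 0.0)
        }
        assert k[1.0] <= k[0.5] <= k[0.0]

    @given(
        cells=st.tuples(st.integers(50, 500), st.integers(1, 150),
                        st.integers(1, 150), st.integers(50, 800)),
        frac=st.floats(0.0, 0.3),
    )
    @settings(max_examples=80, deadline=None)
    def test_kappa_monotone_nonincreasing_in_report_fraction(self, cells, frac):
        design = compute_weights(
            {"BCG+/Asthma+": 1000, "BCG+/Asthma-": 9000,
             "BCG-/Asthma+": 1000, "BCG-/Asthma-": 9000},
            {"BCG+/Asthma+": 400, "BCG+/Asthma-": 410,
             "BCG-/Asthma+": 405, "BCG-/Asthma-": 395},
        )
        table = table_from_cells(*cells)
        prev = None
        for rf in (0.0, 0.25, 0.5, 0.75, 1.0):
            kap = reinclusion_scenario(
                table, design, ScenarioSpec(frac, rf), total_weight=float(table.n_actual)
            ).estimate
            if prev is not None:
                assert kap <= prev + 1e-12
            prev = kap

    def test_invalid_report_fraction(self):
        with pytest.raises(ValueError):
            ScenarioSpec(0.059, 1.5)


def _manual_reinclude(table, design, spec, W):
    non = design.table[design.table.index.str.contains("Asthma-")]
    n_non = int(non["n_survey"].sum())
    m_add = round(spec.excluded_fraction / (1 - spec.excluded_fraction) * n_non)
    added_w = sum(
        m_add * (r["n_survey"] / n_non) * r["weight"] for _, r in non.iterrows()
    )
    n_yes = round(spec.report_fraction * m_add)
    w_yes = added_w * n_yes / m_add
    p = np.array([table.p_a, table.p_b, table.p_c, table.p_d]) * W
    p[2] += w_yes
    p[3] += added_w - w_yes
    p /= W + added_w
    from claimsagree.agreement import AgreementTable

    return AgreementTable(
        table.a, table.b, table.c + n_yes, table.d + (m_add - n_yes),
        *p, table.n_actual + m_add,
    )


class TestCoverageGaps:
    def _persons(self, gaps):
        return pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(len(gaps))], "coverage_gaps": gaps}
        )

    def test_no_gaps_unchanged(self):
        persons = self._persons(["", "", ""])
        events = pd.DataFrame({"person_id": ["p0", "p2"], "date": pd.to_datetime(["1990-01-01"] * 2)})
        kept_p, kept_e = exclude_coverage_gaps(persons, events)
        assert len(kept_p) == 3 and len(kept_e) == 2

    def test_gap_inside_period_removes_person(self):
        persons = self._persons(["1985-01-01/1985-06-30", "", "1995-01-01/1995-12-31"])
        kept_p, _ = exclude_coverage_gaps(persons, pd.DataFrame({"person_id": [], "date": []}))
        # p0 intersects 1983-1994; p2's gap is outside the checkable period
        assert kept_p["person_id"].tolist() == ["p1", "p2"]

    def test_agreement_rises_when_gapped_persons_are_discordant(self):
        # constructed fixture: gapped persons all disagree between sources
        n = 100
        gapped = np.arange(n) < 10
        admin = np.ones(n, bool)
        self_ = np.where(gapped, False, True)
        persons = self._persons(
            ["1986-01-01/1986-12-31" if g else "" for g in gapped]
        )
        persons["admin"] = admin
        persons["self"] = self_
        kept, _ = exclude_coverage_gaps(persons, pd.DataFrame({"person_id": [], "date": []}))
        from claimsagree.agreement import overall_agreement

        before = overall_agreement(build_table(admin, self_)).estimate
        after = overall_agreement(
            build_table(kept["admin"], kept["self"])
        ).estimate
        assert after > before


class TestStratifiedAgreement:
    def _hand_fixture(self):
        # six persons with known bin assignments
        return pd.DataFrame(
            {
                "agree": [True, False, True, True, False, True],
                "age_at_first": [8.2, 11.9, 12.0, 17.9, 18.0, 30.5],
                "age_at_last": [9, 12, 15, 20, 25, 38],
                "duration_years": [0.5, 5.9, 6.0, 10.9, 11.0, 29.0],
                "any_hospitalization": [True, False, False, True, False, True],
            }
        )

    def test_hand_worked_bins(self):
        sub = self._hand_fixture()
        by_first = stratified_agreement(sub, "age_at_first")
        # ages floor to 8,11 | 12,17 | 18,30
        assert by_first["8-11"] == pytest.approx(50.0)
        assert by_first["12-17"] == pytest.approx(100.0)
        assert by_first[">=18"] == pytest.approx(50.0)
        by_dur = stratified_agreement(sub, "duration")
        assert by_dur["0-5"] == pytest.approx(50.0)
        assert by_dur["6-10"] == pytest.approx(100.0)
        assert by_dur["11-20"] == pytest.approx(0.0)
        assert by_dur[">=21"] == pytest.approx(100.0)
        by_hosp = stratified_agreement(sub, "any_hospitalization")
        # hospitalized: persons 1,4,6 all agree; others: only person 3 agrees
        assert by_hosp["yes"] == pytest.approx(100.0)
        assert by_hosp["no"] == pytest.approx(100 / 3)

    def test_all_concordant_subset_is_100(self):
        sub = self._hand_fixture().assign(agree=True)
        for strat in ("age_at_first", "age_at_last", "duration", "any_hospitalization"):
            vals = stratified_agreement(sub, strat).dropna()
            assert (vals == 100.0).all()

    def test_empty_bin_is_nan_not_zero(self):
        sub = self._hand_fixture().iloc[:1]  # only age 8
        out = stratified_agreement(sub, "age_at_first")
        assert np.isnan(out[">=18"])

    def test_bins_partition_subset(self, rng):
        n = 200
        sub = pd.DataFrame(
            {
                "agree": rng.random(n) < 0.7,
                "age_at_first": rng.uniform(8, 38, n),
                "age_at_last": rng.uniform(8, 38, n),
                "duration_years": rng.uniform(0, 30, n),
                "any_hospitalization": rng.random(n) < 0.3,
            }
        )
        for strat, col in (
            ("age_at_first", "age_at_first"),
            ("duration", "duration_years"),
        ):
            counts = []
            from claimsagree.sensitivity import STRATIFIERS

            vals = np.floor(sub[col]).astype(int)
            for lo, hi in STRATIFIERS[strat]:
                m = vals >= lo if hi is None else (vals >= lo) & (vals <= hi)
                counts.append(m.sum())
            assert sum(counts) == n

    def test_unknown_stratifier_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            stratified_agreement(self._hand_fixture(), "zodiac")


def test_generator_duration_gradient(small_cohort):
    """Self-report accuracy rises with disease duration, so agreement in the
    asthma-service subset increases across duration bins."""
    from claimsagree.ascertainment import AlgorithmSpec, classify_cohort
    from claimsagree.determinants import agreement_outcome
    from claimsagree.events import normalize_events

    co = small_cohort
    ev = normalize_events(co.events)
    res = classify_cohort(ev, co.persons, AlgorithmSpec(window_years=30)).set_index("person_id")
    sr = co.self_reports.set_index("person_id")
    ids = res.index
    phys = sr.loc[ids, "physician_diagnosed"]
    has_service = (res["n_claims"] + res["n_hosp"]) >= 1
    either = res["status"] | phys.eq(True).to_numpy()
    keep = (has_service & either & phys.notna().to_numpy()).to_numpy()

    first = pd.to_datetime(res["first_date"][keep])
    last = pd.to_datetime(res["last_date"][keep])
    sub = pd.DataFrame(
        {
            "agree": agreement_outcome(
                res["status"][keep].to_numpy(), phys[keep].to_numpy()
            ).astype(bool).to_numpy(),
            "age_at_first": (first - pd.Timestamp("1974-07-01")).dt.days / 365.25,
            "age_at_last": (last - pd.Timestamp("1974-07-01")).dt.days / 365.25,
            "duration_years": (last - first).dt.days / 365.25,
            "any_hospitalization": (res["n_hosp"][keep] >= 1).to_numpy(),
        }
    )
    by_dur = stratified_agreement(sub, "duration")
    vals = by_dur.to_numpy()
    assert vals[0] < vals[-1]  # short-duration asthma agrees worst
    assert (np.diff(vals) >= -2.0).all()  # non-decreasing up to bin noise
    by_hosp = stratified_agreement(sub, "any_hospitalization")
    assert by_hosp["yes"] > by_hosp["no"]
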