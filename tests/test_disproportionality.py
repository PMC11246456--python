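"""2×2 construction, ROR estimation, the signal rule and screens."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignal.disproportionality import (
    ContingencyTable,
    SignalEstimate,
    StratumSpec,
    build_pt_contingency,
    compute_ror,
    evaluate_signal,
    pt_tally,
    screen_soc,
    stratified_screen,
)

from conftest import make_case


def wald_oracle(a, b, c, d):
    """Independent direct evaluation of the Wald log-odds interval."""
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return ror, math.exp(math.log(ror) - z * se), math.exp(math.log(ror) + z * se)


class TestContingency:
    def test_direct_tally(self):
        t = build_pt_contingency({"X": 10, "Y": 90}, {"X": 100, "Y": 9900}, "X")
        assert (t.a, t.b, t.c, t.d) == (10, 90, 100, 9900)

    def test_absent_pt_zero_cells(self):
        t = build_pt_contingency({"Y": 100}, {"Y": 10000}, "X")
        assert (t.a, t.b, t.c, t.d) == (0, 100, 0, 10000)

    def test_row_totals_conserved_over_all_pts(self):
        rng = np.random.default_rng(0)
        drug = {f"PT{i}": int(rng.integers(0, 50)) for i in range(30)}
        bg = {f"PT{i}": int(rng.integers(0, 500)) for i in range(30)}
        for pt in drug:
            t = build_pt_contingency(drug, bg, pt)
            assert t.a + t.b == sum(drug.values())
            assert t.c + t.d == sum(bg.values())

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestComputeRor:
    def test_wald_formula_example(self):
        est = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert est.ror == pytest.approx(11.0)
        assert est.ci_low == pytest.approx(5.56, abs=0.005)
        assert est.ci_high == pytest.approx(21.764, abs=0.005)

    def test_symmetric_table_is_null(self):
        assert compute_ror(ContingencyTable(5, 5, 5, 5)).ror == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        est = compute_ror(ContingencyTable(0, 10, 10, 1000))
        assert est.corrected
        a, b, c, d = 0.5, 10.5, 10.5, 1000.5
        assert est.ror == pytest.approx((a * d) / (b * c))
        assert est.n == 0  # reported count stays uncorrected

    def test_empty_margin_is_error(self):
        est = compute_ror(ContingencyTable(0, 0, 10, 1000))
        assert est.error is not None and math.isnan(est.ror)

    def test_agrees_with_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            a, b, c, d = (int(v) for v in rng.integers(1, 1000, size=4))
            est = compute_ror(ContingencyTable(a, b, c, d))
            ror, lo, hi = wald_oracle(a, b, c, d)
            assert est.ror == pytest.approx(ror, abs=1e-9, rel=1e-9)
            assert est.ci_low == pytest.approx(lo, abs=1e-9, rel=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9, rel=1e-9)

    @given(
        st.integers(1, 500), st.integers(1, 500),
        st.integers(1, 500), st.integers(1, 500),
    )
    def test_ci_brackets_point_estimate(self, a, b, c, d):
        est = compute_ror(ContingencyTable(a, b, c, d))
        assert est.ci_low <= est.ror <= est.ci_high

    def test_monotone_in_a_cell(self):
        prev = None
        for a in range(1, 60, 5):
            est = compute_ror(ContingencyTable(a, 100, 50, 5000))
            if prev is not None:
                assert est.ror > prev.ror and est.ci_low > prev.ci_low
            prev = est


class TestSignalRule:
    @pytest.mark.parametrize(
        "n,ci_low,expected",
        [
            (67, 16.80, True),   # clear signal
            (4, 3.0, False),     # count rule: n < 5
            (5, 1.0001, True),   # both boundaries just met
            (100, 1.0, False),   # strict inequality on ci_low
            (5, 0.99, False),
        ],
    )
    def test_boundaries(self, n, ci_low, expected):
        est = SignalEstimate(pt="X", n=n, ror=2.0, ci_low=ci_low, ci_high=99.0)
        assert evaluate_signal(est).significant is expected

    def test_null_false_positive_rate_below_nominal(self):
        """200 PTs with no injected signal: ≤5% flagged (seeded draw)."""
        rng = np.random.default_rng(2024)
        n_pts = 200
        probs = rng.dirichlet(np.full(n_pts, 5.0))
        drug_counts = rng.multinomial(20000, probs)
        bg_counts = rng.multinomial(200000, probs)
        drug = {f"PT{i}": int(c) for i, c in enumerate(drug_counts)}
        bg = {f"PT{i}": int(c) for i, c in enumerate(bg_counts)}
        flagged = 0
        for pt in drug:
            est = evaluate_signal(compute_ror(build_pt_contingency(drug, bg, pt), pt))
            flagged += est.significant
        assert flagged / n_pts <= 0.05


class TestScreens:
    def test_injected_signal_flagged_nulls_not(self):
        rng = np.random.default_rng(5)
        n_pts = 20
        q = np.full(n_pts, 1 / n_pts)
        p = q.copy()
        p[0] *= 10  # one strong signal
        p /= p.sum()
        drug = {f"PT{i}": int(c) for i, c in enumerate(rng.multinomial(5000, p))}
        bg = {f"PT{i}": int(c) for i, c in enumerate(rng.multinomial(100000, q))}
        pt_to_soc = {f"PT{i}": "1" for i in range(n_pts)}
        ests, _ = screen_soc(drug, bg, pt_to_soc, "1")
        by_pt = {e.pt: e for e in ests}
        assert by_pt["PT0"].significant
        assert sum(e.significant for e in ests) <= 2  # signal + at most 1 fluke

    def test_soc_a_cell_pools_member_pts(self):
        drug = {"A": 10, "B": 20, "C": 5}
        bg = {"A": 100, "B": 200, "C": 500}
        pt_to_soc = {"A": "1", "B": "1", "C": "2"}
        ests, soc_est = screen_soc(drug, bg, pt_to_soc, "1")
        assert soc_est.n == 30  # = a-cells of A and B
        assert {e.pt for e in ests} == {"A", "B"}
        assert [e.ci_low for e in ests] == sorted(
            (e.ci_low for e in ests), reverse=True
        )

    def test_empty_soc_yields_empty_list(self):
        ests, soc_est = screen_soc({"A": 1}, {"A": 10}, {"A": "1"}, "99")
        assert ests == [] and soc_est.n == 0


def _stratified_cases(sex, n, pts, drugname="VIMPAT"):
    return [
        make_case(
            caseid=f"{sex}{drugname}{i}", primaryid=f"{i}1", sex=sex, pts=pts,
            drugs=[(1, "PS", drugname, drugname)],
        )
        for i in range(n)
    ]


class TestStratified:
    def test_identical_strata_identical_ror(self, lacosamide_config):
        drug = _stratified_cases("F", 30, ["Bradycardia", "Nausea"]) + \
            _stratified_cases("M", 30, ["Bradycardia", "Nausea"])
        bg = _stratified_cases("F", 100, ["Bradycardia"] + ["Nausea"] * 9, "MET") + \
            _stratified_cases("M", 100, ["Bradycardia"] + ["Nausea"] * 9, "MET")
        # identical composition per stratum -> identical estimates
        out = stratified_screen(
            drug, bg, [StratumSpec("sex", "F"), StratumSpec("sex", "M")],
            lacosamide_config,
        )
        assert out[0].estimate.ror == pytest.approx(out[1].estimate.ror)

    def test_signal_only_in_females(self, lacosamide_config):
        drug = _stratified_cases("F", 40, ["Bradycardia", "Nausea"]) + \
            _stratified_cases("M", 40, ["Nausea", "Headache"])
        bg = (
            _stratified_cases("F", 200, ["Bradycardia"] + ["Nausea"] * 19, "MET")
            + _stratified_cases("M", 200, ["Bradycardia"] + ["Nausea"] * 19, "MET")
        )
        out = stratified_screen(
            drug, bg, [StratumSpec("sex", "F"), StratumSpec("sex", "M")],
            lacosamide_config,
        )
        female, male = out
        assert female.estimate.ror > (male.estimate.ror if male.estimate else 0)

    def test_zero_drug_events_gives_error_entry_and_continues(
        self, lacosamide_config
    ):
        drug = _stratified_cases("F", 10, ["Bradycardia"])
        bg = _stratified_cases("F", 50, ["Bradycardia", "Nausea"], "MET")
        out = stratified_screen(
            drug, bg, [StratumSpec("sex", "M"), StratumSpec("sex", "F")],
            lacosamide_config,
        )
        assert out[0].error is not None and out[0].estimate is None
        assert out[1].estimate is not None

    def test_pooled_cells_equal_stratum_sums_without_missingness(
        self, lacosamide_config
    ):
        drug = _stratified_cases("F", 25, ["Bradycardia", "Nausea"]) + \
            _stratified_cases("M", 15, ["Cardiac arrest"])
        bg = _stratified_cases("F", 60, ["Nausea"], "MET") + \
            _stratified_cases("M", 40, ["Bradycardia", "Nausea"], "MET")
        out = stratified_screen(
            drug, bg, [StratumSpec("sex", "F"), StratumSpec("sex", "M")],
            lacosamide_config,
        )
        pooled_a = sum(s.n for s in out)
        pooled_b = sum(s.nl for s in out)
        from pvsignal.cohort import soc_pts

        assert pooled_a == sum(len(soc_pts(c, lacosamide_config)) for c in drug)
        assert pooled_a + pooled_b == sum(v for v in pt_tally(drug).values())


def test_estimated_ror_converges_to_configured_association(tmp_path):
    """Generator→pipeline recovery: the screen's ROR approaches the
    configured odds multiplier as the report count grows."""
    from pvsignal.simulate import SyntheticConfig, generate
    from pvsignal.faers import assemble_cases, read_quarter_dir
    from pvsignal.cohort import CohortConfig, deduplicate, mentions_drug, select_drug_cases

    config = SyntheticConfig(
        n_background_cases=30000, n_drug_cases=10000, duplicate_rate=0.0, seed=17,
    )
    generate(config, tmp_path)
    cases = deduplicate(assemble_cases(read_quarter_dir(tmp_path)))
    cc = CohortConfig(
        generic_names=["LACOSAMIDE"], trade_names=["VIMPAT"],
        pt_to_soc={pt: soc for pt, soc, _ in config.pt_catalog},
        target_soc_code="10007541",
    )
    drug = pt_tally(select_drug_cases(cases, cc))
    bg = pt_tally([c for c in cases if not mentions_drug(c, cc)])
    # strongest-count signal: tight tolerance; weaker ones: sampling slack
    expected = config.expected_ror()
    est = compute_ror(build_pt_contingency(drug, bg, "Bradycardia"), "Bradycardia")
    assert est.ror == pytest.approx(expected["Bradycardia"], rel=0.10)
    for pt in config.signal_spec:
        est = compute_ror(build_pt_contingency(drug, bg, pt), pt)
        assert est.ror == pytest.approx(expected[pt], rel=0.35)
        assert evaluate_signal(est).significant == (expected[pt] > 1.4)
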