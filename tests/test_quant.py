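"""Copies-per-cell quantification, QC, typing and reconciliation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_replicate_rows
from srmquant.pipeline import simulate_and_quantify
from srmquant.quant import (
    choose_spike_level, classify_peptide, outcome_percentages, peptide_cpc,
    qc_filter, quantify_proteins, quantify_qconcat_stock,
    reconcile_and_aggregate, robust_cv, upper_limit_cpc,
)
from srmquant.syndata import SimConfig


class TestStockQuantification:
    def test_equal_areas_return_spike(self):
        assert quantify_qconcat_stock(1e6, 1e6) == pytest.approx(21.5)

    def test_linearity(self):
        assert quantify_qconcat_stock(1e6, 2e6) == pytest.approx(43.0)

    def test_zero_light_area(self):
        with pytest.raises(ValueError):
            quantify_qconcat_stock(0.0, 1e6)


class TestPeptideCpc:
    def test_one_femtomole_on_two_hundred_thousand_cells(self):
        assert peptide_cpc(1.0, 1e-15, 2e5) == pytest.approx(3.011e3, rel=1e-3)

    def test_zero_ratio(self):
        assert peptide_cpc(0.0, 1e-15, 2e5) == 0.0

    def test_linearity_in_ratio(self):
        assert peptide_cpc(2.0, 1e-15, 2e5) == pytest.approx(
            2 * peptide_cpc(1.0, 1e-15, 2e5))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            peptide_cpc(1.0, 1e-15, 0.0)
        with pytest.raises(ValueError):
            peptide_cpc(-1.0, 1e-15, 2e5)


def _spike_rows(medians: dict) -> pd.DataFrame:
    amounts = {"low": 1.75e-16, "medium": 1.5e-15, "high": 1.5e-14}
    rows = []
    for label, med in medians.items():
        for r in range(4):
            rows.append({"spike_label": label, "ratio": med,
                         "spike_amount_mol": amounts[label]})
    return pd.DataFrame(rows)


class TestSpikeChoice:
    def test_closest_to_unity_within_bounds(self):
        label, flag = choose_spike_level(_spike_rows({"low": 15, "medium": 2, "high": 0.3}))
        assert label == "medium" and not flag

    def test_single_level(self):
        label, flag = choose_spike_level(_spike_rows({"low": 0.5}))
        assert label == "low" and not flag

    def test_all_out_of_range_flags(self):
        label, flag = choose_spike_level(_spike_rows({"low": 100, "medium": 30, "high": 12}))
        assert label == "high" and flag

    def test_tie_prefers_higher_spike(self):
        label, _ = choose_spike_level(_spike_rows({"low": 2.0, "medium": 2.0}))
        assert label == "medium"

    def test_empty_rows_error(self):
        with pytest.raises(ValueError):
            choose_spike_level(pd.DataFrame(columns=["spike_label", "ratio",
                                                     "spike_amount_mol"]))


class TestQcFilter:
    def test_all_replicates_passing(self):
        ok, passing = qc_filter(make_replicate_rows())
        assert ok and len(passing) == 4

    def test_two_of_four_fails(self):
        rows = make_replicate_rows(q_value=[0.005, 0.005, 0.5, 0.5])
        ok, passing = qc_filter(rows)
        assert not ok and len(passing) == 2

    def test_sn_failure_counts_against_quorum(self):
        # 3 replicates pass FDR but one of them has S/N 4: only 2 fully pass
        rows = make_replicate_rows(q_value=[0.005, 0.005, 0.005, 0.5],
                                   sn=[10.0, 10.0, 4.0, 10.0])
        ok, passing = qc_filter(rows)
        assert not ok and len(passing) == 2

    def test_lenient_sn_reading(self):
        rows = make_replicate_rows(q_value=[0.005, 0.005, 0.005, 0.5],
                                   sn=[10.0, 10.0, 4.0, 10.0])
        ok, _ = qc_filter(rows, strict_sn=False)
        assert not ok  # the S/N<5 replicate still vetoes under "all had S/N>5"


class TestRobustCv:
    def test_constant_values(self):
        assert robust_cv([10, 10, 10]) == 0.0

    def test_hand_computed_example(self):
        assert robust_cv([8, 10, 12]) == pytest.approx(29.652, abs=1e-3)

    def test_scale_invariance(self, rng):
        x = rng.lognormal(3, 0.4, 20)
        assert robust_cv(7.7 * x) == pytest.approx(robust_cv(x), rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            robust_cv([5.0])
        with pytest.raises(ValueError):
            robust_cv([-2.0, -1.0, 0.0])


class TestTyping:
    @pytest.mark.parametrize("light,heavy,expected", [
        (True, True, "A"), (True, False, "A"),
        (False, True, "B"), (False, False, "C"),
    ])
    def test_classification(self, light, heavy, expected):
        assert classify_peptide(light, heavy) == expected

    def test_upper_limit_direct_substitution(self):
        # noise 100, heavy 1e5, spike 1 fmol: bound = (500/1e5) x 3011 cpc
        bound = upper_limit_cpc(1e5, 100.0, 1e-15, 2e5)
        assert bound == pytest.approx(15.06, abs=0.05)

    def test_upper_limit_linearity_and_monotonicity(self):
        b = upper_limit_cpc(1e5, 100.0, 1e-15, 2e5)
        assert upper_limit_cpc(1e5, 200.0, 1e-15, 2e5) == pytest.approx(2 * b)
        assert upper_limit_cpc(2e5, 100.0, 1e-15, 2e5) < b

    def test_upper_limit_requires_heavy(self):
        with pytest.raises(ValueError):
            upper_limit_cpc(0.0, 100.0, 1e-15, 2e5)


def _pair(x, y, types=("A", "A")):
    return pd.DataFrame({
        "peptide_id": ["p1", "p2"],
        "protein_group_id": ["g", "g"],
        "type": list(types),
        "cpc": [x, y],
        "rcv_percent": [10.0, 12.0],
        "replicate_cpc": [[x * f for f in (0.95, 1.0, 1.05)],
                          [y * f for f in (0.95, 1.0, 1.05)]],
    })


class TestReconciliation:
    def test_concordant_pair_averaged(self):
        assert reconcile_and_aggregate(_pair(1000, 800)).cpc == pytest.approx(900)

    def test_discordant_pair_takes_higher(self):
        pq = reconcile_and_aggregate(_pair(1000, 400))
        assert pq.cpc == pytest.approx(1000)
        assert pq.rule == "higher_peptide"

    def test_equal_values_consistent(self):
        assert reconcile_and_aggregate(_pair(500, 500)).cpc == pytest.approx(500)

    def test_ab_takes_a_peptide(self):
        pq = reconcile_and_aggregate(_pair(1000, 50, types=("A", "B")))
        assert pq.cpc == pytest.approx(1000) and pq.protein_class == "AB"
        assert not pq.upper_limit

    def test_bb_takes_min_bound(self):
        pq = reconcile_and_aggregate(_pair(300, 500, types=("B", "B")))
        assert pq.cpc == pytest.approx(300) and pq.upper_limit

    def test_cc_yields_nothing(self):
        df = _pair(np.nan, np.nan, types=("C", "C"))
        df["cpc"] = [None, None]
        pq = reconcile_and_aggregate(df)
        assert pq.cpc is None and pq.rule == "none"

    def test_just_past_threshold_goes_to_higher(self):
        y = 1000 / 2 ** 0.56
        assert reconcile_and_aggregate(_pair(1000, y)).rule == "higher_peptide"
        y = 1000 / 2 ** 0.52
        assert reconcile_and_aggregate(_pair(1000, y)).rule == "median_of_pair"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            reconcile_and_aggregate(_pair(1, 1).iloc[0:0])


class TestPipelineProperties:
    def test_class_tally_conservation_and_rcv(self):
        cfg = SimConfig(n_genes=150, seed=21)
        truth, peptides, proteins = simulate_and_quantify(cfg)
        assert len(proteins) == cfg.n_genes
        counts = proteins["class"].value_counts()
        assert counts.sum() == cfg.n_genes
        assert set(counts.index) <= {"AA", "AB", "AC", "BB", "BC", "CC", "A", "B", "C"}
        # Type-B values are upper bounds and flagged as such
        b = proteins[proteins["class"].isin(["BB", "BC"])]
        assert b["upper_limit"].all()

    def test_cpc_invariant_to_uniform_area_rescaling(self):
        cfg = SimConfig(n_genes=25, seed=3)
        truth, pep_ref, _ = simulate_and_quantify(cfg)
        from srmquant import syndata
        from srmquant.pipeline import run_quantification
        peaks, _ = syndata.simulate_srm(truth, cfg)
        peaks2 = peaks.copy()
        mask = peaks2["replicate"] == 2
        peaks2.loc[mask, "area"] *= 3.0
        peaks2.loc[mask, "noise_area"] *= 3.0
        pep2, _ = run_quantification(peaks2)
        a = pep_ref[pep_ref["type"] == "A"].set_index("peptide_id")["cpc"]
        b = pep2[pep2["type"] == "A"].set_index("peptide_id")["cpc"]
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a[common], b[common], rtol=1e-9)


class TestOutcomeArithmetic:
    def test_percentages_sum_to_hundred(self):
        pct = outcome_percentages({"A": 3, "B": 2, "C": 5})
        assert sum(pct.values()) == pytest.approx(100.0)
        assert pct["A"] == pytest.approx(30.0)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            outcome_percentages({"A": 0})
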