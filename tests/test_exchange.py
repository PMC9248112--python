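"""Venoarterial differencing, median normalization, the paired screen, BH, Eq-style
percent transformation, and the p-value histogram diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaprot.errors import DataError, InsufficientDataError, UsageError
from vaprot.exchange import (
    VenoarterialDiffs,
    bh_adjust,
    median_normalize,
    paired_exchange_test,
    percent_change,
    pvalue_histogram_diagnostic,
    venoarterial_diffs,
)
from vaprot.simulate import SimConfig, simulate_four_vessel


def _vessel_table(rows):
    """rows: (participant, vessel, {protein: value})"""
    recs = [{"participant_id": pid, "vessel": v, **vals} for pid, v, vals in rows]
    return pd.DataFrame(recs)


def _diffs(arr, proteins=None, normalized=True):
    arr = np.atleast_2d(np.asarray(arr, float))
    cols = proteins or [f"p{i}" for i in range(arr.shape[1])]
    data = pd.DataFrame(arr, columns=cols,
                        index=[f"P{i}" for i in range(arr.shape[0])])
    return VenoarterialDiffs(data=data, vein="UV", artery="RA", normalized=normalized)


class TestVenoarterialDiffs:
    def test_manual_three_participant_fixture(self):
        table = _vessel_table([
            ("a", "RA", {"p1": 10.0, "p2": 8.0}),
            ("a", "UV", {"p1": 10.5, "p2": 7.0}),
            ("b", "RA", {"p1": 9.0, "p2": 9.0}),
            ("b", "UV", {"p1": 9.0, "p2": 9.5}),
            ("c", "RA", {"p1": 11.0, "p2": 10.0}),
            ("c", "UV", {"p1": 12.0, "p2": 10.0}),
        ])
        d = venoarterial_diffs(table, "UV", "RA")
        expected = pd.DataFrame({"p1": [0.5, 0.0, 1.0], "p2": [-1.0, 0.5, 0.0]},
                                index=pd.Index(["a", "b", "c"], name="participant_id"))
        pd.testing.assert_frame_equal(d.data, expected)
        assert d.pair == ("UV", "RA") and not d.normalized

    def test_identical_rows_give_zero(self):
        table = _vessel_table([
            ("a", "RA", {"p1": 10.0}), ("a", "UV", {"p1": 10.0}),
            ("b", "RA", {"p1": 9.0}), ("b", "UV", {"p1": 9.5}),
        ])
        d = venoarterial_diffs(table, "UV", "RA")
        assert d.data.loc["a", "p1"] == 0.0

    def test_complete_case_per_pair(self):
        # participant "b" lacks UV but has AV: excluded from UV-RA, kept in AV-RA
        table = _vessel_table([
            ("a", "RA", {"p1": 1.0}), ("a", "UV", {"p1": 2.0}), ("a", "AV", {"p1": 1.0}),
            ("b", "RA", {"p1": 1.0}), ("b", "AV", {"p1": 3.0}),
            ("c", "RA", {"p1": 1.0}), ("c", "UV", {"p1": 1.0}), ("c", "AV", {"p1": 1.0}),
        ])
        uv = venoarterial_diffs(table, "UV", "RA")
        av = venoarterial_diffs(table, "AV", "RA")
        assert list(uv.data.index) == ["a", "c"]
        assert list(av.data.index) == ["a", "b", "c"]

    def test_too_few_pairs(self):
        table = _vessel_table([("a", "RA", {"p1": 1.0}), ("a", "UV", {"p1": 2.0})])
        with pytest.raises(InsufficientDataError):
            venoarterial_diffs(table, "UV", "RA")


class TestMedianNormalize:
    def test_constant_bias_to_zero(self):
        d = _diffs([[0.3] * 11], normalized=False)
        out = median_normalize(d)
        assert np.allclose(out.data.to_numpy(), 0.0)
        assert out.normalized

    def test_subtract_median(self):
        d = _diffs([[1, 2, 3, 4, 5, 1, 2, 3, 4, 5, 3]], normalized=False)
        out = median_normalize(d)
        assert out.data.iloc[0].median() == 0.0
        np.testing.assert_allclose(out.data.iloc[0, :5], [-2, -1, 0, 1, 2])

    def test_double_normalization_rejected(self):
        d = _diffs([[0.0] * 12], normalized=True)
        with pytest.raises(UsageError):
            median_normalize(d)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_per_participant_bias_cancellation(self, seed):
        """normalize(D + c_i) == normalize(D) for any per-participant constants c."""
        rng = np.random.default_rng(seed)
        D = rng.normal(size=(6, 25))
        c = rng.normal(scale=3.0, size=6)
        a = median_normalize(_diffs(D, normalized=False))
        b = median_normalize(_diffs(D + c[:, None], normalized=False))
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), atol=1e-12)
        assert np.allclose(a.data.median(axis=1), 0.0)

    def test_planted_water_shift_recovered(self):
        cfg = SimConfig(n_participants=20, n_proteins=2001, frac_released=0.0,
                        frac_uptake=0.0, frac_arm_exchange=0.0,
                        pair_noise_sd=0.0, water_shift_sd=0.3, seed=8)
        table, truth = simulate_four_vessel(cfg)
        raw = venoarterial_diffs(table, "UV", "RA")
        # raw differences carry each participant's water shift ...
        shifts = pd.Series({pid: ws["UV"] for pid, ws in truth.water_shift.items()})
        np.testing.assert_allclose(raw.data.median(axis=1), shifts[raw.data.index],
                                   atol=1e-9)
        # ... normalization centers every participant at exactly zero
        out = median_normalize(raw)
        np.testing.assert_allclose(out.data.to_numpy(), 0.0, atol=1e-9)


class TestPairedScreen:
    def test_hand_computed_t(self):
        d = np.array([0.8, 1.1, 0.9, 1.2, 1.0])
        diffs = _diffs(np.column_stack([d] + [np.zeros(5)] * 10))
        res = paired_exchange_test(diffs, alpha=0.05)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.table.loc["p0", "t_stat"] == pytest.approx(expected_t, rel=1e-12)
        assert res.table.loc["p0", "n_pairs"] == 5

    def test_zero_variance_degenerate(self):
        diffs = _diffs(np.column_stack([np.zeros(5), np.random.default_rng(0).normal(size=5)]
                                       + [np.random.default_rng(i).normal(size=5)
                                          for i in range(9)]))
        res = paired_exchange_test(diffs)
        row = res.table.loc["p0"]
        assert row["degenerate"] and row["exchange_class"] == "none"
        assert np.isnan(row["p_raw"])

    def test_classification_thresholds(self):
        rng = np.random.default_rng(4)
        released = rng.normal(2.0, 0.1, size=(20, 3))
        uptaken = rng.normal(-2.0, 0.1, size=(20, 3))
        nulls = rng.normal(0.0, 0.1, size=(20, 14))
        diffs = _diffs(np.hstack([released, uptaken, nulls]))
        res = paired_exchange_test(diffs, alpha=0.05)
        t = res.table
        sig = t["p_fdr"] < 0.05
        assert (t.loc[sig & (t["t_stat"] > 0), "exchange_class"] == "released").all()
        assert (t.loc[sig & (t["t_stat"] < 0), "exchange_class"] == "uptake").all()
        assert (t.loc[~sig, "exchange_class"] == "none").all()
        assert set(t.index[t["exchange_class"] == "released"]) == {"p0", "p1", "p2"}
        assert set(t.index[t["exchange_class"] == "uptake"]) == {"p3", "p4", "p5"}
        assert (t["p_fdr"].dropna() >= t["p_raw"].dropna() - 1e-15).all()

    def test_requires_normalized(self):
        d = _diffs(np.random.default_rng(0).normal(size=(5, 12)), normalized=False)
        with pytest.raises(UsageError):
            paired_exchange_test(d)

    def test_antisymmetry_under_label_swap(self, small_four_vessel):
        _, table, _ = small_four_vessel
        fwd = paired_exchange_test(median_normalize(venoarterial_diffs(table, "UV", "RA")))
        rev = paired_exchange_test(median_normalize(venoarterial_diffs(table, "RA", "UV")))
        np.testing.assert_allclose(rev.table["t_stat"], -fwd.table["t_stat"], atol=1e-9)
        np.testing.assert_allclose(rev.table["mean_diff"], -fwd.table["mean_diff"],
                                   atol=1e-12)
        assert set(rev.released) == set(fwd.uptake)
        assert set(rev.uptake) == set(fwd.released)

    def test_bh_control_under_pure_null(self):
        """Expected classified fraction at FDR 0.05 over a pure-null cohort (200 seeds)."""
        fracs = []
        for s in range(200):
            cfg = SimConfig(n_participants=75, n_proteins=2000, frac_released=0.0,
                            frac_uptake=0.0, frac_arm_exchange=0.0, seed=20_000 + s)
            table, _ = simulate_four_vessel(cfg)
            res = paired_exchange_test(
                median_normalize(venoarterial_diffs(table, "UV", "RA")), alpha=0.05)
            fracs.append((res.table["exchange_class"] != "none").mean())
        assert np.mean(fracs) <= 0.05


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), 0.2)

    def test_stepup_with_monotone_enforcement(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_matches_stepup_oracle(self, seed, m):
        """Direct step-up computation: q_(i) = min over j>=i of m p_(j) / j, capped at 1."""
        p = np.random.default_rng(seed).uniform(size=m)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q[order[rank - 1]] = running
        np.testing.assert_allclose(bh_adjust(p), q, atol=1e-12)

    def test_domain_checked(self):
        with pytest.raises(DataError):
            bh_adjust([0.1, 1.4])


class TestPercentChange:
    @pytest.mark.parametrize("d, expected", [
        ([0.0, 0.0], 0.0),
        ([1.0, 1.0, 1.0], 100.0),
        ([1.0, -1.0], 25.0),
    ])
    def test_reference_points(self, d, expected):
        assert percent_change(d) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    def test_brute_force_equality(self, d):
        brute = (sum(2.0 ** x for x in d) / len(d) - 1.0) * 100.0
        assert percent_change(d) == pytest.approx(brute, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            percent_change([])

    def test_screen_column_matches_function(self, small_four_vessel):
        _, table, _ = small_four_vessel
        diffs = median_normalize(venoarterial_diffs(table, "UV", "RA"))
        res = paired_exchange_test(diffs)
        for protein in diffs.data.columns[:25]:
            assert res.table.loc[protein, "pct_change"] == pytest.approx(
                percent_change(diffs.data[protein]), abs=1e-9)


class TestPValueHistogram:
    def test_uniform_tail_passes(self):
        p = np.random.default_rng(0).uniform(size=5000)
        diag = pvalue_histogram_diagnostic(p)
        assert diag.uniform_tail_ok and not diag.degenerate

    def test_all_small_p_degenerate(self):
        diag = pvalue_histogram_diagnostic(np.full(1000, 0.001))
        assert diag.bin_counts[0] == 1000
        assert diag.degenerate and not diag.uniform_tail_ok

    def test_counts_conserved(self):
        p = np.random.default_rng(1).beta(0.5, 3.0, size=777)
        diag = pvalue_histogram_diagnostic(p)
        assert diag.bin_counts.sum() == 777

    def test_skewed_tail_fails_uniformity(self):
        rng = np.random.default_rng(2)
        p = rng.beta(5.0, 1.0, size=5000)  # mass piled near 1
        assert not pvalue_histogram_diagnostic(p).uniform_tail_ok
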