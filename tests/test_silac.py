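"""Half-life estimation from heavy/light peptide ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrilkit import silac
from fibrilkit.silac import TurnoverConfig


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "peptide", "channel", "intensity", "replicate"]
    )


class TestTurnoverEstimate:
    @pytest.mark.parametrize(
        "hl, expect_t_half",
        [
            # ln2 cancels: t_half = 1/(1/48 - 1/72) = 144 h exactly
            (1.0, 144.0),
            # direct numeric evaluation of the decay equations
            (1.5, 73.2532054119830),
        ],
    )
    def test_known_half_lives(self, hl, expect_t_half):
        est = silac.turnover_estimate(hl)
        assert est.t_half_h == pytest.approx(expect_t_half, rel=1e-10)
        assert not est.censored
        assert est.light_fraction == pytest.approx(1.0 / (hl + 1.0))

    def test_hl_15_rate_constant(self):
        est = silac.turnover_estimate(1.5)
        assert est.k_per_h == pytest.approx(0.0094623, abs=1e-7)

    def test_all_light_is_censored(self):
        est = silac.turnover_estimate(0.0)
        assert est.censored
        assert est.k_per_h == pytest.approx(-math.log(2) / 72)
        assert math.isnan(est.t_half_h)

    def test_censoring_boundary_is_dilution_only_hl(self):
        # k = 0 exactly when ln(HL+1)/48 = ln2/72, i.e. HL = 2^(2/3) - 1
        thr = silac.censoring_threshold(TurnoverConfig())
        assert thr == pytest.approx(2 ** (2 / 3) - 1, rel=1e-12)
        assert thr == pytest.approx(0.58740, abs=5e-6)
        assert silac.turnover_estimate(thr).censored
        assert not silac.turnover_estimate(thr * 1.0001).censored

    def test_no_light_signal_censors_below_detection(self):
        est = silac.turnover_estimate(math.inf)
        assert est.censored and "below detection" in est.censor_reason

    @pytest.mark.parametrize("bad", [-0.5, math.nan])
    def test_invalid_hl_raises(self, bad):
        with pytest.raises(ValueError):
            silac.turnover_estimate(bad)

    def test_t_half_strictly_decreasing_in_hl(self):
        thr = silac.censoring_threshold(TurnoverConfig())
        grid = np.linspace(thr * 1.001, 20.0, 200)
        t = [silac.turnover_estimate(h).t_half_h for h in grid]
        assert np.all(np.diff(t) < 0)


class TestImpliedLightFraction:
    def test_inverse_of_144h(self):
        f, hl = silac.implied_light_fraction(144.0)
        assert f == pytest.approx(0.5, rel=1e-12)
        assert hl == pytest.approx(1.0, rel=1e-9)

    def test_reported_collagen_half_life_gives_39_percent_light(self):
        # 69.8 h half-life implies ~39.1% light peptides at 48 h pulse,
        # 72 h doubling — inside the observed 39-43% light range
        f, _ = silac.implied_light_fraction(69.8)
        assert f == pytest.approx(0.3911, abs=5e-4)
        assert 0.39 <= f <= 0.43

    def test_infinite_half_life_approaches_dilution_only_limit(self):
        f, _ = silac.implied_light_fraction(1e12)
        assert f == pytest.approx(2 ** (-48 / 72), rel=1e-6)
        assert f == pytest.approx(0.6300, abs=1e-4)

    def test_nonpositive_half_life_raises(self):
        with pytest.raises(ValueError):
            silac.implied_light_fraction(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=1e4))
    def test_round_trips_with_turnover_estimate(self, t_half):
        f, hl = silac.implied_light_fraction(t_half)
        est = silac.turnover_estimate(hl)
        assert not est.censored
        assert est.t_half_h == pytest.approx(t_half, rel=1e-12)


class TestHLRatio:
    def test_intensity_sum(self):
        recs = make_table(
            [("P", "A", "heavy", 2, 1), ("P", "B", "heavy", 4, 1),
             ("P", "A", "light", 2, 1), ("P", "B", "light", 1, 1)]
        )
        assert silac.protein_hl_ratio(recs, "intensity-sum") == pytest.approx(2.0)

    def test_symmetric_channels_give_unity_either_method(self):
        recs = make_table(
            [("P", "A", "heavy", 3, 1), ("P", "A", "light", 3, 1),
             ("P", "B", "heavy", 7, 1), ("P", "B", "light", 7, 1)]
        )
        for method in ("intensity-sum", "peptide-median"):
            assert silac.protein_hl_ratio(recs, method) == pytest.approx(1.0)

    def test_median_vs_sum_aggregation(self):
        # heavy/light pairs 1/2, 2/2, 9/3: median of ratios {0.5, 1, 3} is 1,
        # ratio of sums is 12/7
        recs = make_table(
            [("P", "A", "heavy", 1, 1), ("P", "A", "light", 2, 1),
             ("P", "B", "heavy", 2, 1), ("P", "B", "light", 2, 1),
             ("P", "C", "heavy", 9, 1), ("P", "C", "light", 3, 1)]
        )
        assert silac.protein_hl_ratio(recs, "peptide-median") == pytest.approx(1.0)
        assert silac.protein_hl_ratio(recs, "intensity-sum") == pytest.approx(12 / 7)

    def test_zero_light_flags_not_raises(self):
        recs = make_table([("P", "A", "heavy", 5, 1), ("P", "A", "light", 0, 1)])
        assert math.isinf(silac.protein_hl_ratio(recs, "intensity-sum"))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        recs = make_table(
            [("P", "A", "heavy", 2.0, 1), ("P", "B", "heavy", 4.0, 1),
             ("P", "A", "light", 2.0, 1), ("P", "B", "light", 1.0, 1)]
        )
        scaled = recs.assign(intensity=recs.intensity * scale)
        assert silac.protein_hl_ratio(scaled, "intensity-sum") == pytest.approx(
            silac.protein_hl_ratio(recs, "intensity-sum"), rel=1e-12
        )


class TestFilter:
    def test_minimal_passing_protein(self):
        # 3 observations pooled over 2 replicates, 1 heavy: retained
        table = make_table(
            [("P", "A", "heavy", 1, 1), ("P", "B", "light", 1, 1),
             ("P", "C", "light", 1, 2)]
        )
        retained, report = silac.filter_proteins(table)
        assert set(retained.protein_id) == {"P"}
        assert report.empty

    @pytest.mark.parametrize(
        "rows, reason_word",
        [
            # only 2 peptide observations
            ([("P", "A", "heavy", 1, 1), ("P", "B", "light", 1, 2)], "peptides"),
            # 5 light-only observations in 2 replicates
            ([("P", c, "light", 1, r) for c, r in
              zip("ABCDE", (1, 1, 1, 2, 2))], "heavy"),
            # one replicate only
            ([("P", "A", "heavy", 1, 1), ("P", "B", "light", 1, 1),
              ("P", "C", "light", 1, 1)], "replicates"),
        ],
    )
    def test_rejection_reasons(self, rows, reason_word):
        retained, report = silac.filter_proteins(make_table(rows))
        assert retained.empty
        assert reason_word in report.reason.iloc[0]

    def test_empty_table(self):
        retained, report = silac.filter_proteins(make_table([]))
        assert retained.empty and report.empty


class TestRunTurnover:
    def test_noise_free_round_trip(self, silac_noisefree):
        table, truth = silac_noisefree
        est, summary = silac.run_turnover(table)
        merged = est.merge(truth, on="protein_id")
        ok = merged[~merged.censored.astype(bool)]
        rel = np.abs(ok.t_half_h - ok.t_half_true_h) / ok.t_half_true_h
        assert len(ok) > 0
        assert rel.max() < 1e-9

    def test_noisy_recovery_bias(self):
        from fibrilkit import simulate

        cfg = simulate.SilacSimConfig(
            n_proteins=200, peptides_per_protein_mean=8,
            intensity_cv=0.2, n_replicates=2, seed=1,
        )
        table, truth = simulate.gen_silac_table(cfg)
        est, _ = silac.run_turnover(table)
        merged = est.merge(truth, on="protein_id")
        ok = merged[~merged.censored.astype(bool)].dropna(subset=["t_half_h"])
        rel = np.abs(ok.t_half_h - ok.t_half_true_h) / ok.t_half_true_h
        assert rel.median() < 0.05

    def test_all_filtered_gives_empty_estimates(self):
        table = make_table([("P", "A", "light", 1, 1)])
        est, summary = silac.run_turnover(table)
        assert est.empty
        assert summary["n_retained"] == 0

    def test_protein_scale_invariance_end_to_end(self, silac_noisefree):
        table, _ = silac_noisefree
        est1, _ = silac.run_turnover(table)
        scaled = table.assign(intensity=table.intensity * 37.0)
        est2, _ = silac.run_turnover(scaled)
        pd.testing.assert_series_equal(est1.t_half_h, est2.t_half_h, rtol=1e-12)
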