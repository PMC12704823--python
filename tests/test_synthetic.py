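"""Generator tests: moments, determinism, and the analytic effect oracle."""

import numpy as np
import pandas as pd
import pytest

from timecoda import (
    GENERATOR_BASIS,
    CohortSimConfig,
    MinuteSimConfig,
    closure,
    geometric_mean_composition,
    ilr,
    reallocate,
    simulate_cohort,
    simulate_minute_stream,
    true_reallocation_effect,
)
from timecoda.coda import InfeasibleReallocationError
from timecoda.epochs import process_epochs
from timecoda.regression import PART_COLUMNS
from conftest import direct_pivot_ilr


class TestCohortSimulation:
    def test_seed_determinism(self):
        a = simulate_cohort(CohortSimConfig(n_participants=60, seed=5))
        b = simulate_cohort(CohortSimConfig(n_participants=60, seed=5))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_cohort(CohortSimConfig(n_participants=60, seed=6))
        assert not a["twl_pct"].equals(c["twl_pct"])

    def test_degenerate_noise_collapses_to_mean_composition(self):
        cfg = CohortSimConfig(n_participants=30, seed=1,
                              ilr_covariance=np.zeros((3, 3)), sigma_eps=0.0)
        coh = simulate_cohort(cfg)
        expected = closure(cfg.mean_minutes)
        comps = coh[PART_COLUMNS].to_numpy()
        assert np.abs(comps - expected).max() < 1e-9
        # outcome varies only through the surgery term
        twl = coh.groupby("surgery")["twl_pct"].agg(["min", "max"])
        assert np.allclose(twl["min"], twl["max"], atol=1e-12)
        assert np.isclose(
            twl.loc["RYGB", "min"] - twl.loc["SG", "min"],
            cfg.surgery_effect)

    def test_compositions_close_to_1440_and_positive(self, default_cohort):
        comps = default_cohort[PART_COLUMNS].to_numpy()
        assert np.all(comps > 0)
        assert np.abs(comps.sum(axis=1) - 1440.0).max() < 1e-9

    def test_large_n_geometric_mean_matches_configured_means(self):
        cfg = CohortSimConfig(n_participants=10_000, seed=3)
        coh = simulate_cohort(cfg)
        gm = geometric_mean_composition(coh[PART_COLUMNS].to_numpy())
        target = closure(cfg.mean_minutes)
        # log-scale SEs are at most ~0.0054 at n=10k; allow 3x on minutes
        assert np.abs(np.log(gm) - np.log(target)).max() < 3 * 0.0054

    def test_large_n_outcome_moments(self):
        cfg = CohortSimConfig(n_participants=10_000, seed=4,
                              beta_ilr=np.zeros(3), surgery_effect=0.0)
        coh = simulate_cohort(cfg)
        se_mean = 5.1 / np.sqrt(10_000)
        assert abs(coh["twl_pct"].mean() - 23.8) < 3 * se_mean
        assert abs(coh["twl_pct"].std(ddof=1) - 5.1) < 0.15

    def test_large_n_ilr_covariance_converges(self):
        cfg = CohortSimConfig(n_participants=10_000, seed=9)
        coh = simulate_cohort(cfg)
        z = ilr(coh[PART_COLUMNS].to_numpy(), GENERATOR_BASIS)
        emp = np.cov(z, rowvar=False)
        S = cfg.ilr_covariance
        # element-wise SE of a covariance at n=10k is ~sqrt(2) var / 100
        tol = 3 * 1.5 * np.sqrt(np.outer(np.diag(S), np.diag(S))) / 100.0
        assert np.all(np.abs(emp - S) < tol + 1e-6)

    def test_rygb_proportion(self):
        coh = simulate_cohort(CohortSimConfig(n_participants=10_000, seed=2))
        p = (coh["surgery"] == "RYGB").mean()
        assert abs(p - 0.20) < 3 * np.sqrt(0.2 * 0.8 / 10_000)

    @pytest.mark.parametrize("kwargs", [
        {"ilr_covariance": -np.eye(3)},
        {"ilr_covariance": np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]])},
        {"sigma_eps": -1.0},
        {"p_rygb": 1.5},
        {"mean_minutes": [400, -1, 300, 40]},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortSimConfig(**kwargs)


class TestTrueReallocationEffect:
    def test_zero_delta_is_zero_for_every_pair(self):
        cfg = CohortSimConfig()
        for frm in ("sleep", "sb", "lpa", "mvpa"):
            for to in ("sleep", "sb", "lpa", "mvpa"):
                if frm == to:
                    continue
                assert true_reallocation_effect(cfg, frm, to, 0.0) == 0.0

    def test_zero_beta_is_zero_everywhere(self):
        cfg = CohortSimConfig(beta_ilr=np.zeros(3))
        for delta in (-30, 15, 60):
            assert true_reallocation_effect(cfg, "sb", "mvpa", delta) == 0.0

    def test_matches_brute_force_recomputation(self):
        # independent route: finite reallocation + direct pivot log-ratio
        # formula, never touching the package's contrast matrices
        cfg = CohortSimConfig(seed=0)
        ref = 1440.0 * cfg.mean_minutes / cfg.mean_minutes.sum()
        new = ref.copy()
        new[1] -= 15.0
        new[3] += 15.0
        d = direct_pivot_ilr(new, 0) - direct_pivot_ilr(ref, 0)
        expected = float(d @ cfg.beta_ilr)
        got = true_reallocation_effect(cfg, "sb", "mvpa", 15.0)
        assert np.isclose(got, expected, atol=1e-12)

    def test_infeasible_delta_raises(self):
        cfg = CohortSimConfig()
        with pytest.raises(InfeasibleReallocationError):
            true_reallocation_effect(cfg, "mvpa", "sb", 45.0)


class TestMinuteStream:
    def test_sleep_window_across_midnight_gives_480_minutes(self):
        cfg = MinuteSimConfig(sleep_onset=23 * 60, sleep_offset=7 * 60,
                              n_days=3, seed=0)
        stream = simulate_minute_stream(cfg)
        per_day = stream.groupby(stream["timestamp"].dt.date)["sleep"].sum()
        assert (per_day == 480).all()
        assert len(stream) == 3 * 1440

    def test_determinism(self):
        cfg = MinuteSimConfig(n_days=2, seed=42)
        pd.testing.assert_frame_equal(simulate_minute_stream(cfg),
                                      simulate_minute_stream(cfg))

    def test_roundtrip_through_epoch_processing(self):
        # tight count distributions keep essentially all mass in-band, so
        # per-day behavior minutes follow the configured window/multinomial
        cfg = MinuteSimConfig(
            n_days=6, seed=7, nonwear_gap_rate=0.0,
            count_distributions={"sleep": (30.0, 0.5), "sb": (500.0, 0.3),
                                 "lpa": (3800.0, 0.15),
                                 "mvpa": (11000.0, 0.1)})
        stream = simulate_minute_stream(cfg)
        participants, exclusions = process_epochs(stream)
        assert exclusions == []
        assert len(participants) == 1
        row = participants.iloc[0]
        assert row["n_valid_days"] == 6
        wake = 1440 - cfg.sleep_minutes_per_day
        expect = np.array([cfg.sleep_minutes_per_day,
                           *(wake * cfg.wake_probs)])
        got = row[PART_COLUMNS].to_numpy(dtype=float)
        # multinomial SD per behavior per day < ~16 min; mean of 6 days
        sd = np.sqrt(wake * cfg.wake_probs * (1 - cfg.wake_probs) / 6)
        tol = np.maximum(5 * np.concatenate([[0.001], sd]), 1.0)
        assert np.all(np.abs(got - expect) < tol)

    def test_heavy_nonwear_fails_validity_filter(self):
        cfg = MinuteSimConfig(n_days=10, seed=1, nonwear_gap_rate=9.0)
        stream = simulate_minute_stream(cfg)
        participants, exclusions = process_epochs(stream)
        # expected wear is 15 h/day (< 16), so the participant is excluded
        assert participants.empty
        assert len(exclusions) == 1 and "excluded" in exclusions[0]

    def test_degenerate_sleep_window_rejected(self):
        with pytest.raises(ValueError):
            MinuteSimConfig(sleep_onset=600, sleep_offset=600)

    def test_out_of_band_count_distribution_rejected(self):
        with pytest.raises(ValueError):
            MinuteSimConfig(count_distributions={
                "sleep": (30.0, 1.0), "sb": (1500.0, 1.5),
                "lpa": (3800.0, 0.28), "mvpa": (11000.0, 0.2)})
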