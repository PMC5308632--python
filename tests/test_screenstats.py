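"""Robust-Z normalization, Z'-factor, hit calling and control error rates."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emtscreen import screenstats, synthgen


def _plate(values, plate_id="P001", role="sample", gfp=200):
    n = len(values)
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "well": [f"A{i:02d}" for i in range(n)],
            "role": role,
            "orf_id": [f"O{i}" for i in range(n)],
            "gfp_pos_count": gfp,
            "cell_count": gfp * 3,
            "vim_a_well_mean": values,
            "vim_r_well_mean": values,
            "pct_vim_pos_a": 1.0,
            "pct_vim_pos_r": 1.0,
        }
    )


class TestPlateStats:
    def test_median_and_scaled_mad_against_definition(self):
        # brute force from the MAD definition: median 3.5, MAD 1.5
        wells = _plate([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
        stats = screenstats.plate_stats(wells)
        assert stats.loc["P001", "vim_a_median"] == pytest.approx(3.5)
        assert stats.loc["P001", "vim_a_scaled_mad"] == pytest.approx(1.4826 * 1.5)

    def test_constant_plate_flagged_degenerate(self):
        stats = screenstats.plate_stats(_plate([5.0] * 8))
        assert bool(stats.loc["P001", "degenerate"])

    def test_control_wells_never_influence_plate_stats(self):
        wells = _plate([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
        controls = _plate([9e9] * 4, role="vector")
        controls["well"] = [f"H{i:02d}" for i in range(4)]
        both = pd.concat([wells, controls], ignore_index=True)
        a = screenstats.plate_stats(wells)
        b = screenstats.plate_stats(both)
        pd.testing.assert_frame_equal(a, b)

    def test_low_gfp_wells_excluded_from_stats(self):
        wells = _plate([1.0, 2.0, 3.0, 4.0, 5.0, 100.0])
        extra = _plate([1e6, 1e6], gfp=100)  # exactly 100 is not "more than 100"
        extra["well"] = ["G01", "G02"]
        stats = screenstats.plate_stats(pd.concat([wells, extra], ignore_index=True))
        assert stats.loc["P001", "vim_a_median"] == pytest.approx(3.5)

    def test_plate_without_eligible_wells_flagged(self):
        stats = screenstats.plate_stats(_plate([1.0, 2.0, 3.0], gfp=10))
        assert bool(stats.loc["P001", "degenerate"])
        assert stats.loc["P001", "n_eligible_wells"] == 0


class TestRobustZ:
    def test_value_at_median_scores_zero(self):
        assert screenstats.robust_z(3.5, 3.5, 2.2239) == pytest.approx(0.0)

    def test_oracle_arithmetic(self):
        # stats from the brute-force example above
        z = screenstats.robust_z(100.0, 3.5, 1.4826 * 1.5)
        assert z == pytest.approx((100.0 - 3.5) / 2.2239, rel=1e-4)

    def test_degenerate_scale_gives_nan(self):
        assert np.isnan(screenstats.robust_z(1.0, 0.0, 0.0))

    def test_plate_z_centred_and_unit_scale(self, desk_screen):
        wells, _ = desk_screen
        stats = screenstats.plate_stats(wells)
        scored = screenstats.add_z_scores(wells, stats)
        thr = screenstats.ScreenThresholds()
        for _, sub in scored.groupby("plate_id"):
            elig = sub[(sub.role == "sample") & (sub.gfp_pos_count > thr.min_gfp_cells_platestat)]
            assert abs(elig["z_a"].median()) < 1e-9
            assert 0.9 < screenstats.scaled_mad(elig["z_a"]) < 1.1

    def test_affine_invariance(self, small_screen):
        wells, _ = small_screen
        scored = screenstats.add_z_scores(wells, screenstats.plate_stats(wells))
        rescaled = wells.copy()
        for ch in ("vim_a", "vim_r"):
            rescaled[f"{ch}_well_mean"] = 3.7 * rescaled[f"{ch}_well_mean"] + 1234.5
        scored2 = screenstats.add_z_scores(rescaled, screenstats.plate_stats(rescaled))
        np.testing.assert_allclose(scored["z_a"], scored2["z_a"], atol=1e-9)
        np.testing.assert_allclose(scored["z_r"], scored2["z_r"], atol=1e-9)


class TestZPrime:
    def test_closed_form(self):
        assert screenstats.zprime_from_stats(10.0, 1.0, 0.0, 1.0) == pytest.approx(0.4)

    def test_zero_sd_perfect_assay(self):
        assert screenstats.zprime_from_stats(10.0, 0.0, 0.0, 0.0) == 1.0

    def test_equal_means_flagged_with_sentinel(self):
        assert screenstats.zprime_from_stats(5.0, 1.0, 5.0, 2.0) == float("-inf")

    def test_from_values_uses_sample_stats(self, rng):
        pos = rng.normal(10.0, 1.0, 500)
        neg = rng.normal(0.0, 1.0, 500)
        zp = screenstats.zprime(pos, neg)
        expected = screenstats.zprime_from_stats(pos.mean(), pos.std(ddof=1), neg.mean(), neg.std(ddof=1))
        assert zp == pytest.approx(expected)
        assert 0.2 < zp < 0.6

    def test_affine_invariance_and_sign_symmetry(self, rng):
        pos = rng.normal(8.0, 1.5, 40)
        neg = rng.normal(1.0, 0.5, 40)
        base = screenstats.zprime(pos, neg)
        assert screenstats.zprime(2.0 * pos + 7.0, 2.0 * neg + 7.0) == pytest.approx(base)
        assert screenstats.zprime(-pos, -neg) == pytest.approx(base)
        assert screenstats.zprime(neg, pos) == pytest.approx(base)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            screenstats.zprime([1.0], [0.0, 0.1])


def _hit_row(z_a=0.0, z_r=0.0, raw_a=100.0, raw_r=100.0, pct=1.0, gfp=200, role="sample"):
    return {
        "plate_id": "P001", "well": "A01", "role": role, "orf_id": "O1",
        "gfp_pos_count": gfp, "cell_count": 3 * gfp,
        "vim_a_well_mean": raw_a, "vim_r_well_mean": raw_r,
        "pct_vim_pos_a": pct, "pct_vim_pos_r": pct,
        "z_a": z_a, "z_r": z_r,
    }


class TestCallHits:
    def test_z_antibody_hit(self):
        calls = screenstats.call_hits(pd.DataFrame([_hit_row(z_a=16.0, gfp=60)]))
        assert bool(calls.hit.iloc[0]) and bool(calls.za_hit.iloc[0])

    def test_threshold_boundary_is_strict(self):
        calls = screenstats.call_hits(pd.DataFrame([_hit_row(z_a=15.0)]))
        assert not bool(calls.hit.iloc[0])

    def test_eligibility_floor_at_50_gfp_cells(self):
        calls = screenstats.call_hits(pd.DataFrame([_hit_row(z_a=50.0, gfp=49)]))
        assert not bool(calls.hit.iloc[0]) and not bool(calls.eligible.iloc[0])

    def test_raw_intensity_hit(self):
        calls = screenstats.call_hits(pd.DataFrame([_hit_row(raw_a=8001.0)]))
        assert bool(calls.hit.iloc[0]) and bool(calls.raw_hit.iloc[0])

    def test_nan_scores_never_fire(self):
        calls = screenstats.call_hits(pd.DataFrame([_hit_row(z_a=np.nan, z_r=np.nan)]))
        assert not bool(calls.hit.iloc[0])

    def test_truth_table_over_all_threshold_corners(self):
        """All 2^6 combinations of each criterion input crossing its boundary
        reproduce the disjunctive hit rule with strict inequalities."""
        lo_hi = {
            "z_a": (15.0, 15.1), "z_r": (15.0, 15.1),
            "raw_a": (8000.0, 8000.1), "raw_r": (8000.0, 8000.1),
            "pct": (18.0, 18.1), "gfp": (49, 50),
        }
        rows, expected = [], []
        for bits in itertools.product([0, 1], repeat=6):
            za, zr, ra, rr, pc, gf = (lo_hi[k][b] for k, b in zip(lo_hi, bits))
            rows.append(_hit_row(z_a=za, z_r=zr, raw_a=ra, raw_r=rr, pct=pc, gfp=gf))
            eligible = gf >= 50
            expected.append(eligible and (za > 15 or zr > 15 or ra > 8000 or rr > 8000 or pc > 18))
        calls = screenstats.call_hits(pd.DataFrame(rows))
        assert calls["hit"].tolist() == expected

    def test_monotone_in_each_score(self, rng):
        base = _hit_row(z_a=14.0, z_r=10.0, raw_a=7000.0, raw_r=500.0, pct=17.0)
        base_hit = bool(screenstats.call_hits(pd.DataFrame([base])).hit.iloc[0])
        assert not base_hit
        for key in ("z_a", "z_r", "vim_a_well_mean", "vim_r_well_mean", "pct_vim_pos_a"):
            for bump in (1.0, 100.0, 10000.0):
                row = dict(base)
                row[key] = row[key] + bump
                bumped = bool(screenstats.call_hits(pd.DataFrame([row])).hit.iloc[0])
                assert bumped >= base_hit


class TestControlErrorRates:
    def _control_table(self, n_vec, n_vec_hit, n_pos, n_pos_miss):
        rows = []
        for i in range(n_vec):
            rows.append({**_hit_row(role="vector"), "hit": i < n_vec_hit, "eligible": True})
        for i in range(n_pos):
            rows.append({**_hit_row(role="positive"), "hit": i >= n_pos_miss, "eligible": True})
        return pd.DataFrame(rows)

    def test_printed_screen_worked_example(self):
        q = screenstats.control_error_rates(self._control_table(814, 38, 411, 19))
        assert q.fdr_estimate == pytest.approx(38 / 814)
        assert q.fnr_estimate == pytest.approx(19 / 411)

    def test_zero_flagged_gives_zero(self):
        q = screenstats.control_error_rates(self._control_table(100, 0, 10, 0))
        assert q.fdr_estimate == 0.0 and q.fnr_estimate == 0.0

    def test_matches_bruteforce_count_on_random_tables(self, rng):
        for _ in range(5):
            tab = self._control_table(
                int(rng.integers(5, 60)), 0, int(rng.integers(2, 20)), 0
            )
            tab["hit"] = rng.random(len(tab)) < 0.3
            q = screenstats.control_error_rates(tab)
            vec = tab[tab.role == "vector"]
            pos = tab[tab.role == "positive"]
            assert q.n_neg_flagged == int(sum(bool(h) for h in vec.hit))
            assert q.fdr_estimate == q.n_neg_flagged / len(vec)
            assert q.n_pos_missed == int(sum(not bool(h) for h in pos.hit))

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            screenstats.control_error_rates(self._control_table(0, 0, 5, 0))

    def test_null_screen_flag_rate_matches_generative_tail(self):
        """On a null screen the vector flag rate must match the model's own
        tail mass within binomial error."""
        wells, model = synthgen.simulate_screen(n_plates=20, n_hits=0, seed=31)
        hits, _, quality = screenstats.run_primary_screen(wells)
        p0 = synthgen.null_flag_probability(model, screenstats.ScreenThresholds(), n_mc=100_000, seed=32)
        test = sps.binomtest(quality.n_neg_flagged, quality.n_neg_total, p0)
        assert test.pvalue > 0.01


class TestQcCorrelations:
    def test_independent_scores_show_no_correlation(self, desk_screen):
        wells, _ = desk_screen
        scored = screenstats.add_z_scores(wells, screenstats.plate_stats(wells))
        rep = screenstats.qc_correlations(scored, n_perm=199, seed=0)
        assert (rep["spearman_r"].abs() < 0.1).all()

    def test_constructed_dependence_recovered(self, rng):
        n = 200
        wells = pd.DataFrame(
            {
                "z_a": np.arange(n, dtype=float),
                "z_r": rng.normal(size=n),
                "cell_count": np.arange(n, dtype=float),
                "gfp_pos_count": rng.integers(50, 500, n),
            }
        )
        rep = screenstats.qc_correlations(wells, n_perm=199, seed=1)
        r = rep[(rep.score == "z_a") & (rep["count"] == "cell_count")]["spearman_r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        wells = pd.DataFrame(
            {"z_a": 1.0, "z_r": 1.0, "cell_count": np.arange(20), "gfp_pos_count": np.arange(20)}
        )
        rep = screenstats.qc_correlations(wells, n_perm=99, seed=2)
        assert rep["constant"].all()


class TestPlantedHitRecovery:
    def test_sensitivity_and_false_positive_consistency(self, desk_screen):
        """Default 8-plate fixture, 16 hits planted at 20 null-SD units in the
        antibody channel: every planted hit is recovered and the vector flag
        rate stays consistent with the configured null tail."""
        wells, model = desk_screen
        hits, _, quality = screenstats.run_primary_screen(wells)
        sens = hits.loc[wells["true_hit"], "hit"].mean()
        assert sens >= 0.95
        p0 = synthgen.null_flag_probability(model, screenstats.ScreenThresholds(), n_mc=100_000, seed=99)
        assert sps.binomtest(quality.n_neg_flagged, quality.n_neg_total, p0).pvalue > 0.01
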