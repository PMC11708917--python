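"""Lorenz/Gini inequality, hotspot/coldspot calling, element profiles."""

import numpy as np
import pandas as pd
import pytest

from recland.core_io import ValidationError
from recland.hotspots import (
    call_global,
    call_local,
    element_profile,
    gini_oracle,
    lorenz_gini,
    rrr80,
)


def _windows(rates, lg="lg1", size=10_000):
    rates = np.asarray(rates, dtype=float)
    starts = np.arange(len(rates)) * size
    return pd.DataFrame(
        {
            "lg": lg,
            "start": starts,
            "end": starts + size,
            "cm": rates * size / 1e6,
            "cm_per_mb": rates,
            "complete": True,
        }
    )


class TestLorenzGini:
    def test_equal_windows_gini_zero(self):
        res = lorenz_gini(_windows([2.0] * 10))
        assert res.per_lg["gini"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_window_holds_all_mass(self):
        res = lorenz_gini(_windows([0] * 9 + [7.0]))
        assert res.per_lg["gini"].iloc[0] == pytest.approx(0.9, abs=1e-12)

    def test_matches_mean_absolute_difference_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(2, 200)
            v = rng.gamma(0.7, 2.0, n)
            res = lorenz_gini(_windows(v))
            assert res.per_lg["gini"].iloc[0] == pytest.approx(
                gini_oracle(v), abs=1e-9
            )

    def test_scale_invariance(self, rng):
        v = rng.gamma(1.0, 1.0, 50)
        g1 = lorenz_gini(_windows(v)).per_lg["gini"].iloc[0]
        g2 = lorenz_gini(_windows(v * 7.3)).per_lg["gini"].iloc[0]
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_pigou_dalton_transfer_increases_gini(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        g_before = lorenz_gini(_windows(v)).per_lg["gini"].iloc[0]
        v2 = np.array([0.5, 2.0, 3.0, 4.5])  # low -> high transfer
        g_after = lorenz_gini(_windows(v2)).per_lg["gini"].iloc[0]
        assert g_after > g_before

    def test_all_zero_lg_flagged(self):
        res = lorenz_gini(_windows([0.0] * 5))
        assert np.isnan(res.per_lg["gini"].iloc[0])

    def test_uniform_small_lg_less_unequal_than_concentrated_large(self, rng):
        small = _windows([3.0] * 50, lg="small")
        big = _windows(np.concatenate([rng.gamma(0.3, 5.0, 500)]), lg="big")
        both = pd.concat([small, big], ignore_index=True)
        res = lorenz_gini(both).per_lg.set_index("lg")["gini"]
        assert res["small"] < res["big"]

    def test_seq_frac_80(self):
        # one of ten windows holds everything: 80% of cM in 10% of sequence
        res = lorenz_gini(_windows([0] * 9 + [7.0]))
        assert res.per_lg["seq_frac_80"].iloc[0] == pytest.approx(0.08, abs=1e-9)


class TestCallGlobal:
    def test_threshold_boundaries(self):
        w = _windows([10.1, 0.39, 10.0, 20.0])
        out = call_global(w, genome_mean_rate=2.0)
        # exactly 5x the mean (10.0) is NOT a hotspot: "more than" is strict
        assert list(out["is_hotspot"]) == [True, False, False, True]
        assert list(out["is_coldspot"]) == [False, True, False, False]
        # exactly 10x the mean (20.0) IS a global hotspot: "at least" is inclusive
        assert list(out["is_global_hotspot"]) == [False, False, False, True]

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            call_global(_windows([1.0]), genome_mean_rate=0.0)


class TestRrr80:
    def test_flat_track_is_one(self):
        w = _windows([2.0] * 200, size=1_000)
        out = rrr80(w)
        defined = out[out["rrr80_defined"]]
        assert len(defined) > 0
        np.testing.assert_allclose(defined["rrr80"], 1.0, atol=1e-12)

    def test_focal_over_unit_flank(self):
        v = np.ones(81)
        v[40] = 6.0
        out = rrr80(_windows(v, size=1_000))
        assert out["rrr80"].iloc[40] == pytest.approx(6.0)

    def test_half_flank_rule_at_lg_start(self):
        v = np.ones(200)
        out = rrr80(_windows(v, size=1_000))
        # position 0 has exactly 40 downstream flank windows -> defined
        assert out["rrr80_defined"].iloc[0]
        # but a 39-window lg end: undefined beyond reach
        short = rrr80(_windows(np.ones(30), size=1_000))
        assert not short["rrr80_defined"].any()

    def test_zero_flank_undefined(self):
        v = np.zeros(100)
        v[50] = 5.0
        out = rrr80(_windows(v, size=1_000))
        # flank of window 95 (55..99, focal excluded) is all zero
        assert not out["rrr80_defined"].iloc[95]


class TestCallLocal:
    def _annotated(self, v, repeat_bp=None):
        w = _windows(v, size=1_000)
        w["repeat_bp"] = 0 if repeat_bp is None else repeat_bp
        return rrr80(w)

    def test_pair_of_elevated_windows_called(self):
        v = np.ones(200)
        v[100:102] = 6.0
        calls, runs = call_local(self._annotated(v))
        assert len(runs) == 1
        assert runs["n_windows"].iloc[0] == 2
        assert runs["start"].iloc[0] == 100_000 and runs["end"].iloc[0] == 102_000

    def test_isolated_window_not_called(self):
        v = np.ones(200)
        v[100] = 6.0
        calls, runs = call_local(self._annotated(v))
        assert len(runs) == 0

    def test_repeat_filter_breaks_run(self):
        v = np.ones(200)
        v[100:102] = 6.0
        rep = np.zeros(200, dtype=int)
        rep[101] = 600
        calls, runs = call_local(self._annotated(v, repeat_bp=rep))
        assert len(runs) == 0

    def test_rate_band_filter(self):
        v = np.ones(200) * 2.0
        v[100:102] = 24.0  # RRR80 ~ 12 but rate > 10 cM/Mb: excluded
        calls, runs = call_local(self._annotated(v))
        assert len(runs) == 0


class TestElementProfile:
    def test_flat_track_profile_is_one(self):
        w = _windows(np.ones(300), size=1_000)
        flag = pd.Series(False, index=w.index)
        flag.iloc[150] = True
        prof = element_profile(w, flag)
        assert np.allclose(prof["mean_rel_rate"], 1.0, atol=1e-12)
        assert prof["offset_bp"].min() == -40_000 and prof["offset_bp"].max() == 40_000

    def test_peak_at_element(self):
        v = np.ones(300)
        v[150] = 8.0
        w = _windows(v, size=1_000)
        flag = pd.Series(False, index=w.index)
        flag.iloc[150] = True
        prof = element_profile(w, flag).set_index("offset_bp")["mean_rel_rate"]
        assert prof[0] > 2 * prof[20_000]

    def test_no_elements_rejected(self):
        w = _windows(np.ones(100), size=1_000)
        with pytest.raises(ValidationError):
            element_profile(w, pd.Series(False, index=w.index))
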