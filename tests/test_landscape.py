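"""Windowed maps from rate tracks, linkage scaling, covariates, regression."""

import numpy as np
import pandas as pd
import pytest

from recland.core_io import GenomeLayout, IntervalSet, RateTrack, ValidationError
from recland.landscape import (
    genome_mean_rate,
    length_regression,
    scale_to_linkage,
    track_cm_per_lg,
    window_covariates,
    windows_from_track,
)

COLS = ["lg", "start", "end", "value"]


def _track(rows, layout=None):
    return RateTrack(pd.DataFrame(rows, columns=COLS), layout)


class TestWindows:
    def test_closed_form_single_window(self):
        layout = GenomeLayout([("lg1", 10_000)])
        t = _track([("lg1", 0, 10_000, 1e-8)])
        w = windows_from_track(t, layout, 10_000)
        p = 1e-8 * 10_000
        exp_cm = -50 * np.log(1 - 2 * p)
        assert w["cm"].iloc[0] == pytest.approx(exp_cm, rel=1e-12)
        assert w["cm"].iloc[0] == pytest.approx(0.0100010, abs=1e-7)
        assert w["cm_per_mb"].iloc[0] == pytest.approx(1.00010, abs=1e-5)

    def test_zero_rate_zero_windows(self, small_layout):
        t = _track([("lg1", 0, 2_000_000, 0.0)])
        w = windows_from_track(t, small_layout, 10_000)
        assert (w["cm"] == 0).all()

    def test_pro_rata_split_across_windows(self):
        layout = GenomeLayout([("lg1", 20_000)])
        t = _track([("lg1", 5_000, 15_000, 2e-8)])
        w = windows_from_track(t, layout, 10_000)
        assert w["cm"].iloc[0] == pytest.approx(w["cm"].iloc[1], abs=1e-9)

    def test_pathological_rate_rejected(self):
        layout = GenomeLayout([("lg1", 10_000)])
        t = _track([("lg1", 0, 10_000, 1e-4)])  # p = 1 per window
        with pytest.raises(ValidationError, match="pathological"):
            windows_from_track(t, layout, 10_000)

    def test_aggregation_consistency_across_scales(self, rng):
        # Haldane applied per track piece -> 1 Mb window cm == sum of 1 kb cms
        layout = GenomeLayout([("lg1", 3_000_000)])
        starts = np.arange(0, 3_000_000, 7_000)
        ends = np.minimum(starts + 7_000, 3_000_000)
        t = _track(
            list(zip(["lg1"] * len(starts), starts, ends, rng.uniform(0, 5e-8, len(starts))))
        )
        w1k = windows_from_track(t, layout, 1_000)
        w1m = windows_from_track(t, layout, 1_000_000)
        agg = w1k.groupby(w1k["start"] // 1_000_000)["cm"].sum()
        np.testing.assert_allclose(w1m["cm"].to_numpy(), agg.to_numpy(), atol=1e-6)
        # genome total invariant under window size
        assert w1k["cm"].sum() == pytest.approx(w1m["cm"].sum(), abs=1e-6)

    def test_trailing_partial_window_normalized(self):
        layout = GenomeLayout([("lg1", 15_000)])
        t = _track([("lg1", 0, 15_000, 1e-8)])
        w = windows_from_track(t, layout, 10_000)
        assert not w["complete"].iloc[-1]
        assert w["cm_per_mb"].iloc[-1] == pytest.approx(
            w["cm_per_mb"].iloc[0], rel=1e-4
        )


class TestScaling:
    def test_halved_when_ld_twice_linkage(self, small_layout):
        t = _track([("lg1", 0, 2_000_000, 1e-8), ("lg2", 0, 1_000_000, 1e-8)])
        ld = track_cm_per_lg(t)
        target = {"lg1": ld["lg1"] / 2, "lg2": ld["lg2"]}
        st = scale_to_linkage(t, target)
        assert st.factors["lg1"] == pytest.approx(0.5)
        assert st.factors["lg2"] == pytest.approx(1.0)
        got = track_cm_per_lg(st.track)
        assert got["lg1"] == pytest.approx(target["lg1"], abs=1e-6)
        assert got["lg2"] == pytest.approx(target["lg2"], abs=1e-6)

    def test_window_table_scaling_preserves_totals(self, small_layout, rng):
        starts = np.arange(0, 2_000_000, 10_000)
        t = _track(
            list(
                zip(
                    ["lg1"] * len(starts),
                    starts,
                    starts + 10_000,
                    rng.uniform(0, 3e-8, len(starts)),
                )
            )
        )
        w = windows_from_track(t, GenomeLayout([("lg1", 2_000_000)]), 10_000)
        scaled, factors = scale_to_linkage(w, {"lg1": 37.5})
        assert scaled["cm"].sum() == pytest.approx(37.5, abs=1e-9)

    def test_zero_ld_with_positive_linkage_rejected(self, small_layout):
        t = _track([("lg1", 0, 2_000_000, 0.0)])
        with pytest.raises(ValidationError):
            scale_to_linkage(t, {"lg1": 50.0})


class TestCovariates:
    def _win(self, lg="lg1", n=2, size=1_000):
        starts = np.arange(n) * size
        return pd.DataFrame(
            {
                "lg": lg,
                "start": starts,
                "end": starts + size,
                "cm": 0.0,
                "cm_per_mb": 0.0,
                "complete": True,
            }
        )

    def test_gc_all_gc_sequence(self):
        w = window_covariates(self._win(n=1), seqs={"lg1": "GC" * 500})
        assert w["gc_fraction"].iloc[0] == 1.0

    def test_pi_unbiased_single_snp(self):
        sites = pd.DataFrame({"lg": ["lg1"], "pos_bp": [500], "p": [0.5]})
        w = window_covariates(self._win(n=1), sites=sites, n_diploid=10)
        assert w["pi"].iloc[0] == pytest.approx(0.5 * 20 / 19 / 1000, rel=1e-12)
        assert w["pi"].iloc[0] == pytest.approx(5.263e-4, abs=1e-6)

    def test_pi_mask_correction_doubles(self):
        sites = pd.DataFrame({"lg": ["lg1"], "pos_bp": [100], "p": [0.5]})
        mask = IntervalSet(pd.DataFrame([("lg1", 500, 1000, None)], columns=COLS))
        w = window_covariates(self._win(n=1), sites=sites, n_diploid=10, mask=mask)
        assert w["pi"].iloc[0] == pytest.approx(0.5 * 20 / 19 / 500, rel=1e-12)

    def test_fully_masked_window_pi_undefined(self):
        sites = pd.DataFrame({"lg": ["lg1"], "pos_bp": [100], "p": [0.5]})
        mask = IntervalSet(pd.DataFrame([("lg1", 0, 1000, None)], columns=COLS))
        w = window_covariates(self._win(n=1), sites=sites, n_diploid=10, mask=mask)
        assert np.isnan(w["pi"].iloc[0])
        assert not w["pi_defined"].iloc[0]

    def test_gene_tss_cgi_repeat_flags(self):
        w = self._win(n=3)
        genes = IntervalSet(
            pd.DataFrame([("lg1", 500, 2_500, "g1"), ("lg1", 900, 950, "g2")], columns=COLS)
        )
        tss = IntervalSet(pd.DataFrame([("lg1", 500, 501, "t")], columns=COLS))
        cgi = IntervalSet(pd.DataFrame([("lg1", 900, 2_100, "c")], columns=COLS))
        reps = IntervalSet(pd.DataFrame([("lg1", 2_400, 3_100, "r")], columns=COLS))
        out = window_covariates(w, genes=genes, tss=tss, cgi=cgi, repeats=reps)
        assert list(out["n_genes"]) == [2, 1, 1]
        assert list(out["has_tss"]) == [True, False, False]
        assert list(out["full_cgi"]) == [False, True, False]  # cgi spans [1000,2000)
        assert list(out["repeat_bp"]) == [0, 0, 600]


class TestLengthRegression:
    def test_noiseless_exact_fit(self):
        layout = GenomeLayout([(f"lg{i}", int(mb * 1e6)) for i, mb in enumerate([10, 20, 40, 80], 1)])
        lengths = {g.lg_id: 50 + 0.4 * g.length_bp / 1e6 for g in layout}
        reg = length_regression(lengths, layout)
        assert reg["alpha"] == pytest.approx(50.0, abs=1e-8)
        assert reg["beta"] == pytest.approx(0.4, abs=1e-10)
        assert reg["beta_ci"][1] - reg["beta_ci"][0] < 1e-8

    def test_permuted_response_covers_zero(self, rng):
        layout = GenomeLayout([(f"lg{i}", int(mb * 1e6)) for i, mb in enumerate(range(5, 95, 9), 1)])
        mbs = np.array([g.length_bp / 1e6 for g in layout])
        y = 50 + 0.4 * mbs + rng.normal(0, 3, len(mbs))
        covered = 0
        for _ in range(100):
            perm = rng.permutation(y)
            reg = length_regression(dict(zip([g.lg_id for g in layout], perm)), layout)
            lo, hi = reg["beta_ci"]
            covered += lo <= 0 <= hi
        assert covered >= 90

    def test_two_lgs_rejected(self):
        layout = GenomeLayout([("lg1", 10_000_000), ("lg2", 20_000_000)])
        with pytest.raises(ValidationError):
            length_regression({"lg1": 50.0, "lg2": 60.0}, layout)


def test_genome_mean_rate_flat_track(small_layout, flat_track):
    w = windows_from_track(flat_track, small_layout, 10_000)
    # 1e-8 /bp track -> ~1 cM/Mb (Haldane correction is tiny at 10 kb)
    assert genome_mean_rate(w, small_layout) == pytest.approx(1.0, rel=1e-3)
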