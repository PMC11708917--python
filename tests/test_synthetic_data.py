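"""Ground-truth landscape, meiosis, diversity and replicate generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recland.core_io import GenomeLayout, ValidationError
from recland.synthetic_data import (
    CoModel,
    LandscapeModel,
    SimParams,
    default_layout,
    perturb_track,
    simulate_diversity,
    simulate_landscape,
    simulate_meioses,
)


def _one_lg_params(length=10_000_000, **kw):
    layout = GenomeLayout([("lg1", length, True)])
    return SimParams(layout=layout, **kw)


class TestLandscape:
    def test_determinism(self):
        p = SimParams(seed=7)
        a = simulate_landscape(p)
        b = simulate_landscape(p)
        pd.testing.assert_frame_equal(a.track.frame, b.track.frame)
        pd.testing.assert_frame_equal(a.hotspots, b.hotspots)

    def test_zero_density_equals_background(self):
        p = _one_lg_params(
            seed=3, landscape=LandscapeModel(hotspot_density_per_mb=0.0)
        )
        tl = simulate_landscape(p)
        assert len(tl.hotspots) == 0
        # pure background: one interval per 100 kb segment
        assert len(tl.track.frame) == 100

    def test_unit_intensity_indistinguishable_from_background(self):
        lm = LandscapeModel(hotspot_intensity=(1.0, 1.0), hotspot_density_per_mb=1.0)
        a = simulate_landscape(_one_lg_params(seed=11, landscape=lm))
        b = simulate_landscape(
            _one_lg_params(seed=12, landscape=LandscapeModel(hotspot_density_per_mb=0.0))
        )
        _, p = stats.ks_2samp(np.log(a.track.rates), np.log(b.track.rates))
        assert p > 0.01

    def test_capacity_error(self):
        lm = LandscapeModel(hotspot_density_per_mb=300.0, hotspot_width=2_000)
        with pytest.raises(ValidationError, match="density"):
            simulate_landscape(_one_lg_params(seed=1, landscape=lm))

    def test_hotspots_within_genome(self):
        tl = simulate_landscape(SimParams(seed=5))
        for g in tl.layout:
            h = tl.hotspots[tl.hotspots["lg"] == g.lg_id]
            assert (h["start"] >= 0).all() and (h["end"] <= g.length_bp).all()


class TestMeioses:
    def test_tetrad_mode_count_conservation(self):
        p = _one_lg_params(
            seed=2,
            n_meioses_per_sex=500,
            co=CoModel(extra_co_rate=0.0, record="tetrad"),
        )
        tl = simulate_landscape(p)
        cos = simulate_meioses(tl, p)
        # obligate CO: exactly one per meiosis per lg, both sexes
        assert len(cos) == 1000
        assert cos.groupby("meiosis_id").size().eq(1).all()

    def test_gamete_mode_transmits_half(self):
        p = _one_lg_params(
            seed=2, n_meioses_per_sex=5000, co=CoModel(extra_co_rate=0.0)
        )
        tl = simulate_landscape(p)
        cos = simulate_meioses(tl, p)
        # Binomial(10000, 1/2): 5 sigma ~ 250
        assert abs(len(cos) - 5000) < 250

    def test_uniform_placement_mean_position(self):
        L = 50_000_000
        p = _one_lg_params(
            length=L,
            seed=4,
            n_meioses_per_sex=5000,
            landscape=LandscapeModel(log_sd=0.0, hotspot_density_per_mb=0.0),
            co=CoModel(
                extra_co_rate=0.0,
                telomere_weight_male=0.0,
                telomere_weight_female=0.0,
                record="tetrad",
            ),
        )
        tl = simulate_landscape(p)
        cos = simulate_meioses(tl, p)
        se = (L / np.sqrt(12)) / np.sqrt(len(cos))
        assert abs(cos["pos_bp"].mean() - L / 2) < 3 * se

    def test_determinism(self):
        p = SimParams(seed=9)
        tl = simulate_landscape(p)
        pd.testing.assert_frame_equal(simulate_meioses(tl, p), simulate_meioses(tl, p))

    def test_empirical_rate_converges_to_truth(self):
        # binned CO density over many meioses tracks the truth landscape
        p = _one_lg_params(
            seed=6,
            n_meioses_per_sex=25_000,
            co=CoModel(
                extra_co_rate=0.0,
                telomere_weight_male=0.0,
                telomere_weight_female=0.0,
                record="tetrad",
            ),
        )
        tl = simulate_landscape(p)
        cos = simulate_meioses(tl, p)
        bins = np.arange(0, 10_000_001, 100_000)
        h, _ = np.histogram(cos["pos_bp"], bins=bins)
        from recland.synthetic_data import _binned_rate

        truth = _binned_rate(tl.track, "lg1", 10_000_000, 100_000)
        r = np.corrcoef(h, truth)[0, 1]
        assert r > 0.9


class TestDiversity:
    def test_slope_zero_uncorrelated(self):
        from recland.synthetic_data import DiversityModel

        p = SimParams(seed=8, diversity=DiversityModel(pi_slope=0.0, pi_intercept=0.004))
        tl = simulate_landscape(p)
        _, win = simulate_diversity(tl, p)
        r = np.corrcoef(np.log(win["rate"] + 1e-12), win["pi_true"])[0, 1]
        assert abs(r) < 0.05

    def test_positive_slope_correlated(self):
        p = SimParams(seed=8)
        tl = simulate_landscape(p)
        _, win = simulate_diversity(tl, p)
        r = np.corrcoef(np.log(win["rate"] + 1e-12), win["pi_true"])[0, 1]
        assert r > 0.5

    def test_zero_noise_monotone(self):
        from recland.synthetic_data import DiversityModel

        p = _one_lg_params(seed=8, diversity=DiversityModel(noise_sd=0.0))
        tl = simulate_landscape(p)
        _, win = simulate_diversity(tl, p)
        rho = stats.spearmanr(win["rate"], win["pi_true"]).statistic
        assert rho > 0.999


class TestPerturb:
    def test_sd_zero_identity(self, flat_track):
        out = perturb_track(flat_track, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.frame, flat_track.frame)

    def test_lower_noise_correlates_better(self):
        from recland.landscape import windows_from_track

        p = _one_lg_params(seed=10)
        tl = simulate_landscape(p)
        truth_w = windows_from_track(tl.track, p.layout, 1_000)["cm"]
        rs = {}
        for sd in (0.1, 1.0):
            rep = perturb_track(tl.track, sd, seed=42)
            w = windows_from_track(rep, p.layout, 1_000)["cm"]
            rs[sd] = np.corrcoef(np.log(truth_w + 1e-9), np.log(w + 1e-9))[0, 1]
        assert rs[0.1] > rs[1.0]

    def test_same_sd_different_seeds_equal_marginals(self):
        p = _one_lg_params(seed=10)
        tl = simulate_landscape(p)
        a = perturb_track(tl.track, 0.5, seed=1)
        b = perturb_track(tl.track, 0.5, seed=2)
        assert not a.frame.equals(b.frame)
        _, pv = stats.ks_2samp(np.log(a.rates), np.log(b.rates))
        assert pv > 0.01


def test_default_layout_shape():
    lay = default_layout()
    lengths = [g.length_bp for g in lay]
    assert len(lay) == 8
    assert min(lengths) == 5_000_000 and max(lengths) == 90_000_000
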