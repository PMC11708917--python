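"""Shared study context for the numbered analysis scripts.

Every script derives the same synthetic study from one seed, so they can
be run in any order.  The study emulates the structure of a barn-owl-like
data set: a genome of 8 linkage groups (5-90 Mb), 350 observed meioses
(175 per sex), an LD-style per-bp rate track observed with sampling
noise, windowed diversity coupled to recombination, and three
"populations" plus five subsampling pseudoreplicates sharing one true
landscape.
"""

from pathlib import Path

import numpy as np

from recland.genetic_map import build_sex_maps, trim_map_ends
from recland.synthetic_data import (
    SimParams,
    perturb_track,
    simulate_diversity,
    simulate_landscape,
    simulate_meioses,
)

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

MARKER_SPACING = 100_000  # linkage-map marker grid

# observation noise (log-sd of LD estimation error) per population; the
# better-sampled population has the least noise, mirroring n=76 vs n=13
POP_NOISE = {"CH": 0.25, "PT": 0.5, "GB": 0.9}
N_PSEUDOREPS = 5
PSEUDOREP_NOISE = 0.5


def get_study(seed: int = SEED):
    params = SimParams(seed=seed)
    truth = simulate_landscape(params)
    cos = simulate_meioses(truth, params)
    sites, div_windows = simulate_diversity(truth, params)
    return params, truth, cos, sites, div_windows


def marker_grid(layout, spacing: int = MARKER_SPACING):
    return {
        g.lg_id: np.arange(0, g.length_bp + 1, spacing, dtype=np.int64)
        for g in layout
    }


def linkage_maps(params, cos):
    maps = build_sex_maps(
        cos,
        marker_grid(params.layout),
        params.n_meioses_per_sex,
        params.n_meioses_per_sex,
    )
    # the 100-marker trim window of dense SNP maps would span entire lgs on
    # this sparse 100 kb grid; trim only the terminal handful of markers
    return {k: trim_map_ends(m, max_jump=2.0, window_markers=5) for k, m in maps.items()}


def observed_tracks(params, truth, seed: int = SEED):
    """Per-population noisy views of the true landscape."""
    pops = {
        name: perturb_track(truth.track, sd, seed=seed * 100 + i)
        for i, (name, sd) in enumerate(POP_NOISE.items())
    }
    for k in range(N_PSEUDOREPS):
        pops[f"CH13_{k + 1}"] = perturb_track(
            truth.track, PSEUDOREP_NOISE, seed=seed * 100 + 50 + k
        )
    return pops
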