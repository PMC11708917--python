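"""Cross-population comparison of recombination landscapes.

Populations are noisy views of a shared true landscape; comparisons are
made on window tables scaled to the same linkage map.  Correlations use
log-transformed rates with a pseudocount because per-window rates are
heavy-tailed.  Subsampling pseudoreplicates of the best-sampled
population provide an empirical envelope for estimation noise.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import RateTrack, ValidationError
from .synthetic_data import perturb_track

LOG_EPS = 1e-6  # cM/Mb pseudocount before log10


def multiscale_correlation(
    pop_windows: Mapping[str, pd.DataFrame], eps: float = LOG_EPS
) -> pd.DataFrame:
    """Pairwise Pearson matrix on log10(cM/Mb + eps) across populations.

    All tables must be windowed at the same size on the same layout; call
    once per window size.  Pairwise-complete windows are used.
    """
    names = list(pop_windows)
    if len(names) < 2:
        raise ValidationError("need >= 2 populations")
    cols = {}
    base = None
    for name in names:
        w = pop_windows[name]
        w = w[w["complete"]] if "complete" in w else w
        key = w.set_index(["lg", "start"])["cm_per_mb"]
        if base is None:
            base = key.index
        cols[name] = np.log10(key.reindex(base).to_numpy() + eps)
    mat = pd.DataFrame(cols).corr(method="pearson")
    return mat.loc[names, names]


def make_pseudoreplicates(
    truth: RateTrack,
    n_reps: int = 5,
    noise_sd: float = 0.5,
    seed: int = 0,
    segment_bp: int = 10_000,
) -> dict[str, RateTrack]:
    """n independent noisy replicate tracks of one landscape, distinct seeds."""
    return {
        f"rep{k + 1}": perturb_track(truth, noise_sd, seed=seed * 1000 + k, segment_bp=segment_bp)
        for k in range(n_reps)
    }


def hotspot_sharing(
    focal_hotspots: pd.DataFrame,
    pop_windows: Mapping[str, pd.DataFrame],
    span: int = 40_000,
) -> pd.DataFrame:
    """Mean flank-relative rate of each population at another's hotspots.

    ``focal_hotspots`` are hotspot windows (lg, start) called in one
    population; for every population the RRR80-style relative rate is
    averaged over those windows at each offset up to ``span``.  Returns a
    long table (offset_bp, population, mean_rel_rate, n_hotspots).
    """
    if len(focal_hotspots) == 0:
        raise ValidationError("empty hotspot set")
    from .hotspots import element_profile

    key = set(zip(focal_hotspots["lg"], focal_hotspots["start"]))
    out = []
    for name, w in pop_windows.items():
        flag = pd.Series(
            [(lg, s) in key for lg, s in zip(w["lg"], w["start"])], index=w.index
        )
        prof = element_profile(w, flag, span=span)
        prof["population"] = name
        out.append(prof)
    long = pd.concat(out, ignore_index=True)
    return long.rename(columns={"n": "n_hotspots"})


def outside_envelope(
    sharing: pd.DataFrame, population: str, replicate_names: list[str]
) -> bool:
    """True if a population's sharing curve at offset 0 falls outside the
    min-max envelope of the replicate curves (heuristic noise bound)."""
    at0 = sharing[sharing["offset_bp"] == 0].set_index("population")["mean_rel_rate"]
    env = at0.loc[replicate_names]
    val = at0.loc[population]
    return bool(val < env.min() or val > env.max())
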