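"""Landscape inequality: Lorenz curves and Gini coefficients per lg.

Orders 10 kb windows by decreasing rate, quantifies what fraction of
sequence carries 80% of the genetic length, and relates per-lg Gini to
physical length and to windowed nucleotide diversity.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from recland.hotspots import lorenz_gini
from recland.landscape import scale_to_linkage, windows_from_track


def main():
    params, truth, cos, sites, div_windows = common.get_study()
    maps = common.linkage_maps(params, cos)
    ch = common.observed_tracks(params, truth)["CH"]
    scaled = scale_to_linkage(ch, maps["avg"].lengths().to_dict())
    common.RESULTS.mkdir(exist_ok=True)

    w10 = windows_from_track(scaled.track, params.layout, 10_000)
    res = lorenz_gini(w10)

    per_lg = res.per_lg.set_index("lg")
    per_lg["length_mb"] = [params.layout.length_of(lg) / 1e6 for lg in per_lg.index]
    pi_by_lg = div_windows.groupby("lg")["pi_true"].mean()
    per_lg["mean_pi"] = pi_by_lg.reindex(per_lg.index)
    per_lg.to_csv(common.RESULTS / "05_gini.tsv", sep="\t")

    r_len = float(np.corrcoef(per_lg["length_mb"], per_lg["gini"])[0, 1])
    r_pi = float(np.corrcoef(per_lg["mean_pi"], per_lg["gini"])[0, 1])
    report = {
        "pooled_gini": round(res.pooled_gini, 3),
        "pooled_seq_frac_80": round(res.pooled_seq_frac_80, 3),
        "gini_range": [round(per_lg["gini"].min(), 3), round(per_lg["gini"].max(), 3)],
        "gini_vs_length_pearson": round(r_len, 3),
        "gini_vs_diversity_pearson": round(r_pi, 3),
    }
    (common.RESULTS / "05_gini_correlates.json").write_text(
        json.dumps(report, indent=2) + "\n"
    )
    print(json.dumps(report, indent=2))
    print(
        f"\n80% of recombination sits in {res.pooled_seq_frac_80:.0%} of the "
        "sequence. Per-lg Gini varies little here because every lg shares "
        "the same background model, so its correlations with length and "
        "diversity are weak by construction."
    )


if __name__ == "__main__":
    main()
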