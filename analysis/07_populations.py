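"""Compare recombination landscapes across populations.

Three populations (CH best-sampled, PT, GB noisiest) plus five CH
subsampling pseudoreplicates observe the same true landscape with
different noise.  Correlations are computed at 1 kb and 100 kb (broad
scale agrees better), and the RRR80 of every population is profiled at
the hotspots called in CH; the pseudoreplicate envelope separates
estimation noise from genuine divergence.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
import numpy as np
from recland.hotspots import call_local, rrr80
from recland.landscape import scale_to_linkage, windows_from_track
from recland.popcompare import hotspot_sharing, multiscale_correlation, outside_envelope


def main():
    params, truth, cos, _, _ = common.get_study()
    maps = common.linkage_maps(params, cos)
    link_cm = maps["avg"].lengths().to_dict()
    tracks = common.observed_tracks(params, truth)
    scaled = {k: scale_to_linkage(t, link_cm).track for k, t in tracks.items()}
    common.RESULTS.mkdir(exist_ok=True)

    report = {}
    pop_w = {}
    for size, label in ((1_000, "1kb"), (100_000, "100kb")):
        ws = {k: windows_from_track(t, params.layout, size) for k, t in scaled.items()}
        if size == 1_000:
            pop_w = ws
        mat = multiscale_correlation(ws)
        mat.to_csv(common.RESULTS / f"07_correlation_{label}.tsv", sep="\t")
        report[f"mean_pairwise_r_{label}"] = round(
            float(mat.to_numpy()[np.triu_indices(len(mat), k=1)].mean()), 3
        )
        report[f"r_CH_PT_{label}"] = round(float(mat.loc["CH", "PT"]), 3)
        report[f"r_CH_GB_{label}"] = round(float(mat.loc["CH", "GB"]), 3)

    ch = rrr80(pop_w["CH"])
    ch["repeat_bp"] = 0
    calls, runs = call_local(ch)
    sharing = hotspot_sharing(calls, pop_w)
    sharing.to_csv(common.RESULTS / "07_hotspot_sharing.tsv", sep="\t", index=False)
    reps = [f"CH13_{k + 1}" for k in range(common.N_PSEUDOREPS)]
    report["n_CH_hotspot_windows"] = int(len(calls))
    for pop in ("PT", "GB"):
        report[f"{pop}_outside_replicate_envelope"] = outside_envelope(
            sharing, pop, reps
        )
    at0 = sharing[sharing["offset_bp"] == 0].set_index("population")["mean_rel_rate"]
    report["sharing_peak_at_0"] = {k: round(float(v), 2) for k, v in at0.items()}

    (common.RESULTS / "07_populations.json").write_text(
        json.dumps(report, indent=2, default=bool) + "\n"
    )
    print(json.dumps(report, indent=2, default=bool))
    print(
        "\nBroad-scale (100 kb) correlations exceed fine-scale (1 kb); "
        "populations inside the pseudoreplicate envelope are statistically "
        "indistinguishable from sampling noise."
    )


if __name__ == "__main__":
    main()
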