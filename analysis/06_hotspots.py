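"""Hotspot/coldspot annotation and genomic covariates at two scales.

At 10 kb, windows are classified against the genome-average rate
(hotspot > 5x, coldspot < 1/5x, global >= 10x) and contrasted on
covariates (position along lg, GC on the lg with sequence, diversity,
gene count).  At 1 kb, local hotspots are called from RRR80 runs and
TSS/CGI enrichment profiles are computed.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from recland.hotspots import call_global, call_local, element_profile, rrr80
from recland.landscape import (
    genome_mean_rate,
    scale_to_linkage,
    window_covariates,
    windows_from_track,
)


def main():
    params, truth, cos, sites, _ = common.get_study()
    maps = common.linkage_maps(params, cos)
    ch = common.observed_tracks(params, truth)["CH"]
    scaled = scale_to_linkage(ch, maps["avg"].lengths().to_dict())
    common.RESULTS.mkdir(exist_ok=True)

    # GC demo sequence for the smallest lg only (GC ~ Bernoulli(0.5))
    rng = np.random.default_rng(common.SEED + 60)
    seq_lg = "lg8"
    seqs = {seq_lg: "".join(rng.choice(list("ACGT"), params.layout.length_of(seq_lg)))}

    w10 = windows_from_track(scaled.track, params.layout, 10_000)
    w10 = window_covariates(
        w10,
        seqs=seqs,
        genes=truth.genes,
        tss=truth.tss,
        cgi=truth.cgi,
        repeats=truth.repeats,
        mask=truth.mask,
        sites=sites,
        n_diploid=params.diversity.n_diploid,
    )
    mean_rate = genome_mean_rate(w10, params.layout)
    g10 = call_global(w10, mean_rate)
    g10.to_csv(common.SCRATCH / "windows_10kb_annotated.tsv", sep="\t", index=False)

    def contrast(col):
        return {
            "hotspot": float(g10.loc[g10["is_hotspot"], col].mean()),
            "coldspot": float(g10.loc[g10["is_coldspot"], col].mean()),
            "other": float(
                g10.loc[~(g10["is_hotspot"] | g10["is_coldspot"]), col].mean()
            ),
        }

    w1 = windows_from_track(scaled.track, params.layout, 1_000)
    w1 = window_covariates(
        w1, tss=truth.tss, cgi=truth.cgi, repeats=truth.repeats
    )
    w1 = rrr80(w1)
    calls, runs = call_local(w1)
    prof_tss = element_profile(w1, w1["has_tss"])
    prof_cgi = element_profile(w1, w1["full_cgi"])
    prof_tss.assign(element="tss").pipe(
        lambda a: pd.concat([a, prof_cgi.assign(element="cgi")])
    ).to_csv(common.RESULTS / "06_element_profiles.tsv", sep="\t", index=False)
    runs.to_csv(common.RESULTS / "06_local_hotspots.tsv", sep="\t", index=False)

    peak = prof_tss.set_index("offset_bp")["mean_rel_rate"]
    report = {
        "genome_mean_rate_cM_per_Mb": round(mean_rate, 3),
        "n_hotspot_windows_10kb": int(g10["is_hotspot"].sum()),
        "n_coldspot_windows_10kb": int(g10["is_coldspot"].sum()),
        "n_global_hotspot_windows_10kb": int(g10["is_global_hotspot"].sum()),
        "pi_contrast": contrast("pi"),
        "gene_contrast": contrast("n_genes"),
        "n_local_hotspot_windows_1kb": int(len(calls)),
        "n_local_hotspot_runs_1kb": int(len(runs)),
        "tss_profile_peak_rrr80": round(float(peak[0]), 2),
        "tss_profile_at_20kb": round(float(peak[20_000]), 2),
    }
    (common.RESULTS / "06_hotspots.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))
    print("\nRecombination peaks on TSS/CGI windows relative to their 80 kb flanks.")


if __name__ == "__main__":
    main()
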