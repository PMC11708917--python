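"""Generate the synthetic study inputs and write them in pipeline formats.

Creates the true landscape (rate track + annotations + planted hotspots),
the crossover table, the allele-frequency table, and the noisy population
tracks; writes them under scratch/inputs/ in the formats the pipeline
reads (rate-track TSV, BED, TSV), and demonstrates the exact mappability
mask on a small sequence with a planted duplication.  A summary of what
was generated goes to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common
from recland.core_io import (
    exact_mappability_mask,
    write_bed,
    write_fasta,
    write_rate_track,
)


def main():
    params, truth, cos, sites, div_windows = common.get_study()
    out = common.SCRATCH / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    common.RESULTS.mkdir(exist_ok=True)

    write_rate_track(truth.track, out / "truth_track.tsv")
    for name in ("genes", "tss", "cgi", "repeats", "mask"):
        write_bed(getattr(truth, name), out / f"{name}.bed")
    cos.to_csv(out / "crossovers.tsv", sep="\t", index=False)
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    for name, track in common.observed_tracks(params, truth).items():
        write_rate_track(track, out / f"track_{name}.tsv")

    # mappability demo: 100 kb random sequence with a 2 kb duplication
    rng = np.random.default_rng(common.SEED)
    seq = "".join(rng.choice(list("ACGT"), 100_000))
    seq = seq[:60_000] + seq[20_000:22_000] + seq[62_000:]
    write_fasta({"demo": seq}, out / "demo.fa")
    mask = exact_mappability_mask({"demo": seq})

    summary = {
        "seed": common.SEED,
        "linkage_groups": len(params.layout),
        "genome_mb": params.layout.total_bp() / 1e6,
        "n_meioses": 2 * params.n_meioses_per_sex,
        "n_crossovers_observed": int(len(cos)),
        "n_planted_hotspots": int(len(truth.hotspots)),
        "frac_hotspots_on_tss_cgi": float(truth.hotspots["on_element"].mean()),
        "n_sites": int(len(sites)),
        "mask_demo_masked_bp": mask.masked_bp["demo"],
    }
    (common.RESULTS / "01_inputs_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(json.dumps(summary, indent=2))
    print(
        f"\nWrote inputs to {out}; the duplicated 2 kb segment masks "
        f"{mask.masked_bp['demo']} bp of the 102 kb demo sequence."
    )


if __name__ == "__main__":
    main()
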