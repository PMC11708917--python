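"""Heterochiasmy statistics: crossover placement and intrachromosomal shuffling.

The shuffling rate r_intra of a chromosome is the expected probability
that a random pair of loci on it has its alleles shuffled by crossing
over, estimated as the mean over all pseudomarker pairs of a function of
their map separation, weighted by the squared fraction of genome length
the chromosome represents (L^2) — a chromosome twice as long holds four
times as many locus pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeLayout, ValidationError
from .genetic_map import GeneticMap, interpolate_pseudomarkers


# ---------------------------------------------------------------------------
# crossover placement


@dataclass
class PlacementDensity:
    """Per-sex histogram over relative distance from the nearest lg end,
    in % of lg length (support [0, 50]); bin masses sum to 1 per sex."""

    bin_edges: np.ndarray
    density: pd.DataFrame  # columns: sex, bin_lo, bin_hi, mass


def relative_end_distance(cos: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Add ``rel_pct`` = min(x, L - x)/L * 100 for every crossover."""
    out = cos.copy()
    L = out["lg"].map({g.lg_id: g.length_bp for g in layout}).astype(float)
    x = out["pos_bp"].astype(float)
    out["rel_pct"] = np.minimum(x, L - x) / L * 100.0
    return out


def placement_density(
    cos: pd.DataFrame, layout: GenomeLayout, n_bins: int = 50
) -> PlacementDensity:
    if len(cos) == 0:
        raise ValidationError("empty crossover table")
    rel = relative_end_distance(cos, layout)
    edges = np.linspace(0.0, 50.0, n_bins + 1)
    rows = []
    for sex, grp in rel.groupby("sex"):
        h, _ = np.histogram(grp["rel_pct"].to_numpy(), bins=edges)
        mass = h / h.sum()
        rows.append(
            pd.DataFrame(
                {"sex": sex, "bin_lo": edges[:-1], "bin_hi": edges[1:], "mass": mass}
            )
        )
    return PlacementDensity(edges, pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# two-sample KS with permutation p-value


def _ks_stat(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a - ECDF_b| by a sorted-merge sweep."""
    a, b = np.sort(a), np.sort(b)
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(fa - fb).max())


def ks_D(
    sample_a,
    sample_b,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS D and a label-permutation p-value.

    p = (1 + #{permuted D >= observed D}) / (n_perm + 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be non-empty")
    d_obs = _ks_stat(a, b)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    na = len(a)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        if _ks_stat(perm[:na], perm[na:]) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return d_obs, p


# ---------------------------------------------------------------------------
# r_intra


@dataclass
class ShufflingResult:
    frame: pd.DataFrame  # lg, n_pseudomarkers, g_mean, weight, r_intra
    total: float
    mode: str


def _mean_pairwise_cm(D: np.ndarray) -> float:
    """Mean |D_i - D_j| over unordered pairs, O(n log n) via sorted prefix sums."""
    D = np.sort(np.asarray(D, dtype=float))
    n = len(D)
    i = np.arange(n)
    s = float(np.sum(D * (2 * i - n + 1)))
    return s / (n * (n - 1) / 2)


def _mean_pairwise_haldane_p(D: np.ndarray) -> float:
    """Mean over pairs of haldane_p(|D_i - D_j|) via exponential prefix sums.

    haldane_p(d) = (1 - e^{-d/50})/2, so the pair mean needs only
    sum_{i<j} e^{-(D_j - D_i)/50}, computable in O(n) after sorting.
    """
    D = np.sort(np.asarray(D, dtype=float))
    n = len(D)
    x = (D - D.mean()) / 50.0  # centred to avoid overflow
    e_plus = np.exp(x)
    e_minus = np.exp(-x)
    cp = np.cumsum(e_plus)
    s = float(np.sum(e_minus[1:] * cp[:-1]))
    n_pairs = n * (n - 1) / 2
    return 0.5 * (1.0 - s / n_pairs)


def mean_pairwise_oracle(D: np.ndarray, mode: str) -> float:
    """O(n^2) reference for the prefix-sum pair means (tests only)."""
    from .genetic_map import haldane_p

    D = np.asarray(D, dtype=float)
    diff = np.abs(D[:, None] - D[None, :])
    iu = np.triu_indices(len(D), k=1)
    d = diff[iu]
    if mode == "morgan_linear":
        return float(np.mean(d)) / 100.0
    return float(np.mean(haldane_p(d)))


def r_intra(
    gmap: GeneticMap,
    layout: GenomeLayout,
    spacing: int = 10_000,
    mode: str = "haldane_prob",
) -> ShufflingResult:
    """Intrachromosomal shuffling from pseudomarker map separations.

    For each lg, g = mean over pseudomarker pairs of the shuffling
    probability of the pair: ``haldane_prob`` converts the cM separation to
    a recombination probability (bounded by 1/2, appropriate for maps over
    50 cM); ``morgan_linear`` uses the literal pairwise distance in Morgans.
    The lg contribution is g * (L/sum L)^2 over the lgs present in the map.
    """
    if mode not in ("haldane_prob", "morgan_linear"):
        raise ValueError(f"unknown mode {mode!r}")
    pseudo = interpolate_pseudomarkers(gmap, layout, spacing)
    lgs = list(dict.fromkeys(pseudo["lg"]))
    tot_len = float(sum(layout.length_of(lg) for lg in lgs))
    rows = []
    for lg in lgs:
        D = pseudo.loc[pseudo["lg"] == lg, "cm"].to_numpy()
        if len(D) < 2:
            raise ValidationError(f"< 2 pseudomarkers on {lg}")
        if mode == "morgan_linear":
            g = _mean_pairwise_cm(D) / 100.0
        else:
            g = _mean_pairwise_haldane_p(D)
        w = (layout.length_of(lg) / tot_len) ** 2
        rows.append((lg, len(D), g, w, g * w))
    frame = pd.DataFrame(
        rows, columns=["lg", "n_pseudomarkers", "g_mean", "weight", "r_intra"]
    )
    return ShufflingResult(frame, total=float(frame["r_intra"].sum()), mode=mode)


def shuffling_ratio(male: ShufflingResult, female: ShufflingResult) -> pd.DataFrame:
    """Per-lg male/female r_intra ratio; undefined ratios are flagged."""
    m = male.frame.set_index("lg")["r_intra"]
    f = female.frame.set_index("lg")["r_intra"]
    if set(m.index) != set(f.index):
        raise ValidationError("male and female results cover different lgs")
    out = pd.DataFrame({"r_intra_male": m, "r_intra_female": f.loc[m.index]})
    defined = out["r_intra_female"] > 0
    out["ratio"] = np.where(defined, out["r_intra_male"] / out["r_intra_female"], np.nan)
    out["defined"] = defined
    return out.reset_index()
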