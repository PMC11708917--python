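"""Genetic-map construction from crossover tables.

A crossover table records the breakpoints observed in transmitted gametes
(one "meiosis" = one parent-to-offspring transmission).  Map distance
between adjacent markers is estimated from the fraction of meioses with an
odd number of crossovers in the interval — what segregation data can
actually detect; an even number of COs between two markers leaves them in
the parental configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import GenomeLayout, ValidationError

CO_COLUMNS = ["meiosis_id", "sex", "lg", "pos_bp"]


# ---------------------------------------------------------------------------
# Haldane's mapping function


def haldane_cm(p):
    """Map distance d = -50 ln(1 - 2p) in cM for recombination fraction p.

    Assumes no crossover interference.  Domain: 0 <= p < 0.5.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 0.5)):
        raise ValueError("recombination fraction must satisfy 0 <= p < 0.5")
    out = -50.0 * np.log1p(-2.0 * p)
    return float(out) if out.ndim == 0 else out


def haldane_p(d):
    """Inverse of :func:`haldane_cm`: p = (1 - exp(-d/50)) / 2 for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = -0.5 * np.expm1(-d / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# crossover tables


def validate_crossovers(cos: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    cos = cos[CO_COLUMNS].copy()
    cos["pos_bp"] = cos["pos_bp"].astype(np.int64)
    if not cos["sex"].isin(["M", "F"]).all():
        raise ValidationError("sex must be 'M' or 'F'")
    if layout is not None:
        for lg, grp in cos.groupby("lg"):
            if (grp["pos_bp"] < 0).any() or (
                grp["pos_bp"] >= layout.length_of(lg)
            ).any():
                raise ValidationError(f"crossover beyond end of {lg}")
    return cos


# ---------------------------------------------------------------------------
# maps


@dataclass
class GeneticMap:
    """Per-lg ordered markers (bp) with cumulative genetic position (cM)."""

    frame: pd.DataFrame  # columns: lg, pos_bp, cm
    n_meioses: int = 0

    def __post_init__(self):
        f = self.frame[["lg", "pos_bp", "cm"]].copy()
        f["pos_bp"] = f["pos_bp"].astype(np.int64)
        for lg, grp in f.groupby("lg", sort=False):
            pos = grp["pos_bp"].to_numpy()
            cm = grp["cm"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(f"marker positions not strictly increasing on {lg}")
            if np.any(np.diff(cm) < 0):
                raise ValidationError(f"genetic positions decrease on {lg}")
        self.frame = f.reset_index(drop=True)

    @property
    def lg_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["lg"]))

    def markers(self, lg: str) -> tuple[np.ndarray, np.ndarray]:
        grp = self.frame[self.frame["lg"] == lg]
        return grp["pos_bp"].to_numpy(), grp["cm"].to_numpy()

    def lengths(self) -> pd.Series:
        g = self.frame.groupby("lg", sort=False)["cm"]
        return g.max() - g.min()

    def total_cm(self) -> float:
        return float(self.lengths().sum())


def build_map(
    cos: pd.DataFrame,
    markers: Mapping[str, np.ndarray],
    n_meioses: int,
    mode: str = "direct",
) -> GeneticMap:
    """Estimate a genetic map from observed crossovers on a marker grid.

    For each adjacent-marker interval the recombination fraction is
    c = (# meioses with an odd number of COs in the interval) / n_meioses;
    the interval distance is 100*c cM (``direct``) or Haldane-corrected
    -50 ln(1-2c) (``haldane``).  Meioses absent from the table count as
    non-recombinant, so ``n_meioses`` must be the number observed, not the
    number with crossovers.
    """
    if n_meioses <= 0:
        raise ValidationError("n_meioses must be positive")
    if mode not in ("direct", "haldane"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for lg, pos in markers.items():
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValidationError(f"markers not sorted/unique on {lg}")
        sub = cos[cos["lg"] == lg]
        n_iv = len(pos) - 1
        n_odd = np.zeros(n_iv)
        if len(sub) and n_iv > 0:
            iv = np.searchsorted(pos, sub["pos_bp"].to_numpy(), side="right") - 1
            ok = (iv >= 0) & (iv < n_iv)
            if ok.any():
                key = pd.DataFrame(
                    {"m": sub["meiosis_id"].to_numpy()[ok], "iv": iv[ok]}
                )
                odd = key.groupby(["m", "iv"]).size() % 2
                per_iv = odd.groupby(level="iv").sum()
                n_odd[per_iv.index.to_numpy()] = per_iv.to_numpy()
        c = n_odd / n_meioses
        if mode == "haldane":
            if np.any(c >= 0.5):
                raise ValidationError(
                    f"recombination fraction >= 0.5 on {lg}; use denser markers"
                )
            d = haldane_cm(c)
        else:
            d = 100.0 * c
        cm = np.concatenate([[0.0], np.cumsum(d)])
        rows.append(pd.DataFrame({"lg": lg, "pos_bp": pos, "cm": cm}))
    return GeneticMap(pd.concat(rows, ignore_index=True), n_meioses=n_meioses)


def build_sex_maps(
    cos: pd.DataFrame,
    markers: Mapping[str, np.ndarray],
    n_meioses_male: int,
    n_meioses_female: int,
    mode: str = "direct",
) -> dict[str, GeneticMap]:
    """Male, female, and sex-averaged maps from one crossover table.

    The sex-averaged map pools male and female meioses (as a pedigree
    mapper does across families), rather than averaging the two maps.
    """
    male = build_map(cos[cos["sex"] == "M"], markers, n_meioses_male, mode)
    female = build_map(cos[cos["sex"] == "F"], markers, n_meioses_female, mode)
    avg = build_map(cos, markers, n_meioses_male + n_meioses_female, mode)
    return {"M": male, "F": female, "avg": avg}


def trim_map_ends(
    gmap: GeneticMap, max_jump: float = 2.0, window_markers: int = 100
) -> GeneticMap:
    """Drop unreliable markers at LG ends.

    Markers within the terminal ``window_markers`` whose separation from
    their neighbour exceeds ``max_jump`` cM are removed iteratively from
    the ends inward; interior jumps are left alone.  Genetic positions are
    re-anchored to 0 at the new first marker.
    """
    rows = []
    for lg in gmap.lg_ids:
        pos, cm = gmap.markers(lg)
        pos, cm = pos.copy(), cm.copy()
        changed = True
        while changed and len(pos) > 1:
            changed = False
            gaps = np.diff(cm)
            n = len(pos)
            w = min(window_markers, n - 1)
            left_bad = np.nonzero(gaps[:w] > max_jump)[0]
            if len(left_bad):
                k = left_bad.max()  # drop markers 0..k (outer side of the gap)
                pos, cm = pos[k + 1 :], cm[k + 1 :]
                changed = True
                continue
            right_bad = np.nonzero(gaps[n - 1 - w :] > max_jump)[0]
            if len(right_bad):
                k = (n - 1 - w) + right_bad.min()  # gap between k and k+1
                pos, cm = pos[: k + 1], cm[: k + 1]
                changed = True
        if len(pos) < 2:
            raise ValidationError(f"all markers removed on {lg} (trimmed map degenerate)")
        cm = cm - cm[0]
        rows.append(pd.DataFrame({"lg": lg, "pos_bp": pos, "cm": cm}))
    return GeneticMap(pd.concat(rows, ignore_index=True), n_meioses=gmap.n_meioses)


def interpolate_pseudomarkers(
    gmap: GeneticMap,
    layout: GenomeLayout | None = None,
    spacing: int = 10_000,
) -> pd.DataFrame:
    """Place equidistant pseudomarkers and interpolate their cM positions.

    The grid starts at 0, steps by ``spacing`` and includes the sequence
    end (lg length if a layout is given, else the last marker).  cM values
    are linear interpolations between flanking true markers; positions
    outside the marker span clamp to the terminal cM values, since no
    segregation information exists out there.
    """
    rows = []
    for lg in gmap.lg_ids:
        pos, cm = gmap.markers(lg)
        if len(pos) < 2:
            raise ValidationError(f"need >= 2 markers on {lg}")
        if len(np.unique(pos)) != len(pos):
            raise ValidationError(f"duplicate marker positions on {lg}")
        end = layout.length_of(lg) if layout is not None else int(pos[-1])
        grid = np.arange(0, end, spacing, dtype=np.int64)
        if len(grid) == 0 or grid[-1] != end:
            grid = np.append(grid, end)
        d = np.interp(grid, pos, cm)  # clamps beyond the marker span
        rows.append(pd.DataFrame({"lg": lg, "pos_bp": grid, "cm": d}))
    return pd.concat(rows, ignore_index=True)


def write_sex_maps_tsv(maps: dict[str, GeneticMap], path) -> None:
    """Map TSV: lg, marker_bp, cM_male, cM_female, cM_avg."""
    out = maps["avg"].frame.rename(columns={"pos_bp": "marker_bp", "cm": "cM_avg"})
    for sex, col in (("M", "cM_male"), ("F", "cM_female")):
        f = maps[sex].frame.rename(columns={"pos_bp": "marker_bp", "cm": col})
        out = out.merge(f, on=["lg", "marker_bp"], how="left")
    out[["lg", "marker_bp", "cM_male", "cM_female", "cM_avg"]].to_csv(
        path, sep="\t", index=False
    )
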