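"""Windowed recombination maps, linkage scaling and window covariates.

Per-bp rate tracks are aggregated into fixed-size windows by converting
each track piece to map distance with Haldane's function (p = r * length,
d = -50 ln(1-2p)) and summing pieces pro-rata at window boundaries.
Because Haldane is applied per track piece, not per window, window cM are
additive across scales: a 1 Mb window equals the sum of its 1 kb windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    GenomeLayout,
    IntervalSet,
    RateTrack,
    ValidationError,
    merge_intervals,
)
from .genetic_map import haldane_cm, haldane_p

WINDOW_COLUMNS = ["lg", "start", "end", "cm", "cm_per_mb", "complete"]


def _pieces(s, e, r, extra_cuts):
    """Split intervals at extra cut points; returns (p0, p1, rate, interval index)."""
    cuts = np.unique(np.concatenate([s, e, np.asarray(extra_cuts, dtype=np.int64)]))
    p0, p1 = cuts[:-1], cuts[1:]
    iv = np.searchsorted(s, p0, side="right") - 1
    cov = (iv >= 0) & (p0 < e[np.clip(iv, 0, None)])
    return p0[cov], p1[cov], r[iv[cov]], iv[cov]


def windows_from_track(
    track: RateTrack, layout: GenomeLayout, size: int
) -> pd.DataFrame:
    """Tile each lg with ``size``-bp windows and accumulate cM from the track.

    Trailing partial windows are kept and their cM/Mb normalised by their
    true length; the ``complete`` flag marks full-size windows.
    """
    frames = []
    for g in layout:
        lg, L = g.lg_id, g.length_bp
        n_win = -(-L // size)
        starts = np.arange(n_win, dtype=np.int64) * size
        ends = np.minimum(starts + size, L)
        cm = np.zeros(n_win)
        s, e, r = track.arrays(lg)
        if len(s):
            p_iv = r.astype(float) * (e - s)
            if np.any(p_iv >= 0.5):
                raise ValidationError(
                    f"pathological rate on {lg}: interval recombination probability >= 0.5"
                )
            # Haldane per track interval; cM distributed pro-rata by bp so
            # window sums are exact across scales
            d_iv = haldane_cm(p_iv)
            edges = np.arange(size, n_win * size, size, dtype=np.int64)
            p0, p1, _, iv = _pieces(s, e, r.astype(float), edges)
            d = d_iv[iv] * (p1 - p0) / (e - s)[iv]
            np.add.at(cm, p0 // size, d)
        frames.append(
            pd.DataFrame(
                {
                    "lg": lg,
                    "start": starts,
                    "end": ends,
                    "cm": cm,
                    "cm_per_mb": cm / ((ends - starts) / 1e6),
                    "complete": ends - starts == size,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def track_cm_per_lg(track: RateTrack) -> pd.Series:
    """Total genetic length per lg implied by the track (Haldane per interval)."""
    f = track.frame
    d = haldane_cm((f["value"] * (f["end"] - f["start"])).to_numpy())
    return pd.Series(d).groupby(f["lg"].to_numpy()).sum()


def genome_mean_rate(windows: pd.DataFrame, layout: GenomeLayout) -> float:
    """Genome-average rate in cM/Mb: total autosomal cM / total autosomal Mb."""
    auto = set(layout.autosome_ids)
    sub = windows[windows["lg"].isin(auto)]
    mb = sum(layout.length_of(lg) for lg in auto) / 1e6
    return float(sub["cm"].sum() / mb)


@dataclass
class ScaledTrack:
    track: RateTrack
    factors: dict[str, float]


def scale_to_linkage(obj, linkage_cm: Mapping[str, float]):
    """Rescale LD-derived genetic lengths to match the linkage map per lg.

    LD-based rates are confounded by Ne; the per-lg factor
    f = linkage cM / LD cM fixes each lg's total.  Accepts a RateTrack
    (returns :class:`ScaledTrack`; per-interval cM are scaled and converted
    back to rates, so totals match exactly) or a window table (returns
    ``(windows, factors)``).
    """
    if isinstance(obj, RateTrack):
        ld = track_cm_per_lg(obj)
        rows, factors = [], {}
        for lg in obj.lg_ids:
            s, e, r = obj.arrays(lg)
            tot = float(ld.get(lg, 0.0))
            target = float(linkage_cm[lg])
            if tot == 0.0:
                if target > 0:
                    raise ValidationError(f"LD map length 0 on {lg} but linkage > 0")
                factors[lg] = 1.0
                rows.append(pd.DataFrame({"lg": lg, "start": s, "end": e, "value": r}))
                continue
            f = target / tot
            factors[lg] = f
            d = haldane_cm(r * (e - s)) * f
            r2 = haldane_p(d) / (e - s)
            rows.append(pd.DataFrame({"lg": lg, "start": s, "end": e, "value": r2}))
        return ScaledTrack(RateTrack(pd.concat(rows, ignore_index=True)), factors)
    windows = obj.copy()
    factors = {}
    for lg, grp in windows.groupby("lg", sort=False):
        tot = float(grp["cm"].sum())
        target = float(linkage_cm[lg])
        if tot == 0.0:
            if target > 0:
                raise ValidationError(f"LD map length 0 on {lg} but linkage > 0")
            factors[lg] = 1.0
            continue
        factors[lg] = target / tot
        idx = grp.index
        windows.loc[idx, "cm"] = grp["cm"] * factors[lg]
        windows.loc[idx, "cm_per_mb"] = windows.loc[idx, "cm"] / (
            (grp["end"] - grp["start"]) / 1e6
        )
    return windows, factors


# ---------------------------------------------------------------------------
# covariates


def _overlap_bp(iset: IntervalSet, lg: str, size: int, n_win: int, span: int) -> np.ndarray:
    """bp of the union of intervals overlapping each window; clipped to span."""
    merged = merge_intervals(iset)
    s, e, _ = merged.arrays(lg)
    out = np.zeros(n_win, dtype=np.int64)
    if len(s) == 0:
        return out
    edges = np.arange(size, n_win * size, size, dtype=np.int64)
    p0, p1, _, _ = _pieces(s, e, np.zeros(len(s)), np.append(edges, span))
    keep = p0 < span
    p0, p1 = p0[keep], np.minimum(p1[keep], span)
    np.add.at(out, p0 // size, p1 - p0)
    return out


def _count_overlapping(iset: IntervalSet, lg: str, size: int, n_win: int) -> np.ndarray:
    """Number of intervals overlapping each window (difference-array trick)."""
    s, e, _ = iset.arrays(lg)
    diff = np.zeros(n_win + 1, dtype=np.int64)
    if len(s):
        w0 = np.clip(s // size, 0, n_win - 1)
        w1 = np.clip((e - 1) // size, 0, n_win - 1)
        np.add.at(diff, w0, 1)
        np.add.at(diff, w1 + 1, -1)
    return np.cumsum(diff)[:-1]


def window_covariates(
    windows: pd.DataFrame,
    seqs: Mapping[str, str] | None = None,
    genes: IntervalSet | None = None,
    tss: IntervalSet | None = None,
    cgi: IntervalSet | None = None,
    repeats: IntervalSet | None = None,
    mask: IntervalSet | None = None,
    sites: pd.DataFrame | None = None,
    n_diploid: int | None = None,
) -> pd.DataFrame:
    """Annotate windows with GC, diversity, gene/TSS/CGI/repeat/mask covariates.

    GC is computed over unmasked bases.  Nucleotide diversity per window is
    sum over unmasked sites of 2p(1-p) * 2n/(2n-1), divided by the
    unmasked bp (mask-corrected); fully masked windows get pi = NaN with
    ``pi_defined`` False, not 0.
    """
    out = windows.copy()
    size = int((out["end"] - out["start"]).max())
    for col in ("gc_fraction", "pi"):
        out[col] = np.nan
    out["pi_defined"] = False
    out["n_genes"] = 0
    out["has_tss"] = False
    out["full_cgi"] = False
    out["repeat_bp"] = 0
    out["masked_bp"] = 0
    for lg, grp in out.groupby("lg", sort=False):
        n_win = len(grp)
        L = int(grp["end"].max())
        idx = grp.index
        win_len = (grp["end"] - grp["start"]).to_numpy()
        masked = np.zeros(n_win, dtype=np.int64)
        mask_s = mask_e = None
        if mask is not None:
            masked = _overlap_bp(mask, lg, size, n_win, L)
            mask_s, mask_e, _ = merge_intervals(mask).arrays(lg)
        out.loc[idx, "masked_bp"] = masked
        unmasked = win_len - masked
        if repeats is not None:
            out.loc[idx, "repeat_bp"] = _overlap_bp(repeats, lg, size, n_win, L)
        if genes is not None:
            out.loc[idx, "n_genes"] = _count_overlapping(genes, lg, size, n_win)
        if tss is not None:
            s, _, _ = tss.arrays(lg)
            flags = np.zeros(n_win, dtype=bool)
            if len(s):
                flags[np.clip(s // size, 0, n_win - 1)] = True
            out.loc[idx, "has_tss"] = flags
        if cgi is not None:
            s, e, _ = cgi.arrays(lg)
            flags = np.zeros(n_win, dtype=bool)
            ws = grp["start"].to_numpy()
            we = grp["end"].to_numpy()
            for a, b in zip(s, e):
                covered = (a <= ws) & (b >= we)
                flags |= covered
            out.loc[idx, "full_cgi"] = flags
        if seqs is not None and lg in seqs:
            seq = np.frombuffer(seqs[lg][:L].encode("ascii"), dtype=np.uint8)
            is_gc = (seq == ord("G")) | (seq == ord("C"))
            keep = np.ones(L, dtype=bool)
            if mask_s is not None:
                for a, b in zip(mask_s, mask_e):
                    keep[a:b] = False
            widx = np.arange(L) // size
            gc_counts = np.bincount(widx, weights=is_gc & keep, minlength=n_win)
            base_counts = np.bincount(widx, weights=keep, minlength=n_win)
            with np.errstate(invalid="ignore"):
                out.loc[idx, "gc_fraction"] = np.where(
                    base_counts > 0, gc_counts / np.maximum(base_counts, 1), np.nan
                )
        if sites is not None and n_diploid is not None:
            sub = sites[sites["lg"] == lg]
            pos = sub["pos_bp"].to_numpy()
            p = sub["p"].to_numpy()
            if mask_s is not None and len(mask_s):
                mi = np.searchsorted(mask_s, pos, side="right") - 1
                in_mask = (mi >= 0) & (pos < mask_e[np.clip(mi, 0, None)])
                pos, p = pos[~in_mask], p[~in_mask]
            corr = 2 * n_diploid / (2 * n_diploid - 1)
            het = 2.0 * p * (1.0 - p) * corr
            sums = np.bincount(
                np.clip(pos // size, 0, n_win - 1), weights=het, minlength=n_win
            )
            defined = unmasked > 0
            pi = np.full(n_win, np.nan)
            pi[defined] = sums[defined] / unmasked[defined]
            out.loc[idx, "pi"] = pi
            out.loc[idx, "pi_defined"] = defined
    return out


# ---------------------------------------------------------------------------
# genetic vs physical length


def length_regression(lengths_cm: Mapping[str, float], layout: GenomeLayout) -> dict:
    """OLS of genetic length (cM) on physical length (Mb), with 95% t CIs.

    Under one obligate CO per chromosome the intercept is expected near
    50 cM and the slope reflects extra crossovers on longer chromosomes.
    """
    import statsmodels.api as sm

    lgs = list(lengths_cm.keys())
    if len(lgs) < 3:
        raise ValidationError("need >= 3 lgs for the length regression")
    y = np.array([lengths_cm[lg] for lg in lgs], dtype=float)
    x = np.array([layout.length_of(lg) / 1e6 for lg in lgs], dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return {
        "alpha": float(model.params[0]),
        "beta": float(model.params[1]),
        "alpha_ci": (float(ci[0][0]), float(ci[0][1])),
        "beta_ci": (float(ci[1][0]), float(ci[1][1])),
        "t_beta": float(model.tvalues[1]),
        "p_beta": float(model.pvalues[1]),
        "n": len(lgs),
    }
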