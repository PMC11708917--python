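"""Landscape inequality (Lorenz/Gini) and hotspot/coldspot annotation.

Two hotspot definitions are kept separate, as they answer different
questions: 10 kb windows compared against the *genome-average* rate
(global hotspots/coldspots, used for covariate contrasts), and 1 kb
windows compared against their own *local* 80 kb flank (RRR80), used for
fine-scale hotspot calling and TSS/CGI enrichment profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ValidationError


# ---------------------------------------------------------------------------
# Lorenz / Gini


@dataclass
class LorenzResult:
    per_lg: pd.DataFrame  # lg, n_windows, gini, seq_frac_80
    curves: dict  # lg -> (x, y) cumulative sequence vs cumulative cM fraction
    pooled_gini: float
    pooled_curve: tuple[np.ndarray, np.ndarray]
    pooled_seq_frac_80: float


def _lorenz(values: np.ndarray):
    """Windows ordered by decreasing rate: cumulative sequence fraction x,
    cumulative cM fraction y, Gini = 2 x (trapezoid area above diagonal)."""
    v = np.sort(np.asarray(values, dtype=float))[::-1]
    n = len(v)
    tot = v.sum()
    x = np.arange(n + 1) / n
    if tot == 0:
        return x, np.full(n + 1, np.nan), np.nan, np.nan
    y = np.concatenate([[0.0], np.cumsum(v) / tot])
    gini = 2.0 * (np.trapezoid(y, x) - 0.5)
    seq80 = float(np.interp(0.8, y, x))
    return x, y, float(gini), seq80


def gini_oracle(values: np.ndarray) -> float:
    """O(n^2) mean-absolute-difference Gini (tests only)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    mu = v.mean()
    if mu == 0:
        return np.nan
    return float(np.abs(v[:, None] - v[None, :]).sum() / (2 * n * n * mu))


def lorenz_gini(windows: pd.DataFrame, value_col: str = "cm") -> LorenzResult:
    """Per-lg and pooled Lorenz curves and Gini coefficients.

    Only complete windows enter (partial trailing windows have unequal
    support); an all-zero lg gets gini = NaN.  Also reports the sequence
    fraction holding 80% of the genetic length.
    """
    comp = windows[windows["complete"]] if "complete" in windows else windows
    rows, curves = [], {}
    for lg, grp in comp.groupby("lg", sort=False):
        v = grp[value_col].to_numpy()
        if len(v) < 2:
            raise ValidationError(f"< 2 complete windows on {lg}")
        x, y, g, s80 = _lorenz(v)
        curves[lg] = (x, y)
        rows.append((lg, len(v), g, s80))
    x, y, g_all, s80_all = _lorenz(comp[value_col].to_numpy())
    return LorenzResult(
        per_lg=pd.DataFrame(rows, columns=["lg", "n_windows", "gini", "seq_frac_80"]),
        curves=curves,
        pooled_gini=g_all,
        pooled_curve=(x, y),
        pooled_seq_frac_80=s80_all,
    )


# ---------------------------------------------------------------------------
# global (genome-mean-relative) hotspots, 10 kb scale


def call_global(
    windows: pd.DataFrame,
    genome_mean_rate: float,
    hot_fold: float = 5.0,
    cold_fold: float = 5.0,
    alt_hot_fold: float = 10.0,
) -> pd.DataFrame:
    """Flag windows against the genome-average rate.

    Hotspots are *strictly more than* ``hot_fold`` times the mean;
    coldspots strictly less than mean/``cold_fold``; the alternative
    global set is *at least* ``alt_hot_fold`` times the mean (inclusive),
    matching the distinct "more than" and "at least" definitions.
    """
    if genome_mean_rate <= 0:
        raise ValidationError("genome mean rate must be positive")
    out = windows.copy()
    rate = out["cm_per_mb"].to_numpy()
    out["fold"] = rate / genome_mean_rate
    out["is_hotspot"] = rate > hot_fold * genome_mean_rate
    out["is_coldspot"] = rate < genome_mean_rate / cold_fold
    out["is_global_hotspot"] = rate >= alt_hot_fold * genome_mean_rate
    return out


# ---------------------------------------------------------------------------
# local (flank-relative) statistics, 1 kb scale


def rrr80(windows: pd.DataFrame, flank_bp: int = 40_000) -> pd.DataFrame:
    """Relative recombination rate in 80 kb: focal rate / mean flank rate.

    The flank is ``flank_bp`` each side, focal window excluded.  Near lg
    ends the statistic is computed if at least half of the flank windows
    exist, else left undefined; a zero flank mean is also undefined.
    """
    out = windows.copy()
    size = int((out["end"] - out["start"]).max())
    nf = flank_bp // size
    out["rrr80"] = np.nan
    out["rrr80_defined"] = False
    for lg, grp in out.groupby("lg", sort=False):
        v = grp["cm_per_mb"].to_numpy()
        n = len(v)
        c = np.concatenate([[0.0], np.cumsum(v)])
        i = np.arange(n)
        lo = np.maximum(i - nf, 0)
        hi = np.minimum(i + nf, n - 1)
        fsum = c[hi + 1] - c[lo] - v
        cnt = hi - lo  # flank windows available (focal excluded)
        with np.errstate(invalid="ignore", divide="ignore"):
            fmean = fsum / cnt
            rel = v / fmean
        defined = (cnt >= nf) & (fmean > 0)
        out.loc[grp.index, "rrr80"] = np.where(defined, rel, np.nan)
        out.loc[grp.index, "rrr80_defined"] = defined
    return out


def call_local(
    windows: pd.DataFrame,
    rrr80_min: float = 5.0,
    min_run: int = 2,
    rate_lo: float = 1.0,
    rate_hi: float = 10.0,
    max_repeat_bp: int = 500,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Local hotspots: runs of flank-elevated 1 kb windows.

    Candidates satisfy RRR80 >= ``rrr80_min`` (strictly > with
    ``strict=True``), a rate within [rate_lo, rate_hi] cM/Mb (hotspot
    inference has little power at extreme rates), and at most
    ``max_repeat_bp`` of annotated repeats.  Runs of at least ``min_run``
    consecutive candidates are emitted; returns (candidate windows in
    kept runs, merged run table).
    """
    if "rrr80" not in windows:
        raise ValidationError("run rrr80() first")
    w = windows.copy()
    size = int((w["end"] - w["start"]).max())
    rel = w["rrr80"].to_numpy()
    ok_rel = (rel > rrr80_min) if strict else (rel >= rrr80_min)
    cand = (
        w["rrr80_defined"].to_numpy()
        & np.nan_to_num(ok_rel)
        & (w["cm_per_mb"].to_numpy() >= rate_lo)
        & (w["cm_per_mb"].to_numpy() <= rate_hi)
        & (w.get("repeat_bp", pd.Series(0, index=w.index)).to_numpy() <= max_repeat_bp)
    )
    w["candidate"] = cand
    c = w[cand].copy()
    if len(c) == 0:
        empty = pd.DataFrame(columns=["lg", "start", "end", "n_windows"])
        return c, empty
    widx = c["start"].to_numpy() // size
    new_run = np.concatenate(
        [[True], (c["lg"].to_numpy()[1:] != c["lg"].to_numpy()[:-1]) | (np.diff(widx) != 1)]
    )
    c["run_id"] = np.cumsum(new_run) - 1
    runs_all = c.groupby("run_id").agg(
        lg=("lg", "first"),
        start=("start", "min"),
        end=("end", "max"),
        n_windows=("lg", "size"),
    )
    good = runs_all.index[runs_all["n_windows"] >= min_run]
    runs = runs_all.loc[good].reset_index(drop=True)
    calls = c[c["run_id"].isin(good)].drop(columns="run_id").reset_index(drop=True)
    return calls, runs


def element_profile(
    windows: pd.DataFrame,
    element_flag: pd.Series,
    span: int = 40_000,
) -> pd.DataFrame:
    """Mean flank-relative rate around annotated elements.

    For windows flagged as elements (containing a TSS, or fully inside a
    CGI), the rate at each +-``span`` offset is divided by the element's
    own 80 kb flank mean (focal excluded, require-half rule at lg ends)
    and averaged across elements.  A peak at offset 0 indicates elevated
    recombination at the elements themselves.
    """
    flag = np.asarray(element_flag, dtype=bool)
    if flag.sum() == 0:
        raise ValidationError("no elements flagged")
    size = int((windows["end"] - windows["start"]).max())
    nf = span // size
    offsets = np.arange(-nf, nf + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=np.int64)
    pos = 0
    for lg, grp in windows.groupby("lg", sort=False):
        v = grp["cm_per_mb"].to_numpy()
        n = len(v)
        f = flag[pos : pos + n]
        pos += n
        c = np.concatenate([[0.0], np.cumsum(v)])
        i = np.arange(n)
        lo = np.maximum(i - nf, 0)
        hi = np.minimum(i + nf, n - 1)
        fsum = c[hi + 1] - c[lo] - v
        cnt = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            fmean = fsum / cnt
        ok = (cnt >= nf) & (fmean > 0)
        el = np.nonzero(f & ok)[0]
        if len(el) == 0:
            continue
        for k, o in enumerate(offsets):
            t = el + o
            valid = (t >= 0) & (t < n)
            sums[k] += np.sum(v[t[valid]] / fmean[el[valid]])
            counts[k] += valid.sum()
    with np.errstate(invalid="ignore"):
        mean_rel = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"offset_bp": offsets * size, "mean_rel_rate": mean_rel, "n": counts}
    )
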