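"""Synthetic study inputs with ground truth.

Generates every input the pipeline consumes — a piecewise-constant "true"
recombination landscape with kb-scale hotspots colocated with TSS/CGI,
crossover tables from simulated meioses with sex-specific telomere-biased
placement, allele-frequency tables whose diversity tracks recombination,
and noisy population replicates of the shared landscape — so that recovery
of known truth can be tested end to end.

Defaults emulate the study conditions the pipeline targets: a bird-like
genome of linkage groups between 5 and 90 Mb, roughly 1–2 crossovers per
chromosome per meiosis with an obligate one, a genome-average rate near
2.3 cM/Mb, and 2 kb hotspots of 10–50 fold intensity placed mostly on
TSS/CGI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    GenomeLayout,
    IntervalSet,
    RateTrack,
    ValidationError,
)

_COLS = ["lg", "start", "end", "value"]


def default_layout() -> GenomeLayout:
    """Eight linkage groups spanning 5–90 Mb (desk-scale stand-in for ~40)."""
    mbs = (90, 70, 50, 35, 25, 15, 10, 5)
    return GenomeLayout(
        [(f"lg{i + 1}", mb * 1_000_000, True) for i, mb in enumerate(mbs)]
    )


@dataclass
class CoModel:
    """Crossover number and placement per meiosis.

    ``extra_co_rate`` is the expected number of additional COs per Morgan
    beyond the obligate one.  ``telomere_weight_*`` is the per-sex mixture
    weight of a symmetric U-shaped (Beta(1/2,1/2)-style) placement density
    on relative position; the remainder is uniform.  ``record`` selects
    whether the table holds the crossovers of the tetrad or only those
    transmitted to the sampled gamete (each tetrad CO is transmitted with
    probability 1/2) — pedigree data see the latter.
    """

    obligate: bool = True
    extra_co_rate: float = 0.5
    telomere_weight_male: float = 0.7
    telomere_weight_female: float = 0.4
    record: str = "gamete"  # or "tetrad"


@dataclass
class LandscapeModel:
    """Background rates are log-normal per 100 kb segment with arithmetic
    mean ``mean_rate`` (2.33e-8 /bp == 2.33 cM/Mb); hotspots are
    ``hotspot_width``-bp intervals multiplying the local background by a
    Uniform(*hotspot_intensity*) fold, a fraction of them centred on
    TSS/CGI elements."""

    mean_rate: float = 2.33e-8
    log_sd: float = 0.7
    segment_bp: int = 100_000
    hotspot_density_per_mb: float = 1.0
    hotspot_width: int = 2_000
    hotspot_intensity: tuple[float, float] = (10.0, 50.0)
    frac_at_tss_cgi: float = 0.8


@dataclass
class AnnotationModel:
    genes_per_mb: float = 10.0
    mean_gene_bp: int = 20_000
    cgi_per_mb: float = 10.0
    cgi_bp: int = 1_500
    repeat_fraction: float = 0.1
    repeat_bp: int = 500
    mask_fraction: float = 0.02
    mask_bp: int = 1_000


@dataclass
class DiversityModel:
    """pi = intercept + slope * ln(rate) + Normal(0, noise_sd), per window."""

    pi_intercept: float = 0.030
    pi_slope: float = 0.0015
    noise_sd: float = 2e-4
    n_diploid: int = 20
    site_window_bp: int = 10_000
    maf_low: float = 0.05
    maf_high: float = 0.5


@dataclass
class SimParams:
    seed: int = 0
    layout: GenomeLayout = field(default_factory=default_layout)
    n_meioses_per_sex: int = 175
    co: CoModel = field(default_factory=CoModel)
    landscape: LandscapeModel = field(default_factory=LandscapeModel)
    annotation: AnnotationModel = field(default_factory=AnnotationModel)
    diversity: DiversityModel = field(default_factory=DiversityModel)
    replicate_noise_sd: float = 0.5

    def __post_init__(self):
        for w in (self.co.telomere_weight_male, self.co.telomere_weight_female):
            if not 0.0 <= w <= 1.0:
                raise ValidationError("telomere mixture weight must be in [0, 1]")
        if self.landscape.mean_rate < 0 or self.co.extra_co_rate < 0:
            raise ValidationError("rates must be non-negative")
        if self.co.record not in ("gamete", "tetrad"):
            raise ValidationError("co.record must be 'gamete' or 'tetrad'")


@dataclass
class TrueLandscape:
    layout: GenomeLayout
    track: RateTrack
    hotspots: pd.DataFrame  # lg, start, end, intensity, on_element
    genes: IntervalSet
    tss: IntervalSet
    cgi: IntervalSet
    repeats: IntervalSet
    mask: IntervalSet
    params: SimParams


# ---------------------------------------------------------------------------
# landscape


def _random_intervals(rng, L, n, width):
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.sort(rng.integers(0, max(1, L - width), size=n))
    return starts, np.minimum(starts + width, L)


def simulate_landscape(params: SimParams) -> TrueLandscape:
    """Piecewise-constant truth track with planted hotspots and annotations."""
    rng = np.random.default_rng([params.seed, 1])
    lm, am = params.landscape, params.annotation
    track_rows, hot_rows = [], []
    gene_rows, tss_rows, cgi_rows, rep_rows, mask_rows = [], [], [], [], []
    for g in params.layout:
        lg, L = g.lg_id, g.length_bp
        mb = L / 1e6
        # background: log-normal per segment, arithmetic mean = mean_rate
        n_seg = -(-L // lm.segment_bp)
        mu = np.log(lm.mean_rate) - 0.5 * lm.log_sd**2 if lm.mean_rate > 0 else -np.inf
        seg_r = (
            np.exp(mu + lm.log_sd * rng.standard_normal(n_seg))
            if lm.mean_rate > 0
            else np.zeros(n_seg)
        )
        # annotations
        n_gene = rng.poisson(am.genes_per_mb * mb)
        g_start = np.sort(rng.integers(0, L, size=n_gene))
        g_len = np.maximum(rng.exponential(am.mean_gene_bp, size=n_gene), 200).astype(
            np.int64
        )
        g_end = np.minimum(g_start + g_len, L)
        gene_rows += [(lg, s, e, "gene") for s, e in zip(g_start, g_end)]
        tss_rows += [(lg, s, s + 1, "tss") for s in g_start]
        n_cgi = rng.poisson(am.cgi_per_mb * mb)
        c_start, c_end = _random_intervals(rng, L, n_cgi, am.cgi_bp)
        cgi_rows += [(lg, s, e, "cgi") for s, e in zip(c_start, c_end)]
        n_rep = int(round(am.repeat_fraction * L / am.repeat_bp))
        r_start, r_end = _random_intervals(rng, L, n_rep, am.repeat_bp)
        rep_rows += [(lg, s, e, "repeat") for s, e in zip(r_start, r_end)]
        n_mask = int(round(am.mask_fraction * L / am.mask_bp))
        m_start, m_end = _random_intervals(rng, L, n_mask, am.mask_bp)
        mask_rows += [(lg, s, e, np.nan) for s, e in zip(m_start, m_end)]
        # hotspots
        w = lm.hotspot_width
        n_hot = rng.poisson(lm.hotspot_density_per_mb * mb)
        if n_hot * w > 0.5 * L:
            raise ValidationError(
                f"hotspot density too high for {lg}: {n_hot} x {w} bp > half the lg"
            )
        elements = np.concatenate(
            [g_start, ((c_start + c_end) // 2).astype(np.int64)]
        )
        n_on = rng.binomial(n_hot, lm.frac_at_tss_cgi) if n_hot else 0
        n_on = min(n_on, len(elements))
        centers_on = (
            rng.choice(elements, size=n_on, replace=False) if n_on else np.empty(0)
        )
        centers_off = rng.integers(w // 2, max(w // 2 + 1, L - w // 2), size=n_hot - n_on)
        centers = np.concatenate([centers_on, centers_off]).astype(np.int64)
        on_flag = np.concatenate(
            [np.ones(n_on, bool), np.zeros(n_hot - n_on, bool)]
        )
        order = np.argsort(centers, kind="stable")
        centers, on_flag = centers[order], on_flag[order]
        hs = np.clip(centers - w // 2, 0, L)
        he = np.clip(hs + w, 0, L)
        keep_s, keep_e, keep_on = [], [], []
        last_end = -1
        for s, e, fl in zip(hs, he, on_flag):
            if s >= last_end and e > s:  # drop overlaps, keep first
                keep_s.append(s)
                keep_e.append(e)
                keep_on.append(fl)
                last_end = e
        inten = rng.uniform(*lm.hotspot_intensity, size=len(keep_s))
        hot_rows += [
            (lg, s, e, it, fl)
            for s, e, it, fl in zip(keep_s, keep_e, inten, keep_on)
        ]
        # assemble track: segment edges + hotspot edges
        seg_edges = np.arange(0, L, lm.segment_bp, dtype=np.int64)
        cuts = np.unique(
            np.concatenate([seg_edges, [L], np.array(keep_s + keep_e, dtype=np.int64)])
        )
        p0, p1 = cuts[:-1], cuts[1:]
        r = seg_r[p0 // lm.segment_bp].astype(float)
        if keep_s:
            hs_arr = np.array(keep_s, dtype=np.int64)
            he_arr = np.array(keep_e, dtype=np.int64)
            hi = np.searchsorted(hs_arr, p0, side="right") - 1
            in_hot = (hi >= 0) & (p0 < he_arr[np.clip(hi, 0, None)])
            r[in_hot] = r[in_hot] * inten[hi[in_hot]]
        track_rows.append(pd.DataFrame({"lg": lg, "start": p0, "end": p1, "value": r}))

    track = RateTrack(pd.concat(track_rows, ignore_index=True), params.layout)
    return TrueLandscape(
        layout=params.layout,
        track=track,
        hotspots=pd.DataFrame(
            hot_rows, columns=["lg", "start", "end", "intensity", "on_element"]
        ),
        genes=IntervalSet(pd.DataFrame(gene_rows, columns=_COLS), params.layout),
        tss=IntervalSet(pd.DataFrame(tss_rows, columns=_COLS), params.layout),
        cgi=IntervalSet(pd.DataFrame(cgi_rows, columns=_COLS), params.layout),
        repeats=IntervalSet(pd.DataFrame(rep_rows, columns=_COLS), params.layout),
        mask=IntervalSet(pd.DataFrame(mask_rows, columns=_COLS), params.layout),
        params=params,
    )


# ---------------------------------------------------------------------------
# meioses


def _binned_rate(track: RateTrack, lg: str, L: int, bin_bp: int) -> np.ndarray:
    """Mean per-bp rate in fixed bins (used as a sampling grid)."""
    nb = -(-L // bin_bp)
    s, e, r = track.arrays(lg)
    out = np.zeros(nb)
    if len(s) == 0:
        return out
    cuts = np.unique(
        np.concatenate([s, e, np.arange(bin_bp, nb * bin_bp, bin_bp, dtype=np.int64)])
    )
    p0, p1 = cuts[:-1], cuts[1:]
    iv = np.searchsorted(s, p0, side="right") - 1
    cov = (iv >= 0) & (p0 < e[np.clip(iv, 0, None)])
    np.add.at(out, p0[cov] // bin_bp, r[iv[cov]] * (p1 - p0)[cov])
    widths = np.full(nb, bin_bp, dtype=float)
    widths[-1] = L - (nb - 1) * bin_bp
    return out / widths


def _u_shape_pdf(t: np.ndarray) -> np.ndarray:
    """Beta(1/2, 1/2) density on (0, 1): symmetric, telomere-biased."""
    t = np.clip(t, 1e-6, 1 - 1e-6)
    return 1.0 / (np.pi * np.sqrt(t * (1.0 - t)))


def simulate_meioses(
    truth: TrueLandscape, params: SimParams, seed: int | None = None
) -> pd.DataFrame:
    """Crossover table (meiosis_id, sex, lg, pos_bp) from simulated meioses.

    Per meiosis and lg the tetrad receives one obligate CO (if enabled)
    plus Poisson(extra_co_rate x map Morgans) extras, all placed from the
    per-sex telomere/uniform mixture density re-weighted by the truth
    track.  With ``record='gamete'`` each tetrad CO is retained with
    probability 1/2, emulating what a parent-offspring transmission shows.
    """
    rng = np.random.default_rng([params.seed if seed is None else seed, 2])
    co = params.co
    bin_bp = 1_000
    rows = []
    for g in truth.layout:
        lg, L = g.lg_id, g.length_bp
        rate = _binned_rate(truth.track, lg, L, bin_bp)
        morgans = float(np.sum(rate) * bin_bp)  # total Morgans of the lg
        nb = len(rate)
        centers = (np.arange(nb) + 0.5) * bin_bp
        t = centers / L
        for sex, w in (
            ("M", co.telomere_weight_male),
            ("F", co.telomere_weight_female),
        ):
            pdf = w * _u_shape_pdf(t) + (1.0 - w)
            wt = pdf * rate
            if wt.sum() <= 0:
                wt = pdf.copy()
            wt = wt / wt.sum()
            n_extra = rng.poisson(co.extra_co_rate * morgans, size=params.n_meioses_per_sex)
            counts = (1 if co.obligate else 0) + n_extra
            total = int(counts.sum())
            if total == 0:
                continue
            bins = rng.choice(nb, size=total, p=wt)
            width = np.where(bins == nb - 1, L - (nb - 1) * bin_bp, bin_bp)
            pos = (bins * bin_bp + rng.random(total) * width).astype(np.int64)
            mei = np.repeat(np.arange(params.n_meioses_per_sex), counts)
            if co.record == "gamete":
                keep = rng.random(total) < 0.5
                pos, mei = pos[keep], mei[keep]
            rows.append(
                pd.DataFrame(
                    {
                        "meiosis_id": [f"{sex}{i}" for i in mei],
                        "sex": sex,
                        "lg": lg,
                        "pos_bp": pos,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=["meiosis_id", "sex", "lg", "pos_bp"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# diversity


def simulate_diversity(
    truth: TrueLandscape, params: SimParams, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site allele-frequency table plus the windowed true-pi covariate.

    Window-level target diversity follows pi = a + b ln(rate) + noise; the
    number of segregating sites per window is Poisson with mean chosen so
    the expected sum of 2p(1-p) over sites matches the target, with allele
    frequencies Uniform(maf_low, maf_high).
    """
    rng = np.random.default_rng([params.seed if seed is None else seed, 3])
    dm = params.diversity
    win = dm.site_window_bp
    lo, hi = dm.maf_low, dm.maf_high
    # E[2p(1-p)] for p ~ U(lo, hi)
    ep = (lo + hi) / 2.0
    ep2 = (lo * lo + lo * hi + hi * hi) / 3.0
    e2pq = 2.0 * (ep - ep2)
    site_rows, win_rows = [], []
    for g in truth.layout:
        lg, L = g.lg_id, g.length_bp
        rate = _binned_rate(truth.track, lg, L, win)
        nb = len(rate)
        starts = np.arange(nb, dtype=np.int64) * win
        ends = np.minimum(starts + win, L)
        pi = (
            dm.pi_intercept
            + dm.pi_slope * np.log(np.maximum(rate, 1e-12))
            + (rng.standard_normal(nb) * dm.noise_sd if dm.noise_sd > 0 else 0.0)
        )
        pi = np.maximum(pi, 0.0)
        n_sites = rng.poisson(pi * (ends - starts) / e2pq)
        tot = int(n_sites.sum())
        widx = np.repeat(np.arange(nb), n_sites)
        pos = starts[widx] + (rng.random(tot) * (ends - starts)[widx]).astype(np.int64)
        p = rng.uniform(lo, hi, size=tot)
        site_rows.append(pd.DataFrame({"lg": lg, "pos_bp": pos, "p": p}))
        win_rows.append(
            pd.DataFrame(
                {"lg": lg, "start": starts, "end": ends, "rate": rate, "pi_true": pi}
            )
        )
    return (
        pd.concat(site_rows, ignore_index=True),
        pd.concat(win_rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# population replicates


def perturb_track(
    track: RateTrack,
    noise_sd: float,
    seed: int,
    segment_bp: int = 10_000,
) -> RateTrack:
    """Noisy replicate of a rate track.

    Multiplicative log-normal noise, exp(Normal(0, noise_sd)), applied on
    ``segment_bp`` segments so estimation error is locally correlated, as
    it is for LD-based inference.  The expectation of the log-rate is
    preserved.  Adjacent equal-rate pieces are re-merged.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if noise_sd == 0:
        return RateTrack(track.frame.copy())
    rng = np.random.default_rng([seed, 4])
    rows = []
    for lg in track.lg_ids:
        s, e, r = track.arrays(lg)
        if len(s) == 0:
            continue
        L = int(e[-1])
        n_seg = -(-L // segment_bp)
        fac = np.exp(rng.standard_normal(n_seg) * noise_sd)
        cuts = np.unique(
            np.concatenate(
                [s, e, np.arange(segment_bp, n_seg * segment_bp, segment_bp, dtype=np.int64)]
            )
        )
        p0, p1 = cuts[:-1], cuts[1:]
        iv = np.searchsorted(s, p0, side="right") - 1
        cov = (iv >= 0) & (p0 < e[np.clip(iv, 0, None)])
        p0, p1, iv = p0[cov], p1[cov], iv[cov]
        pr = r[iv] * fac[p0 // segment_bp]
        # merge adjacent contiguous pieces with equal rate
        brk = np.concatenate([[True], (pr[1:] != pr[:-1]) | (p0[1:] != p1[:-1])])
        gid = np.cumsum(brk) - 1
        ms = p0[brk]
        me = np.zeros(gid.max() + 1, dtype=np.int64)
        np.maximum.at(me, gid, p1)
        mr = pr[brk]
        rows.append(pd.DataFrame({"lg": lg, "start": ms, "end": me, "value": mr}))
    return RateTrack(pd.concat(rows, ignore_index=True))
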