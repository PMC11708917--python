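"""Data model, coordinate conventions and file I/O.

All interval data are 0-based, half-open ``[start, end)`` (BED convention);
marker and crossover positions are 0-based bp points.  Recombination rates
are per-bp, per-generation crossover probabilities — the scale produced by
LD-based estimators such as pyrho once rho is divided by 4Ne — so a rate of
1e-8 /bp equals 1 cM/Mb.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a structural invariant (bad coordinates, negative rate...)."""


class ParseError(ValueError):
    """A file could not be parsed; message carries the offending line number."""


# ---------------------------------------------------------------------------
# genome layout


@dataclass(frozen=True)
class LinkageGroup:
    lg_id: str
    length_bp: int
    is_autosome: bool = True


class GenomeLayout:
    """Ordered set of linkage groups (chromosome-scale scaffolds) with lengths."""

    def __init__(self, groups: Iterable):
        gs = []
        for g in groups:
            if not isinstance(g, LinkageGroup):
                g = LinkageGroup(*g)
            gs.append(g)
        ids = [g.lg_id for g in gs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate linkage-group ids")
        for g in gs:
            if int(g.length_bp) < 1:
                raise ValidationError(f"non-positive length for {g.lg_id}")
        self.groups = tuple(gs)
        self._length = {g.lg_id: int(g.length_bp) for g in gs}
        self._auto = {g.lg_id: bool(g.is_autosome) for g in gs}

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    @property
    def ids(self) -> list[str]:
        return [g.lg_id for g in self.groups]

    @property
    def autosome_ids(self) -> list[str]:
        return [g.lg_id for g in self.groups if g.is_autosome]

    def length_of(self, lg_id: str) -> int:
        return self._length[lg_id]

    def is_autosome(self, lg_id: str) -> bool:
        return self._auto[lg_id]

    def total_bp(self, autosomes_only: bool = False) -> int:
        return sum(
            g.length_bp for g in self.groups if g.is_autosome or not autosomes_only
        )


# ---------------------------------------------------------------------------
# interval containers

_COLS = ["lg", "start", "end", "value"]


class IntervalSet:
    """Records of (lg, start, end, value), per-lg sorted.

    ``value`` may be a label (BED name) or a number; overlap between
    intervals is allowed here (genes overlap), but not in :class:`RateTrack`.
    """

    def __init__(self, frame: pd.DataFrame, layout: GenomeLayout | None = None):
        f = frame.copy()
        if "value" not in f.columns:
            f["value"] = np.nan
        f = f[_COLS]
        f["start"] = f["start"].astype(np.int64)
        f["end"] = f["end"].astype(np.int64)
        f["lg"] = f["lg"].astype(str)
        f = f.sort_values(["lg", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        if (f["start"] < 0).any():
            raise ValidationError("negative interval start")
        if (f["start"] >= f["end"]).any():
            bad = f[f["start"] >= f["end"]].iloc[0]
            raise ValidationError(
                f"interval start >= end on {bad.lg}: {bad.start} >= {bad.end}"
            )
        if layout is not None:
            for lg, grp in f.groupby("lg", sort=False):
                if lg not in layout._length:
                    raise ValidationError(f"unknown linkage group {lg!r}")
                if (grp["end"] > layout.length_of(lg)).any():
                    raise ValidationError(f"interval beyond end of {lg}")
        self.frame = f

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        if not isinstance(other, IntervalSet):
            return NotImplemented
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        same = (
            a[["lg", "start", "end"]].reset_index(drop=True).equals(
                b[["lg", "start", "end"]].reset_index(drop=True)
            )
        )
        av, bv = a["value"].to_numpy(), b["value"].to_numpy()
        vals = all(
            (x == y) or (pd.isna(x) and pd.isna(y)) for x, y in zip(av, bv)
        )
        return same and vals

    @property
    def lg_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["lg"]))

    def arrays(self, lg: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one lg; empty arrays if absent."""
        grp = self.frame[self.frame["lg"] == lg]
        return (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["value"].to_numpy(),
        )

    def total_bp(self) -> int:
        return int((self.frame["end"] - self.frame["start"]).sum())

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=_COLS))


class RateTrack(IntervalSet):
    """Piecewise-constant per-bp per-generation recombination probabilities.

    Intervals tile or partially cover each lg without overlap; rates are
    finite and non-negative.
    """

    def __init__(self, frame: pd.DataFrame, layout: GenomeLayout | None = None):
        super().__init__(frame, layout)
        r = pd.to_numeric(self.frame["value"], errors="coerce")
        if r.isna().any() or not np.isfinite(r).all():
            raise ValidationError("non-numeric or non-finite rate")
        if (r < 0).any():
            raise ValidationError("negative recombination rate")
        self.frame["value"] = r.astype(float)
        for lg, grp in self.frame.groupby("lg", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise ValidationError(f"overlapping rate intervals on {lg}")

    @property
    def rates(self) -> np.ndarray:
        return self.frame["value"].to_numpy()


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Union of intervals per lg (values dropped)."""
    rows = []
    for lg in iset.lg_ids:
        s, e, _ = iset.arrays(lg)
        cs, ce = None, None
        for a, b in zip(s, e):
            if cs is None:
                cs, ce = a, b
            elif a <= ce:
                ce = max(ce, b)
            else:
                rows.append((lg, cs, ce, np.nan))
                cs, ce = a, b
        if cs is not None:
            rows.append((lg, cs, ce, np.nan))
    return IntervalSet(pd.DataFrame(rows, columns=_COLS))


# ---------------------------------------------------------------------------
# readers / writers


def read_rate_track(path, layout: GenomeLayout | None = None) -> RateTrack:
    """Parse a 4-column whitespace-separated 'chrom start end rate' file."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            lg, s, e, r = parts
            try:
                s, e, r = int(s), int(e), float(r)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            if s >= e:
                raise ParseError(f"{path}:{ln}: start >= end ({s} >= {e})")
            rows.append((lg, s, e, r))
    return RateTrack(pd.DataFrame(rows, columns=_COLS), layout)


def write_rate_track(track: RateTrack, path) -> None:
    with open(path, "w") as fh:
        for row in track.frame.itertuples(index=False):
            fh.write(f"{row.lg}\t{row.start}\t{row.end}\t{row.value:.12g}\n")


def read_bed(path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read a 3+ column BED file; column 4 (name) becomes ``value``."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >= 3 columns")
            lg, s, e = parts[0], parts[1], parts[2]
            try:
                s, e = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from None
            name = parts[3] if len(parts) > 3 else np.nan
            rows.append((lg, s, e, name))
    return IntervalSet(pd.DataFrame(rows, columns=_COLS), layout)


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for row in iset.frame.itertuples(index=False):
            if pd.isna(row.value):
                fh.write(f"{row.lg}\t{row.start}\t{row.end}\n")
            else:
                fh.write(f"{row.lg}\t{row.start}\t{row.end}\t{row.value}\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_run_metadata(path, **params) -> None:
    """JSON sidecar recording the parameters and seed of a run."""
    Path(path).write_text(json.dumps(params, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# mappability mask


@dataclass
class MaskResult:
    intervals: IntervalSet
    masked_bp: dict[str, int]


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def exact_mappability_mask(
    fasta,
    read_len: int = 150,
    step: int = 1,
    min_frac: float = 0.9,
    block: int = 150,
) -> MaskResult:
    """Mask blocks where short reads cannot be placed uniquely.

    The genome is split into ``read_len``-mers every ``step`` bp; a read is
    "unique" when its sequence occurs exactly once in the genome counting
    both strands (canonical k-mer counting).  Reads containing non-ACGT
    bases are never unique.  For each ``block``-bp block, the fraction of
    overlapping reads that are unique is computed; blocks with fraction
    strictly below ``min_frac`` are masked.

    ``fasta`` may be a path or a mapping of name -> sequence.
    """
    if isinstance(fasta, (str, Path)):
        seqs = read_fasta(fasta)
    else:
        seqs = {k: v.upper() for k, v in fasta.items()}
    if not seqs:
        raise ValidationError("empty genome")
    for name, seq in seqs.items():
        if len(seq) < read_len:
            raise ValidationError(f"sequence {name} shorter than read_len")

    acgt = frozenset("ACGT")
    counts: dict[str, int] = {}
    starts_per_seq: dict[str, np.ndarray] = {}
    for name, seq in seqs.items():
        starts = np.arange(0, len(seq) - read_len + 1, step)
        starts_per_seq[name] = starts
        for i in starts:
            km = seq[i : i + read_len]
            if not acgt.issuperset(km):
                continue
            rc = _revcomp(km)
            canon = km if km <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1

    rows = []
    masked_bp = {}
    for name, seq in seqs.items():
        starts = starts_per_seq[name]
        uniq = np.zeros(len(starts), dtype=bool)
        for k, i in enumerate(starts):
            km = seq[i : i + read_len]
            if not acgt.issuperset(km):
                continue
            rc = _revcomp(km)
            canon = km if km <= rc else rc
            uniq[k] = counts[canon] == 1
        L = len(seq)
        mb = 0
        run_start = None
        for b0 in range(0, L, block):
            b1 = min(b0 + block, L)
            # reads overlapping [b0, b1): start in [b0-read_len+1, b1-1]
            lo = np.searchsorted(starts, b0 - read_len + 1)
            hi = np.searchsorted(starts, b1 - 1, side="right")
            frac = uniq[lo:hi].mean() if hi > lo else 0.0
            if frac < min_frac:
                mb += b1 - b0
                if run_start is None:
                    run_start = b0
            else:
                if run_start is not None:
                    rows.append((name, run_start, b0, np.nan))
                    run_start = None
        if run_start is not None:
            rows.append((name, run_start, L, np.nan))
        masked_bp[name] = mb
    return MaskResult(
        intervals=IntervalSet(pd.DataFrame(rows, columns=_COLS)),
        masked_bp=masked_bp,
    )
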