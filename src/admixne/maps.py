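"""Recombination-map containers, dialects, binning, comparison and hotspot calling.

A genetic map is stored as a piecewise-constant rate function over contiguous,
0-based half-open intervals.  Rates are per-bp per-generation recombination
probabilities; genetic positions are centimorgans (cM), with
``cm[i+1] = cm[i] + rate[i] * width[i] * 100``.

Two text dialects are supported:

* ``hapmap`` -- columns ``Chromosome  Position(bp)  Rate(cM/Mb)  Map(cM)``;
  each rate applies from its position to the next (the last rate is 0).
* ``interval`` -- TSV columns ``chrom  start  end  rate`` with the rate in
  per-bp per-generation units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "RecombinationMap",
    "BinnedMap",
    "read_map",
    "write_map",
    "bin_rates",
    "spearman_matrix",
    "cluster_order",
    "call_hotspots",
    "hotspot_concordance",
]


class MapFormatError(ValueError):
    """Raised when a map file violates its dialect."""


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination map over one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray  # per-bp per-generation
    hotspots: np.ndarray | None = None  # (n, 2) bp intervals, if known
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.starts.size == 0:
            raise MapFormatError("empty map")
        if self.starts.shape != self.ends.shape or self.starts.shape != self.rates.shape:
            raise MapFormatError("starts/ends/rates length mismatch")
        if np.any(self.ends <= self.starts):
            raise MapFormatError("intervals must have positive width")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise MapFormatError("intervals must be contiguous and sorted")
        if np.any(self.rates < 0):
            raise MapFormatError("negative recombination rate")
        widths = (self.ends - self.starts).astype(np.float64)
        self._edges = np.concatenate([self.starts, self.ends[-1:]]).astype(np.float64)
        self._cum_cm = np.concatenate([[0.0], np.cumsum(self.rates * widths * 100.0)])

    # ------------------------------------------------------------------ basic
    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    @property
    def total_cm(self) -> float:
        return float(self._cum_cm[-1])

    @property
    def total_morgans(self) -> float:
        return self.total_cm / 100.0

    @property
    def cumulative_cm(self) -> np.ndarray:
        """Cumulative cM at interval starts."""
        return self._cum_cm[:-1].copy()

    def interp_cm(self, pos, clamp: bool = False):
        """Genetic position (cM) at physical position(s) by linear interpolation."""
        pos = np.asarray(pos, dtype=np.float64)
        lo, hi = self.span
        if clamp:
            pos = np.clip(pos, lo, hi)
        elif np.any(pos < lo) or np.any(pos > hi):
            raise ValueError(f"position outside map span [{lo}, {hi})")
        out = np.interp(pos, self._edges, self._cum_cm)
        return float(out) if out.ndim == 0 else out

    def cm_between(self, start, end) -> float:
        return float(self.interp_cm(end) - self.interp_cm(start))

    def pos_at_cm(self, cm):
        """Inverse of :meth:`interp_cm` (physical bp at a cumulative cM)."""
        cm = np.asarray(cm, dtype=np.float64)
        out = np.interp(cm, self._cum_cm, self._edges)
        return float(out) if out.ndim == 0 else out


@dataclass
class BinnedMap:
    """Mean rate (cM/Mb) in fixed-width bins anchored at ``origin``."""

    chrom: str
    bin_width: int
    origin: int
    values: pd.Series  # index = bin start bp; NaN where the map has no coverage

    @property
    def total_cm(self) -> float:
        return float(np.nansum(self.values.to_numpy()) * self.bin_width / 1e6)


# ---------------------------------------------------------------------- I/O

_HAPMAP_HEADER = "Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)"


def read_map(path, dialect: str = "hapmap", map_tolerance_cm: float = 1e-6) -> RecombinationMap:
    """Read a genetic map in the ``hapmap`` or ``interval`` dialect."""
    if dialect == "hapmap":
        return _read_hapmap(path, map_tolerance_cm)
    if dialect == "interval":
        return _read_interval(path)
    raise ValueError(f"unknown map dialect: {dialect!r}")


def _read_hapmap(path, tol_cm: float) -> RecombinationMap:
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    cols = [c.lower() for c in df.columns]
    if len(df.columns) == 3:  # chromosome column omitted
        df.columns = ["pos", "rate", "map"]
        chrom = "1"
    elif len(df.columns) == 4:
        df.columns = ["chrom", "pos", "rate", "map"]
        chroms = df["chrom"].astype(str).unique()
        if len(chroms) != 1:
            raise MapFormatError("hapmap reader handles one chromosome per file")
        chrom = chroms[0]
    else:
        raise MapFormatError(f"expected 3 or 4 columns, got {len(df.columns)} ({cols})")
    pos = df["pos"].to_numpy(dtype=np.int64)
    rate_cm_mb = df["rate"].to_numpy(dtype=np.float64)
    map_cm = df["map"].to_numpy(dtype=np.float64)
    if len(pos) < 2:
        raise MapFormatError("hapmap map needs at least two positions")
    if np.any(np.diff(pos) <= 0):
        bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 2
        raise MapFormatError(f"non-increasing position at data line {bad}")
    if np.any(rate_cm_mb < 0):
        raise MapFormatError("negative rate")
    starts, ends = pos[:-1], pos[1:]
    rates = rate_cm_mb[:-1] * 1e-8  # cM/Mb -> per-bp per-generation
    m = RecombinationMap(chrom=str(chrom), starts=starts, ends=ends, rates=rates)
    recomputed = m._cum_cm + map_cm[0]
    if np.max(np.abs(recomputed - map_cm)) > tol_cm:
        raise MapFormatError(
            "Map(cM) column inconsistent with rates beyond "
            f"{tol_cm} cM (max deviation {np.max(np.abs(recomputed - map_cm)):.3g})"
        )
    return m


def _read_interval(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["chrom", "start", "end", "rate"]
    if list(df.columns) != expected:
        raise MapFormatError(f"interval dialect needs columns {expected}, got {list(df.columns)}")
    chroms = df["chrom"].astype(str).unique()
    if len(chroms) != 1:
        raise MapFormatError("interval reader handles one chromosome per file")
    return RecombinationMap(
        chrom=chroms[0],
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        rates=df["rate"].to_numpy(np.float64),
    )


def write_map(gmap: RecombinationMap, path, dialect: str = "hapmap") -> None:
    """Write a map in the requested dialect (round-trips bit-exactly)."""
    if dialect == "hapmap":
        pos = np.concatenate([gmap.starts, gmap.ends[-1:]])
        rate = np.concatenate([gmap.rates * 1e8, [0.0]])
        with open(path, "w") as fh:
            fh.write(_HAPMAP_HEADER + "\n")
            for p, r, c in zip(pos, rate, gmap._cum_cm):
                fh.write(f"{gmap.chrom}\t{p}\t{r:.17g}\t{c:.17g}\n")
    elif dialect == "interval":
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\trate\n")
            for s, e, r in zip(gmap.starts, gmap.ends, gmap.rates):
                fh.write(f"{gmap.chrom}\t{s}\t{e}\t{r:.17g}\n")
    else:
        raise ValueError(f"unknown map dialect: {dialect!r}")


# ------------------------------------------------------------------- binning


def bin_rates(gmap: RecombinationMap, bin_width: int = 2000) -> BinnedMap:
    """Mean rate per bin in cM/Mb, computed from cumulative-cM differences.

    Bins are anchored at position 0.  The value of a bin is
    ``cM inside the bin / bin width in Mb``, which makes
    ``sum(value * width)`` equal the map's total cM exactly; bins with no map
    coverage are NaN (missing), never zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = gmap.span
    first = lo // bin_width
    last = (hi - 1) // bin_width
    bin_starts = np.arange(first, last + 1, dtype=np.int64) * bin_width
    a = np.maximum(bin_starts, lo).astype(np.float64)
    b = np.minimum(bin_starts + bin_width, hi).astype(np.float64)
    cm = gmap.interp_cm(b) - gmap.interp_cm(a)
    values = cm / (bin_width / 1e6)
    return BinnedMap(
        chrom=gmap.chrom,
        bin_width=int(bin_width),
        origin=0,
        values=pd.Series(values, index=bin_starts),
    )


def spearman_matrix(binned: dict[str, BinnedMap] | list[BinnedMap], min_overlap: int = 100) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of binned maps over shared bins.

    Ties are mid-ranked.  Pairs with fewer than ``min_overlap`` jointly covered
    bins get NaN (flagged missing, never silently 0).
    """
    if isinstance(binned, list):
        binned = {f"map{i}": b for i, b in enumerate(binned)}
    names = list(binned)
    widths = {b.bin_width for b in binned.values()}
    origins = {b.origin for b in binned.values()}
    if len(widths) != 1 or len(origins) != 1:
        raise ValueError("all maps must be binned at identical width and origin")
    table = pd.DataFrame({k: b.values for k, b in binned.items()})
    n = len(names)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            sub = table.iloc[:, [i, j]].dropna()
            if len(sub) < min_overlap:
                continue
            rho = spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=names, columns=names)


def cluster_order(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering on distance ``1 - rho``.

    Returns the leaf ordering (labels) and the scipy linkage matrix.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError(
            "correlation matrix has missing entries; impute or raise min_overlap coverage first"
        )
    dist = 1.0 - matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [matrix.index[i] for i in leaves_list(z)]
    return order, z


# ------------------------------------------------------------------ hotspots


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def call_hotspots(
    gmap: RecombinationMap,
    bg_window_bp: int = 100_000,
    fold: float = 10.0,
    min_width_bp: int = 500,
) -> np.ndarray:
    """Call hotspot intervals: maximal runs with rate >= fold x local background.

    The local background at an interval is the length-weighted median rate in
    the ``bg_window_bp`` flanking window centred on the interval midpoint.
    Returns an (n, 2) array of bp intervals.  Calls are invariant to global
    rate scaling (both the rate and the median scale together).
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    widths = gmap.ends - gmap.starts
    if bg_window_bp < np.min(widths):
        raise ValueError(
            f"bg_window_bp={bg_window_bp} is below the map's resolution "
            f"(finest interval width {np.min(widths)} bp)"
        )
    mids = (gmap.starts + gmap.ends) / 2.0
    hot = np.zeros(len(mids), dtype=bool)
    for i, m in enumerate(mids):
        lo = np.searchsorted(gmap.ends, m - bg_window_bp, side="right")
        hi = np.searchsorted(gmap.starts, m + bg_window_bp, side="left")
        hi = max(hi, lo + 1)
        bg = _weighted_median(gmap.rates[lo:hi], widths[lo:hi].astype(float))
        hot[i] = bg > 0 and gmap.rates[i] >= fold * bg
    calls = []
    i = 0
    n = len(hot)
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            s, e = int(gmap.starts[i]), int(gmap.ends[j])
            if e - s >= min_width_bp:
                calls.append((s, e))
            i = j + 1
        else:
            i += 1
    return np.asarray(calls, dtype=np.int64).reshape(-1, 2)


def _reciprocal_overlap(a: np.ndarray, b: np.ndarray) -> float:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0])) if ov else 0.0


def hotspot_concordance(calls_a: np.ndarray, calls_b: np.ndarray, min_reciprocal: float = 0.5) -> dict:
    """Two-map hotspot concordance: shared = reciprocal overlap >= ``min_reciprocal``."""
    shared_a = sum(any(_reciprocal_overlap(a, b) >= min_reciprocal for b in calls_b) for a in calls_a)
    shared_b = sum(any(_reciprocal_overlap(b, a) >= min_reciprocal for a in calls_a) for b in calls_b)
    return {
        "n_a": int(len(calls_a)),
        "n_b": int(len(calls_b)),
        "shared_a": int(shared_a),
        "shared_b": int(shared_b),
        "fraction_a_shared": shared_a / len(calls_a) if len(calls_a) else float("nan"),
        "fraction_b_shared": shared_b / len(calls_b) if len(calls_b) else float("nan"),
    }
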