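"""IBD segment tables: dialect I/O, gap merging, ancestry assignment, partitioning.

This is the core of ancestry-specific IBD analysis: detected (or truth) IBD
segments are fused across small gaps, each segment is assigned the ancestry
carried by *both* haplotypes over most of its length, and segments are
partitioned by ancestry for per-ancestry effective-population-size inference.

Segment tables are pandas DataFrames with columns ``sample_a, hap_a,
sample_b, hap_b, chrom, start, end, score, length_cm`` (plus ``ancestry``
once assigned); the haplotype pair is stored in canonical order.  The text
dialect is whitespace-separated ``id1 hap1 id2 hap2 chrom start end score
length_cm`` with 1-based haplotype indices (0-based in memory).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .maps import RecombinationMap
from .tracts import TractSet

__all__ = [
    "read_ibd",
    "write_ibd",
    "merge_ibd_gaps",
    "assign_ibd_ancestry",
    "partition_by_ancestry",
    "effective_pair_count",
]

UNASSIGNED = "unassigned"
SEG_COLUMNS = ["sample_a", "hap_a", "sample_b", "hap_b", "chrom", "start", "end", "score", "length_cm"]


class IBDFormatError(ValueError):
    pass


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Store each haplotype pair with (sample_a, hap_a) <= (sample_b, hap_b)."""
    df = df.copy()
    swap = (df["sample_a"].astype(str) > df["sample_b"].astype(str)) | (
        (df["sample_a"].astype(str) == df["sample_b"].astype(str)) & (df["hap_a"] > df["hap_b"])
    )
    for a, b in (("sample_a", "sample_b"), ("hap_a", "hap_b")):
        df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df.sort_values(["sample_a", "hap_a", "sample_b", "hap_b", "chrom", "start"]).reset_index(
        drop=True
    )


def read_ibd(path, gmap: RecombinationMap | None = None) -> pd.DataFrame:
    """Read an IBD dialect file; ``length_cm`` is recomputed from ``gmap``
    when one is supplied, otherwise the file's value is kept."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 9:
                raise IBDFormatError(f"line {lineno}: expected 9 fields, got {len(parts)}")
            try:
                rec = (
                    parts[0], int(parts[1]) - 1, parts[2], int(parts[3]) - 1, parts[4],
                    int(parts[5]), int(parts[6]), float(parts[7]), float(parts[8]),
                )
            except ValueError as exc:
                raise IBDFormatError(f"line {lineno}: {exc}") from None
            if rec[5] >= rec[6]:
                raise IBDFormatError(f"line {lineno}: start >= end")
            if rec[1] not in (0, 1) or rec[3] not in (0, 1):
                raise IBDFormatError(f"line {lineno}: haplotype index must be 1 or 2")
            rows.append(rec)
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    if gmap is not None and len(df):
        df["length_cm"] = gmap.interp_cm(df["end"].to_numpy(), clamp=True) - gmap.interp_cm(
            df["start"].to_numpy(), clamp=True
        )
    return canonicalize(df)


def write_ibd(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in df.itertuples(index=False):
            score = getattr(r, "score", np.nan)
            fh.write(
                f"{r.sample_a}\t{r.hap_a + 1}\t{r.sample_b}\t{r.hap_b + 1}\t{r.chrom}\t"
                f"{r.start}\t{r.end}\t{0.0 if pd.isna(score) else score:.6g}\t{r.length_cm:.6f}\n"
            )


def merge_ibd_gaps(
    segments: pd.DataFrame,
    gmap: RecombinationMap,
    max_gap_cm: float = 0.6,
    max_gap_bp: float = np.inf,
) -> pd.DataFrame:
    """Fuse consecutive same-pair segments whose gap is within *both*
    thresholds; genetic lengths are recomputed from the map.  Idempotent and
    never decreases total covered length."""
    if max_gap_cm < 0 or max_gap_bp < 0:
        raise ValueError("gap thresholds must be >= 0")
    if segments.empty:
        return segments.copy()
    segments = canonicalize(segments)
    out = []
    for _, g in segments.groupby(["sample_a", "hap_a", "sample_b", "hap_b", "chrom"], sort=False):
        g = g.sort_values("start")
        cur = None
        for r in g.itertuples(index=False):
            if cur is None:
                cur = r._asdict()
                continue
            gap_bp = r.start - cur["end"]
            gap_cm = gmap.cm_between(min(cur["end"], r.start), max(cur["end"], r.start))
            if gap_bp <= max_gap_bp and gap_cm <= max_gap_cm:
                cur["end"] = max(cur["end"], r.end)
                cur["score"] = min(cur["score"], r.score)
            else:
                out.append(cur)
                cur = r._asdict()
        out.append(cur)
    df = pd.DataFrame(out)
    df["length_cm"] = gmap.interp_cm(df["end"].to_numpy(), clamp=True) - gmap.interp_cm(
        df["start"].to_numpy(), clamp=True
    )
    keep = [c for c in segments.columns if c in df.columns]
    return canonicalize(df[keep])


def assign_ibd_ancestry(
    segments: pd.DataFrame, tracts: TractSet, min_fraction: float = 0.9
) -> pd.DataFrame:
    """Label each IBD segment with the ancestry both haplotypes carry.

    For every ancestry, the *dual coverage* is the length of the segment over
    which BOTH haplotypes carry that ancestry.  The segment is labelled with
    the ancestry whose dual-coverage fraction is at least ``min_fraction`` and
    strictly exceeds every other ancestry's; otherwise (including ties) it is
    labelled ``"unassigned"``.  Dual-coverage fractions sum to <= 1 across
    ancestries because the dual-label regions are disjoint.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    known = set(tracts.haplotypes())
    labels = []
    fractions = []
    part_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def partition(sample, hap, chrom):
        key = (sample, hap, chrom)
        if key not in part_cache:
            if (sample, int(hap)) not in known:
                raise KeyError(f"haplotype ({sample}, {hap}) missing from tract set")
            part_cache[key] = tracts.partition(sample, hap, chrom)
        return part_cache[key]

    for r in segments.itertuples(index=False):
        ea, la = partition(r.sample_a, r.hap_a, r.chrom)
        eb, lb = partition(r.sample_b, r.hap_b, r.chrom)
        edges = np.union1d(ea, eb)
        edges = edges[(edges >= r.start) & (edges <= r.end)]
        edges = np.unique(np.concatenate([[r.start], edges, [r.end]]))
        ia = np.clip(np.searchsorted(ea, edges[:-1], side="right") - 1, 0, len(la) - 1)
        ib = np.clip(np.searchsorted(eb, edges[:-1], side="right") - 1, 0, len(lb) - 1)
        widths = np.diff(edges).astype(float)
        seg_len = float(r.end - r.start)
        dual: dict[str, float] = {}
        same = la[ia] == lb[ib]
        for w, lab in zip(widths[same], la[ia][same]):
            dual[lab] = dual.get(lab, 0.0) + w
        frac = {a: v / seg_len for a, v in dual.items()}
        fractions.append(frac)
        if frac:
            best = max(frac, key=frac.get)
            tied = sum(1 for v in frac.values() if v == frac[best]) > 1
            labels.append(UNASSIGNED if tied or frac[best] < min_fraction else best)
        else:
            labels.append(UNASSIGNED)
    out = segments.copy()
    out["ancestry"] = labels
    out.attrs["dual_fractions"] = fractions
    return out


def partition_by_ancestry(segments: pd.DataFrame, min_cm: float = 3.0) -> dict[str, pd.DataFrame]:
    """Group labelled segments by ancestry, dropping ``unassigned`` and
    segments shorter than ``min_cm`` (default 3 cM, the conventional lower
    bound for reliable IBD detection)."""
    if "ancestry" not in segments.columns:
        raise ValueError("segments carry no ancestry labels; run assign_ibd_ancestry first")
    kept = segments[(segments["ancestry"] != UNASSIGNED) & (segments["length_cm"] >= min_cm)]
    return {str(a): g.reset_index(drop=True) for a, g in kept.groupby("ancestry", sort=True)}


def effective_pair_count(tracts: TractSet, ancestry: str) -> float:
    """Effective number of haplotype pairs for one ancestry.

    C(H, 2) scaled by the mean (over pairs) fraction of the genome where both
    haplotypes carry the ancestry -- computed exactly from the per-position
    carrier count c(x) as sum over x of c(x)(c(x)-1)/2 divided by genome
    length.  This is the pair count that makes a per-ancestry IBD length
    spectrum comparable with the expectation for fully covered pairs.
    """
    total = 0.0
    genome = 0.0
    haps = tracts.haplotypes()
    for chrom, length in tracts.chrom_lengths.items():
        genome += length
        sub = tracts.df[(tracts.df["chrom"] == chrom) & (tracts.df["ancestry"] == ancestry)]
        if sub.empty:
            continue
        events = np.concatenate(
            [
                np.stack([sub["start"].to_numpy(), np.ones(len(sub))], axis=1),
                np.stack([sub["end"].to_numpy(), -np.ones(len(sub))], axis=1),
            ]
        )
        events = events[np.argsort(events[:, 0], kind="stable")]
        pos = np.unique(events[:, 0])
        counts = np.zeros(len(pos))
        np.add.at(counts, np.searchsorted(pos, events[:, 0]), events[:, 1])
        c = np.cumsum(counts)
        widths = np.diff(np.concatenate([pos, [length]]))
        total += float(np.sum(c * (c - 1) / 2.0 * widths))
    _ = haps
    return total / genome
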