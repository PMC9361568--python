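"""Integrated haplotype score (iHS) scan parameterized by a genetic map.

EHH (extended haplotype homozygosity) at distance d from a core site is the
probability that two random carriers of the core allele are identical over
all sites between the core and d:  EHH = sum_h C(n_h, 2) / C(n, 2) over the
distinct extended haplotypes h among the n carriers.  iHH integrates the EHH
curve over genetic distance (trapezoids, truncated where EHH crosses the
cutoff) in both directions; iHS is the log-ratio ln(iHH_ancestral /
iHH_derived), standardized within derived-allele-frequency bins.

Because EHH curves depend only on the haplotypes, a scan under several
genetic maps (``scan_with_maps``) computes every curve once and re-integrates
it per map — the machinery behind map-sensitivity comparisons of top-scoring
candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import RecombinationMap

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "HaplotypeMatrix",
    "ehh",
    "integrate_ehh",
    "ihs_scores",
    "scan_with_maps",
    "standardize_ihs",
    "top_hits",
    "read_gene_ranges",
    "annotate_genes",
    "compare_runs",
]


@dataclass
class HaplotypeMatrix:
    """Phased biallelic haplotypes with known ancestral/derived polarity.

    ``alleles`` is sites x haplotypes in {0, 1}, 1 = derived; positions are
    strictly increasing bp.
    """

    positions: np.ndarray
    alleles: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.alleles.shape[0] != len(self.positions):
            raise ValueError("alleles/positions mismatch")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be biallelic 0/1")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=1)

    @property
    def monomorphic(self) -> np.ndarray:
        f = self.derived_freq
        return (f == 0.0) | (f == 1.0)

    @classmethod
    def from_cohort(cls, cohort) -> "HaplotypeMatrix":
        if cohort.haplotypes is None:
            raise ValueError("cohort carries no allele matrix")
        return cls(positions=cohort.site_positions, alleles=cohort.haplotypes, chrom=cohort.chrom)

    @classmethod
    def read_tsv(cls, path) -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        chrom = str(df["chrom"].iloc[0])
        return cls(
            positions=df["pos"].to_numpy(np.int64),
            alleles=df.drop(columns=["chrom", "pos"]).to_numpy(np.uint8),
            chrom=chrom,
        )

    @classmethod
    def read_vcf(cls, path) -> "HaplotypeMatrix":
        from cyvcf2 import VCF

        positions, rows = [], []
        chrom = "1"
        for v in VCF(str(path)):
            chrom = v.CHROM
            gts = np.asarray(v.genotypes)[:, :2].reshape(-1)
            positions.append(v.POS - 1)  # back to 0-based
            rows.append(gts)
        return cls(
            positions=np.asarray(positions, dtype=np.int64),
            alleles=np.asarray(rows, dtype=np.uint8),
            chrom=chrom,
        )


# --------------------------------------------------------------- EHH kernels


def _walk_py(alleles, mono, core, carriers, step, cutoff):
    m = len(carriers)
    ids = np.zeros(m, dtype=np.int64)
    idx_out, ehh_out = [], []
    denom = m * (m - 1) / 2.0
    j = core + step
    n_sites = alleles.shape[0]
    while 0 <= j < n_sites:
        if not mono[j]:
            ids = ids * 2 + alleles[j, carriers]
            _, ids = np.unique(ids, return_inverse=True)
            counts = np.bincount(ids)
            cur = float(np.sum(counts * (counts - 1) / 2.0) / denom)
            idx_out.append(j)
            ehh_out.append(cur)
            if cur < cutoff:
                break
        j += step
    return np.asarray(idx_out, dtype=np.int64), np.asarray(ehh_out)


if _HAVE_NUMBA:

    @njit(cache=False)
    def _walk_nb(alleles, mono, core, carriers, step, cutoff):  # pragma: no cover - jit
        m = carriers.size
        n_sites = alleles.shape[0]
        ids = np.zeros(m, np.int64)
        idx_out = np.empty(n_sites, np.int64)
        ehh_out = np.empty(n_sites, np.float64)
        cnt = 0
        denom = m * (m - 1) / 2.0
        j = core + step
        while 0 <= j < n_sites:
            if not mono[j]:
                for i in range(m):
                    ids[i] = ids[i] * 2 + alleles[j, carriers[i]]
                order = np.argsort(ids)
                new = np.empty(m, np.int64)
                rank = 0
                prev = ids[order[0]]
                new[order[0]] = 0
                for t in range(1, m):
                    v = ids[order[t]]
                    if v != prev:
                        rank += 1
                        prev = v
                    new[order[t]] = rank
                for i in range(m):
                    ids[i] = new[i]
                counts = np.zeros(rank + 1, np.int64)
                for i in range(m):
                    counts[ids[i]] += 1
                num = 0.0
                for c in counts:
                    num += c * (c - 1) / 2.0
                cur = num / denom
                idx_out[cnt] = j
                ehh_out[cnt] = cur
                cnt += 1
                if cur < cutoff:
                    break
            j += step
        return idx_out[:cnt], ehh_out[:cnt]

    _walk = _walk_nb
else:
    _walk = _walk_py


def ehh(
    hapmat: HaplotypeMatrix,
    core_site: int,
    carrier_class: str = "derived",
    direction: str = "right",
    cutoff: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH curve from a core site in one direction.

    Returns (site indices, EHH values) starting at the core (EHH = 1) and
    extending until EHH drops below ``cutoff`` or the data end.  Sites
    monomorphic in the full sample are skipped (they cannot split
    haplotypes).  Raises if the class has < 2 carriers.
    """
    if carrier_class not in {"derived", "ancestral"}:
        raise ValueError("carrier_class must be 'derived' or 'ancestral'")
    want = 1 if carrier_class == "derived" else 0
    carriers = np.flatnonzero(hapmat.alleles[core_site] == want).astype(np.int64)
    if len(carriers) < 2:
        raise ValueError(f"core site {core_site} has < 2 {carrier_class} carriers")
    step = 1 if direction == "right" else -1
    idx, vals = _walk(hapmat.alleles, hapmat.monomorphic, core_site, carriers, step, cutoff)
    return (
        np.concatenate([[core_site], idx]),
        np.concatenate([[1.0], vals]),
    )


# -------------------------------------------------------------- integration


def integrate_ehh(
    positions_bp: np.ndarray,
    ehh_values: np.ndarray,
    gmap: RecombinationMap,
    cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
    scale_gap_bp: float = 20_000,
) -> tuple[float | None, str | None]:
    """Trapezoidal integral of an EHH curve over genetic distance (cM x EHH).

    Truncated (linear interpolation on the genetic axis) where the curve
    crosses ``cutoff``.  Physical gaps larger than ``max_gap_bp`` censor the
    curve (returns (None, reason)); gaps above ``scale_gap_bp`` have their
    genetic width scaled by ``scale_gap_bp / gap``.
    """
    pos = np.asarray(positions_bp, dtype=float)
    e = np.asarray(ehh_values, dtype=float)
    if len(pos) < 2:
        return 0.0, None
    gaps = np.abs(np.diff(pos))
    w = np.abs(np.diff(gmap.interp_cm(pos, clamp=True)))
    w = np.where(gaps > scale_gap_bp, w * scale_gap_bp / np.maximum(gaps, 1.0), w)
    crossings = np.flatnonzero((e[:-1] >= cutoff) & (e[1:] < cutoff))
    if len(crossings):
        k = int(crossings[0])  # trapezoids 0..k-1 are full; k is partial
        if np.any(gaps[: k + 1] > max_gap_bp):
            bad = int(np.max(gaps[: k + 1]))
            return None, f"gap {bad} bp > {max_gap_bp:g}"
        total = float(np.sum((e[:k] + e[1 : k + 1]) / 2.0 * w[:k]))
        t = (e[k] - cutoff) / (e[k] - e[k + 1])
        total += (e[k] + cutoff) / 2.0 * w[k] * t
        return total, None
    if np.any(gaps > max_gap_bp):
        return None, f"gap {int(np.max(gaps))} bp > {max_gap_bp:g}"
    return float(np.sum((e[:-1] + e[1:]) / 2.0 * w)), None


# ------------------------------------------------------------------ the scan


def _site_curves(hapmat: HaplotypeMatrix, core: int, cutoff: float):
    """Four EHH curves (class x direction) in physical coordinates."""
    curves = {}
    for cls in ("derived", "ancestral"):
        for direction in ("left", "right"):
            idx, vals = ehh(hapmat, core, cls, direction, cutoff)
            curves[(cls, direction)] = (hapmat.positions[idx], vals)
    return curves


def _qualifying_sites(hapmat: HaplotypeMatrix, maf_min: float) -> np.ndarray:
    f = hapmat.derived_freq
    maf = np.minimum(f, 1 - f)
    n = hapmat.n_haplotypes
    cnt = (f * n).round()
    return np.flatnonzero((maf >= maf_min) & (cnt >= 2) & (n - cnt >= 2))


def scan_with_maps(
    hapmat: HaplotypeMatrix,
    maps: dict[str, RecombinationMap],
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
    scale_gap_bp: float = 20_000,
) -> dict[str, pd.DataFrame]:
    """Unstandardized iHS tables for the same haplotypes under several maps.

    EHH curves are computed once per core site and integrated under every
    map (curves depend only on the haplotypes; only iHH sees the map).
    """
    cores = _qualifying_sites(hapmat, maf_min)
    f = hapmat.derived_freq
    records: dict[str, list] = {name: [] for name in maps}
    for core in cores:
        curves = _site_curves(hapmat, int(core), cutoff)
        for name, gmap in maps.items():
            vals = {}
            flag = None
            for cls in ("derived", "ancestral"):
                tot = 0.0
                for direction in ("left", "right"):
                    pos, eh = curves[(cls, direction)]
                    v, why = integrate_ehh(pos, eh, gmap, cutoff, max_gap_bp, scale_gap_bp)
                    if v is None:
                        flag = why
                        break
                    tot += v
                if flag:
                    break
                vals[cls] = tot
            if flag is None and (vals["derived"] <= 0 or vals["ancestral"] <= 0):
                flag = "zero iHH"
            records[name].append(
                (
                    int(hapmat.positions[core]),
                    float(f[core]),
                    vals.get("derived", np.nan),
                    vals.get("ancestral", np.nan),
                    np.log(vals["ancestral"] / vals["derived"]) if flag is None else np.nan,
                    flag or "",
                )
            )
    cols = ["pos", "derived_freq", "ihh_derived", "ihh_ancestral", "ihs_unstd", "flag"]
    return {name: pd.DataFrame(rows, columns=cols) for name, rows in records.items()}


def ihs_scores(
    hapmat: HaplotypeMatrix,
    gmap: RecombinationMap,
    maf_min: float = 0.05,
    cutoff: float = 0.05,
    max_gap_bp: float = 200_000,
    scale_gap_bp: float = 20_000,
) -> pd.DataFrame:
    """Per-site unstandardized iHS: ln(iHH_ancestral / iHH_derived)."""
    return scan_with_maps(hapmat, {"map": gmap}, maf_min, cutoff, max_gap_bp, scale_gap_bp)["map"]


def standardize_ihs(table: pd.DataFrame, n_freq_bins: int = 20) -> pd.DataFrame:
    """Standardize iHS within derived-frequency bins (equal width over [0,1]).

    Bins with fewer than 2 scored sites are merged with their nearest occupied
    neighbor.  Adds an ``ihs_std`` column (NaN for flagged sites).
    """
    table = table.copy()
    scored = table["ihs_unstd"].notna()
    if scored.sum() < 2:
        raise ValueError("need at least 2 scored sites to standardize")
    f = table.loc[scored, "derived_freq"].to_numpy()
    raw_bin = np.minimum((f * n_freq_bins).astype(int), n_freq_bins - 1)
    # merge undersized bins with the nearest occupied neighbor
    merged = raw_bin.astype(float)
    bins, counts = np.unique(raw_bin, return_counts=True)
    mapping = {int(b): int(b) for b in bins}
    for b, c in zip(bins, counts):
        if c < 2:
            others = [x for x in bins if x != b and np.sum(merged == mapping[int(x)]) >= 2]
            if not others:
                others = [x for x in bins if x != b]
            if not others:
                raise ValueError("cannot standardize: all sites fall in one undersized bin")
            tgt = min(others, key=lambda x: abs(int(x) - int(b)))
            merged[merged == b] = mapping[int(tgt)]
            mapping[int(b)] = mapping[int(tgt)]
    z = np.empty(len(f))
    for b in np.unique(merged):
        sel = merged == b
        mu = f_std = None
        vals = table.loc[scored, "ihs_unstd"].to_numpy()[sel]
        mu = vals.mean()
        f_std = vals.std(ddof=0)
        if f_std == 0:
            if len(np.unique(merged)) == 1:
                raise ValueError("cannot standardize: single bin with zero variance")
            f_std = 1.0  # degenerate sub-bin: centre only
        z[sel] = (vals - mu) / f_std
    table["ihs_std"] = np.nan
    table.loc[scored, "ihs_std"] = z
    return table


def top_hits(table: pd.DataFrame, fraction: float = 0.01) -> pd.DataFrame:
    """Sites in the top ``fraction`` of |iHS| (ties at the threshold included)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scored = table[table["ihs_std"].notna()]
    if scored.empty:
        raise ValueError("no scored sites")
    mag = scored["ihs_std"].abs().to_numpy()
    if fraction == 1.0:
        return scored.copy()
    thr = np.quantile(mag, 1 - fraction, method="higher")
    return scored[scored["ihs_std"].abs() >= thr].copy()


# --------------------------------------------------------------------- genes


def read_gene_ranges(path) -> pd.DataFrame:
    """Gene range list: whitespace columns chrom, start, end, symbol."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected 4 columns (chrom start end symbol)")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])


def annotate_genes(
    sites: np.ndarray, gene_ranges: pd.DataFrame, chrom: str | None = None, flank_bp: int = 0
) -> set[str]:
    """Deduplicated symbols of genes whose (optionally flanked) range contains
    at least one hit site."""
    sites = np.sort(np.asarray(sites, dtype=np.int64))
    ranges = gene_ranges if chrom is None else gene_ranges[gene_ranges["chrom"].astype(str) == str(chrom)]
    out = set()
    starts = ranges["start"].to_numpy() - flank_bp
    ends = ranges["end"].to_numpy() + flank_bp
    for s, e, sym in zip(starts, ends, ranges["symbol"]):
        i = np.searchsorted(sites, s, side="left")
        if i < len(sites) and sites[i] < e:
            out.add(sym)
    return out


def compare_runs(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    gene_ranges: pd.DataFrame,
    fraction: float = 0.01,
    chrom: str | None = None,
    flank_bp: int = 0,
) -> dict:
    """Map-sensitivity report for two standardized iHS tables.

    Restricts both tables to their shared scored sites, takes top-|iHS| hits
    per table, annotates genes, and reports the candidate-gene Venn counts
    plus the per-SNP Pearson correlation of standardized scores.
    """
    a = table_a[table_a["ihs_std"].notna()]
    b = table_b[table_b["ihs_std"].notna()]
    shared = np.intersect1d(a["pos"].to_numpy(), b["pos"].to_numpy())
    if len(shared) == 0:
        raise ValueError("tables share no scored sites")
    a = a[a["pos"].isin(shared)].sort_values("pos").reset_index(drop=True)
    b = b[b["pos"].isin(shared)].sort_values("pos").reset_index(drop=True)
    genes_a = annotate_genes(top_hits(a, fraction)["pos"].to_numpy(), gene_ranges, chrom, flank_bp)
    genes_b = annotate_genes(top_hits(b, fraction)["pos"].to_numpy(), gene_ranges, chrom, flank_bp)
    inter = genes_a & genes_b
    union = genes_a | genes_b
    r = float(np.corrcoef(a["ihs_std"], b["ihs_std"])[0, 1])
    return {
        "n_shared_sites": int(len(shared)),
        "genes_a": sorted(genes_a),
        "genes_b": sorted(genes_b),
        "n_shared_genes": len(inter),
        "n_unique_a": len(genes_a - genes_b),
        "n_unique_b": len(genes_b - genes_a),
        "overlap_fraction": (len(inter) / len(union)) if union else float("nan"),
        "pearson_r": r,
    }
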