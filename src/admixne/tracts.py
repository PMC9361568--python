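"""Local-ancestry tract tables: dialects, proportions, and accuracy scoring.

Tracts are stored 0-based half-open.  For every (sample, haplotype,
chromosome) the tract intervals must sort, not overlap, and tile the declared
chromosome extent exactly.  Accuracy against a truth set is computed by
interval intersection (length-weighted over bp), never per-site loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TractSet", "AccuracyReport", "read_local_ancestry", "global_proportions", "lai_accuracy"]

TRACT_COLUMNS = ["sample", "hap", "chrom", "start", "end", "ancestry"]


class TractFormatError(ValueError):
    pass


@dataclass
class TractSet:
    """Per-haplotype local-ancestry intervals over chromosomes."""

    df: pd.DataFrame  # columns sample, hap, chrom, start, end, ancestry
    alphabet: list[str]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        missing = [c for c in TRACT_COLUMNS if c not in self.df.columns]
        if missing:
            raise TractFormatError(f"missing tract columns: {missing}")
        unknown = set(self.df["ancestry"]) - set(self.alphabet)
        if unknown:
            raise TractFormatError(f"ancestry labels outside alphabet: {sorted(unknown)}")
        if not self.chrom_lengths:
            self.chrom_lengths = {
                str(c): int(g["end"].max()) for c, g in self.df.groupby("chrom")
            }
        self.validate()

    def validate(self) -> None:
        """Check the tiling invariant for every haplotype."""
        for (sample, hap, chrom), g in self.df.groupby(["sample", "hap", "chrom"], sort=False):
            g = g.sort_values("start")
            length = self.chrom_lengths[str(chrom)]
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            ok = (
                starts[0] == 0
                and ends[-1] == length
                and np.all(starts[1:] == ends[:-1])
                and np.all(ends > starts)
            )
            if not ok:
                raise TractFormatError(
                    f"tracts for ({sample}, hap {hap}, chrom {chrom}) do not tile [0, {length})"
                )

    # ----------------------------------------------------------------- access
    def haplotypes(self) -> list[tuple[str, int]]:
        return sorted({(s, int(h)) for s, h in zip(self.df["sample"], self.df["hap"])})

    def partition(self, sample: str, hap: int, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(edges, labels) of the tiling partition for one haplotype."""
        g = self.df[
            (self.df["sample"] == sample) & (self.df["hap"] == hap) & (self.df["chrom"] == chrom)
        ].sort_values("start")
        if g.empty:
            raise KeyError(f"no tracts for ({sample}, hap {hap}, chrom {chrom})")
        edges = np.concatenate([g["start"].to_numpy(np.int64), [np.int64(g["end"].iloc[-1])]])
        return edges, g["ancestry"].to_numpy(dtype=object)

    def labels_at(self, sample: str, hap: int, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Label of each elementary interval [edges[i], edges[i+1])."""
        own_edges, labels = self.partition(sample, hap, chrom)
        idx = np.searchsorted(own_edges, edges[:-1], side="right") - 1
        return labels[np.clip(idx, 0, len(labels) - 1)]

    # -------------------------------------------------------------------- I/O
    def write_tsv(self, path) -> None:
        self.df[TRACT_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, alphabet: list[str] | None = None) -> "TractSet":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
        if alphabet is None:
            alphabet = sorted(df["ancestry"].unique())
        return cls(df=df, alphabet=list(alphabet))

    def write_msp(self, path, site_positions: np.ndarray | None = None, gmap=None) -> None:
        """Write the RFMix-v2 msp.tsv dialect.

        Windows are the elementary intervals of the union of all tract
        breakpoints.  Genetic positions come from ``gmap`` when given,
        otherwise bp * 1e-6 is used as a 1 cM/Mb placeholder.
        """
        code = {a: i for i, a in enumerate(self.alphabet)}
        haps = self.haplotypes()
        with open(path, "w") as fh:
            fh.write(
                "#Subpopulation order/codes: "
                + "\t".join(f"{a}={i}" for a, i in code.items())
                + "\n"
            )
            fh.write(
                "#chm\tspos\tepos\tsgpos\tegpos\tn snps\t"
                + "\t".join(f"{s}.{h}" for s, h in haps)
                + "\n"
            )
            for chrom in sorted(self.df["chrom"].unique()):
                sub = self.df[self.df["chrom"] == chrom]
                edges = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
                labels = {
                    (s, h): self.labels_at(s, h, chrom, edges) for s, h in haps
                }
                for i in range(len(edges) - 1):
                    s_bp, e_bp = int(edges[i]), int(edges[i + 1])
                    if gmap is not None:
                        sg, eg = gmap.interp_cm(s_bp, clamp=True), gmap.interp_cm(e_bp, clamp=True)
                    else:
                        sg, eg = s_bp * 1e-6, e_bp * 1e-6
                    if site_positions is not None:
                        nsnp = int(
                            np.searchsorted(site_positions, e_bp)
                            - np.searchsorted(site_positions, s_bp)
                        )
                    else:
                        nsnp = 0
                    row = [str(chrom), str(s_bp), str(e_bp), f"{sg:.6f}", f"{eg:.6f}", str(nsnp)]
                    row += [str(code[labels[(s, h)][i]]) for s, h in haps]
                    fh.write("\t".join(row) + "\n")


def read_local_ancestry(path) -> TractSet:
    """Read an msp.tsv file, merging consecutive equal-label windows into tracts."""
    with open(path) as fh:
        header1 = fh.readline().rstrip("\n")
        header2 = fh.readline().rstrip("\n")
        if not header1.startswith("#Subpopulation"):
            raise TractFormatError("line 1: expected '#Subpopulation order/codes:' header")
        codes: dict[int, str] = {}
        for tok in header1.split(":", 1)[1].replace(",", "\t").split():
            name, _, num = tok.partition("=")
            if not num.isdigit():
                raise TractFormatError(f"line 1: malformed code {tok!r}")
            codes[int(num)] = name
        cols = header2.lstrip("#").split("\t")
        hap_cols = cols[6:]
        haps = []
        for c in hap_cols:
            sample, _, h = c.rpartition(".")
            if h not in {"0", "1"}:
                raise TractFormatError(f"line 2: haplotype column {c!r} must end in .0/.1")
            haps.append((sample, int(h)))
        rows = []
        prev_epos: dict[str, int] = {}
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + len(hap_cols):
                raise TractFormatError(f"line {lineno}: expected {6 + len(hap_cols)} fields")
            chrom, spos, epos = parts[0], int(parts[1]), int(parts[2])
            if spos >= epos:
                raise TractFormatError(f"line {lineno}: empty window")
            if chrom in prev_epos and spos != prev_epos[chrom]:
                raise TractFormatError(f"line {lineno}: windows do not tile (gap/overlap at {spos})")
            prev_epos[chrom] = epos
            for (sample, h), tok in zip(haps, parts[6:]):
                c = int(tok)
                if c not in codes:
                    raise TractFormatError(f"line {lineno}: unknown ancestry code {c}")
                rows.append((sample, h, chrom, spos, epos, codes[c]))
    alphabet = [codes[k] for k in sorted(codes)]
    if not rows:
        return TractSet(
            df=pd.DataFrame(columns=TRACT_COLUMNS),
            alphabet=alphabet,
            chrom_lengths={"0": 0},
        )
    df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    return TractSet(df=_merge_adjacent(df), alphabet=alphabet)


def _merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Fuse consecutive tracts with identical labels per haplotype."""
    out = []
    for (sample, hap, chrom), g in df.groupby(["sample", "hap", "chrom"], sort=False):
        g = g.sort_values("start")
        cur = None
        for r in g.itertuples(index=False):
            if cur is not None and r.ancestry == cur[5] and r.start == cur[4]:
                cur[4] = r.end
            else:
                if cur is not None:
                    out.append(tuple(cur))
                cur = [sample, hap, chrom, r.start, r.end, r.ancestry]
        out.append(tuple(cur))
    return pd.DataFrame(out, columns=TRACT_COLUMNS)


# --------------------------------------------------------------------- scoring


@dataclass
class AccuracyReport:
    """Length-weighted agreement between inferred and truth tracts."""

    global_accuracy: float
    mean_individual_accuracy: float
    per_ancestry_recall: dict[str, float]
    per_individual_fractions: pd.DataFrame  # sample x ancestry, from the inferred tracts


def global_proportions(tracts: TractSet) -> pd.DataFrame:
    """Per-individual ancestry fractions (tract length over both haplotypes)."""
    df = tracts.df.copy()
    df["len"] = df["end"] - df["start"]
    table = df.pivot_table(index="sample", columns="ancestry", values="len", aggfunc="sum", fill_value=0.0)
    table = table.reindex(columns=tracts.alphabet, fill_value=0.0)
    return table.div(table.sum(axis=1), axis=0)


def lai_accuracy(truth: TractSet, inferred: TractSet) -> AccuracyReport:
    """Score inferred tracts against truth by interval intersection.

    global accuracy = total length where labels agree / total length;
    per-ancestry recall = agreeing length within truth tracts of that ancestry
    / total truth length of that ancestry.  Haplotypes are compared as phased.
    """
    th, ih = truth.haplotypes(), inferred.haplotypes()
    if th != ih:
        only_t = set(th) - set(ih)
        only_i = set(ih) - set(th)
        raise ValueError(f"sample/haplotype sets differ; truth-only={sorted(only_t)}, inferred-only={sorted(only_i)}")
    agree_total = 0.0
    total = 0.0
    recall_num: dict[str, float] = {a: 0.0 for a in truth.alphabet}
    recall_den: dict[str, float] = {a: 0.0 for a in truth.alphabet}
    per_ind_agree: dict[str, float] = {}
    per_ind_total: dict[str, float] = {}
    chroms = sorted(truth.df["chrom"].unique())
    for sample, hap in th:
        for chrom in chroms:
            e_t, l_t = truth.partition(sample, hap, chrom)
            e_i, l_i = inferred.partition(sample, hap, chrom)
            if e_t[0] != e_i[0] or e_t[-1] != e_i[-1]:
                raise ValueError(f"chromosome extents differ for ({sample}, {hap}, {chrom})")
            edges = np.union1d(e_t, e_i)
            widths = np.diff(edges).astype(float)
            lt = truth.labels_at(sample, hap, chrom, edges)
            li = inferred.labels_at(sample, hap, chrom, edges)
            agree = lt == li
            agree_len = float(widths[agree].sum())
            agree_total += agree_len
            total += float(widths.sum())
            per_ind_agree[sample] = per_ind_agree.get(sample, 0.0) + agree_len
            per_ind_total[sample] = per_ind_total.get(sample, 0.0) + float(widths.sum())
            for a in truth.alphabet:
                in_a = lt == a
                recall_den[a] += float(widths[in_a].sum())
                recall_num[a] += float(widths[in_a & agree].sum())
    recall = {
        a: (recall_num[a] / recall_den[a]) if recall_den[a] > 0 else float("nan")
        for a in truth.alphabet
    }
    mean_ind = float(np.mean([per_ind_agree[s] / per_ind_total[s] for s in per_ind_agree]))
    return AccuracyReport(
        global_accuracy=agree_total / total,
        mean_individual_accuracy=mean_ind,
        per_ancestry_recall=recall,
        per_individual_fractions=global_proportions(inferred),
    )
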