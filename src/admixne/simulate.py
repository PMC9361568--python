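"""Forward-time admixture simulation with truth ancestry tracts and truth IBD.

The simulator models a single chromosome per run.  A founder panel supplies
phased biallelic haplotypes for each source ancestry (Balding-Nichols
differentiated).  The admixed population random-mates for ``n_generations``;
each generation, a parent slot is filled by a migrant drawn from a source
panel (with the per-generation fraction of an active gene-flow event) or by a
resident of the previous generation.  Gametes are crossover mosaics: the
crossover count is Poisson in the map length (Morgans, no interference) and
positions are drawn uniformly on the genetic (cM) axis.

Every copied block keeps its founder-haplotype identity, so the cohort carries
exact truth ancestry tracts and a founder-block pedigree from which true IBD
segments (shared founder descent) can be extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import RecombinationMap
from .tracts import TRACT_COLUMNS, TractSet

__all__ = [
    "GeneticMapSpec",
    "GeneFlowSchedule",
    "FounderPanel",
    "Cohort",
    "synth_map",
    "derive_sibling_map",
    "generate_founders",
    "sample_crossovers",
    "simulate_admixture",
    "simulate_admixture_genome",
    "extract_true_ibd",
    "corrupt_tracts",
    "generate_gene_ranges",
    "three_way_schedule",
]

IBD_COLUMNS = [
    "sample_a", "hap_a", "sample_b", "hap_b", "chrom",
    "start", "end", "length_cm", "founder_id",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ----------------------------------------------------------------- map synthesis


@dataclass
class GeneticMapSpec:
    """Parameters of a hotspot-punctuated recombination map."""

    chrom_length_bp: int
    background_rate: float = 1e-8  # per-bp per-generation
    hotspot_rate: float = 1.0  # expected hotspots per Mb
    hotspot_width_bp: int = 2000
    intensity_fold: float = 20.0  # multiplier over background inside a hotspot
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.chrom_length_bp <= 0:
            raise ValueError("chrom_length_bp must be positive")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.hotspot_rate < 0:
            raise ValueError("hotspot_rate must be >= 0")
        if self.intensity_fold < 1:
            raise ValueError("intensity_fold must be >= 1")
        if self.hotspot_width_bp <= 0:
            raise ValueError("hotspot_width_bp must be positive")


def _merge_intervals(spots: np.ndarray) -> np.ndarray:
    if len(spots) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(spots[:, 0], kind="stable")
    merged: list[list[int]] = []
    for a, b in spots[order]:
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(b))
        else:
            merged.append([int(a), int(b)])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _centers_to_spots(centers: np.ndarray, width: int, length: int) -> np.ndarray:
    half = width // 2
    s = np.clip(centers - half, 0, length)
    e = np.clip(centers + (width - half), 0, length)
    return _merge_intervals(np.stack([s, e], axis=1))


def _build_hotspot_map(
    chrom: str, length: int, background: float, fold: float, hotspots: np.ndarray, meta: dict
) -> RecombinationMap:
    edges = [0]
    rates = []
    pos = 0
    for s, e in hotspots:
        if s > pos:
            edges.append(int(s))
            rates.append(background)
        edges.append(int(e))
        rates.append(background * fold)
        pos = int(e)
    if pos < length:
        edges.append(length)
        rates.append(background)
    edges_arr = np.asarray(edges, dtype=np.int64)
    return RecombinationMap(
        chrom=chrom,
        starts=edges_arr[:-1],
        ends=edges_arr[1:],
        rates=np.asarray(rates),
        hotspots=hotspots.copy(),
        meta=meta,
    )


def synth_map(spec: GeneticMapSpec) -> RecombinationMap:
    """Hotspot-punctuated map; hotspot centres are a homogeneous Poisson
    process at ``hotspot_rate`` per Mb, each a ``hotspot_width_bp`` window at
    ``intensity_fold`` times the background rate.  Deterministic given seed."""
    rng = _rng(spec.seed)
    n_hot = rng.poisson(spec.hotspot_rate * spec.chrom_length_bp / 1e6)
    centers = np.sort(rng.integers(0, spec.chrom_length_bp, size=n_hot))
    hotspots = _centers_to_spots(centers, spec.hotspot_width_bp, spec.chrom_length_bp)
    meta = {
        "background_rate": spec.background_rate,
        "intensity_fold": spec.intensity_fold,
        "hotspot_width_bp": spec.hotspot_width_bp,
    }
    return _build_hotspot_map(
        spec.chrom, spec.chrom_length_bp, spec.background_rate, spec.intensity_fold, hotspots, meta
    )


def derive_sibling_map(gmap: RecombinationMap, shared_fraction: float, seed) -> RecombinationMap:
    """A second map sharing each hotspot of the input with probability
    ``shared_fraction``; dropped hotspots are replaced by new private ones so
    the hotspot count is preserved.  Background is unchanged.

    Keep decisions and replacement positions are coupled to per-hotspot
    uniform draws, so sibling maps at increasing ``shared_fraction`` (same
    seed) form a nested family: raising the fraction only converts private
    hotspots back into shared ones.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    if gmap.hotspots is None:
        raise ValueError("input map carries no hotspot annotation")
    meta = gmap.meta
    if "background_rate" not in meta:
        raise ValueError("input map lacks synthesis metadata (background_rate)")
    rng = _rng(seed)
    length = gmap.span[1]
    n = len(gmap.hotspots)
    u = rng.random(n)
    replacement_centers = rng.integers(0, max(length, 1), size=n)
    keep = u < shared_fraction
    width = int(meta["hotspot_width_bp"])
    half = width // 2
    new_centers = replacement_centers[~keep]
    new = np.stack(
        [np.clip(new_centers - half, 0, length), np.clip(new_centers + (width - half), 0, length)],
        axis=1,
    ).astype(np.int64) if len(new_centers) else np.empty((0, 2), np.int64)
    hotspots = _merge_intervals(np.concatenate([gmap.hotspots[keep], new]))
    return _build_hotspot_map(
        gmap.chrom, length, float(meta["background_rate"]), float(meta["intensity_fold"]),
        hotspots, dict(meta),
    )


# -------------------------------------------------------------------- founders


@dataclass
class FounderPanel:
    """Phased founder haplotypes for each source ancestry at shared sites.

    ``founder_blocks``/``founder_ancestry`` support panels built from the
    output of an earlier simulation (each panel haplotype is itself a mosaic
    of *ultimate* founder haplotypes); for a fresh panel the mapping is the
    identity.
    """

    ancestries: list[str]
    site_positions: np.ndarray  # sorted bp
    alleles: np.ndarray  # n_sites x n_haplotypes, {0, 1}
    hap_ancestry: np.ndarray  # per panel haplotype, ancestry label
    freqs: pd.DataFrame | None = None  # per-site per-ancestry allele frequency
    founder_blocks: list[list[tuple[int, int, int]]] | None = None
    founder_ancestry: np.ndarray | None = None  # ultimate founder id -> label

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.hap_ancestry = np.asarray(self.hap_ancestry, dtype=object)
        if self.alleles.shape[0] != len(self.site_positions):
            raise ValueError("alleles/site_positions mismatch")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1")
        if self.founder_blocks is None:
            self.founder_ancestry = self.hap_ancestry.copy()
        elif self.founder_ancestry is None:
            raise ValueError("founder_blocks requires founder_ancestry")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ancestry)

    def hap_ids(self, ancestry: str) -> np.ndarray:
        ids = np.flatnonzero(self.hap_ancestry == ancestry)
        if len(ids) == 0:
            raise ValueError(f"founder panel has no haplotypes of ancestry {ancestry!r}")
        return ids

    def blocks_of(self, hap_id: int, length: int) -> list[tuple[int, int, int]]:
        """Ultimate-founder blocks of one panel haplotype over [0, length)."""
        if self.founder_blocks is None:
            return [(int(hap_id), 0, int(length))]
        return self.founder_blocks[hap_id]

    @classmethod
    def from_cohorts(cls, cohorts: dict[str, "Cohort"]) -> "FounderPanel":
        """Pedigreed panel from the final generations of earlier runs (one
        ancestry label per source run).  Ultimate founder ids are offset to
        stay globally unique, so true IBD extracted downstream resolves
        through to the original founders of each source run."""
        labels = list(cohorts)
        first = cohorts[labels[0]]
        positions = first.site_positions
        mats, anc, blocks, fanc = [], [], [], []
        offset = 0
        for lab in labels:
            c = cohorts[lab]
            if positions is not None and c.site_positions is not None:
                if len(c.site_positions) != len(positions) or np.any(c.site_positions != positions):
                    raise ValueError("cohorts must share one site list to form a panel")
            if c.haplotypes is not None:
                mats.append(c.haplotypes)
            anc.extend([lab] * c.n_haplotypes)
            for h in range(c.n_haplotypes):
                blocks.append([(f + offset, s, e) for f, s, e in c.blocks[h]])
            fanc.extend([lab] * len(c.founder_ancestry))
            offset += len(c.founder_ancestry)
        n_sites = len(positions) if positions is not None else 0
        alleles = np.concatenate(mats, axis=1) if mats else np.zeros((n_sites, len(anc)), np.int8)
        return cls(
            ancestries=labels,
            site_positions=positions if positions is not None else np.empty(0, np.int64),
            alleles=alleles,
            hap_ancestry=np.asarray(anc, dtype=object),
            founder_blocks=blocks,
            founder_ancestry=np.asarray(fanc, dtype=object),
        )


def generate_founders(
    n_per_pop: int,
    n_sites: int,
    fst: float,
    length_bp: int,
    seed,
    ancestries: tuple[str, ...] = ("SAN", "EUR", "BNT"),
) -> FounderPanel:
    """Balding-Nichols differentiated founder panel.

    Ancestral frequency p ~ U(0.05, 0.95) per site; each ancestry's frequency
    is Beta(p(1-F)/F, (1-p)(1-F)/F) with F the divergence parameter; alleles
    are sampled independently per haplotype.  Positions are uniform, sorted
    and deduplicated (topped up if collisions occur).
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    if n_sites > length_bp:
        raise ValueError(f"cannot place {n_sites} distinct sites on {length_bp} bp")
    rng = _rng(seed)
    positions = np.unique(rng.integers(0, length_bp, size=n_sites))
    while len(positions) < n_sites:
        extra = rng.integers(0, length_bp, size=n_sites - len(positions))
        positions = np.unique(np.concatenate([positions, extra]))
    p = rng.uniform(0.05, 0.95, size=n_sites)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    freqs = {}
    mats = []
    anc: list[str] = []
    for label in ancestries:
        f = rng.beta(a, b)
        freqs[label] = f
        mats.append((rng.random((n_sites, 2 * n_per_pop)) < f[:, None]).astype(np.int8))
        anc.extend([label] * (2 * n_per_pop))
    return FounderPanel(
        ancestries=list(ancestries),
        site_positions=positions,
        alleles=np.concatenate(mats, axis=1),
        hap_ancestry=np.asarray(anc, dtype=object),
        freqs=pd.DataFrame(freqs),
    )


# -------------------------------------------------------------------- schedule


@dataclass
class GeneFlowSchedule:
    """Continuous gene-flow schedule into a random-mating admixed population.

    Each event ``(source, start_generation, per_gen_fraction)`` contributes
    migrant parents with probability ``per_gen_fraction`` per parent slot in
    every mating round from ``start_generation`` generations before present to
    the present.  ``initial_composition`` sets the ancestry mix of the
    starting population (default: all ``base_ancestry``).
    """

    events: list[tuple[str, int, float]] = field(default_factory=list)
    base_ancestry: str = "SAN"
    initial_composition: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for _, start, frac in self.events:
            if start < 1:
                raise ValueError("start_generation must be >= 1")
            if not 0 <= frac <= 1:
                raise ValueError("per_gen_fraction must be in [0, 1]")
        for g in range(1, max((s for _, s, _ in self.events), default=0) + 1):
            if sum(f for _, s, f in self.events if s >= g) > 1:
                raise ValueError(f"per-generation fractions sum to > 1 at generation {g}")
        if self.initial_composition is not None:
            if not np.isclose(sum(self.initial_composition.values()), 1.0):
                raise ValueError("initial_composition must sum to 1")

    def active_fractions(self, gens_before_present: int) -> list[tuple[str, float]]:
        """Migrant fractions for the mating round that creates the cohort
        living ``gens_before_present`` generations before present (an event
        starting g generations ago feeds the rounds creating cohorts
        g-1, ..., 0)."""
        return [(src, frac) for src, start, frac in self.events if start >= gens_before_present + 1]

    def expected_fractions(self, n_generations: int) -> dict[str, float]:
        """Exact expected present-day ancestry fractions under the model,
        by the coupled recursion m_s <- f_s + (1 - sum_s' f_s') m_s."""
        sources = {self.base_ancestry} | {src for src, _, _ in self.events}
        if self.initial_composition:
            sources |= set(self.initial_composition)
            m = {s: self.initial_composition.get(s, 0.0) for s in sources}
        else:
            m = {s: float(s == self.base_ancestry) for s in sources}
        for t in range(n_generations - 1, -1, -1):
            active = self.active_fractions(t)
            resid = 1.0 - sum(f for _, f in active)
            m = {s: resid * v for s, v in m.items()}
            for src, f in active:
                m[src] += f
        return m


def three_way_schedule() -> GeneFlowSchedule:
    """The canonical three-way schedule used across examples and experiments:
    European gene flow at 1% per generation starting 8 generations ago and
    Bantu-speaking (West-African) gene flow at 2% per generation starting 14
    generations ago, into a Khoe-San base population."""
    return GeneFlowSchedule(events=[("EUR", 8, 0.01), ("BNT", 14, 0.02)], base_ancestry="SAN")


# ------------------------------------------------------------------- crossover


def sample_crossovers(gmap: RecombinationMap, seed) -> np.ndarray:
    """Crossover positions for one meiosis: count ~ Poisson(map Morgans),
    positions uniform on the cM axis (no interference), returned sorted (bp)."""
    rng = _rng(seed)
    morgans = gmap.total_morgans
    if morgans <= 0:
        raise ValueError("map must have positive total genetic length")
    n = rng.poisson(morgans)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    u_cm = np.sort(rng.uniform(0.0, gmap.total_cm, size=n))
    pos = np.atleast_1d(gmap.pos_at_cm(u_cm))
    return np.floor(pos).astype(np.int64)


# ----------------------------------------------------------------------- cohort

Block = tuple[int, int, int]  # (haplotype id, start bp, end bp)


def _slice_blocks(blocks: list[Block], s: int, e: int) -> list[Block]:
    out = []
    for f, bs, be in blocks:
        if be <= s:
            continue
        if bs >= e:
            break
        out.append((f, max(bs, s), min(be, e)))
    return out


def _compact(blocks: list[Block]) -> list[Block]:
    out: list[Block] = []
    for f, s, e in blocks:
        if out and out[-1][0] == f and out[-1][2] == s:
            out[-1] = (f, out[-1][1], e)
        else:
            out.append((f, s, e))
    return out


def _gamete(hap0: list[Block], hap1: list[Block], xovers: np.ndarray, length: int, rng) -> list[Block]:
    cur = int(rng.integers(2))
    cuts = [int(x) for x in xovers if 0 < x < length]
    if not cuts:
        return list((hap0, hap1)[cur])
    cuts = [0] + cuts + [length]
    parents = (hap0, hap1)
    out: list[Block] = []
    for i in range(len(cuts) - 1):
        s, e = cuts[i], cuts[i + 1]
        if e > s:
            out.extend(_slice_blocks(parents[cur], s, e))
        cur ^= 1
    return _compact(out)


@dataclass
class Cohort:
    """An admixed cohort with truth tracts and a founder-block pedigree."""

    chrom: str
    chrom_length: int
    gmap: RecombinationMap
    blocks: list[list[Block]]  # per haplotype, ultimate-founder blocks tiling [0, L)
    founder_ancestry: np.ndarray  # ultimate founder id -> ancestry label
    alphabet: list[str]
    n_generations: int
    site_positions: np.ndarray | None = None
    haplotypes: np.ndarray | None = None  # n_sites x n_haplotypes

    @property
    def n_haplotypes(self) -> int:
        return len(self.blocks)

    @property
    def sample_ids(self) -> list[str]:
        return [f"ind{i}" for i in range(self.n_haplotypes // 2)]

    def hap_name(self, h: int) -> tuple[str, int]:
        return f"ind{h // 2}", h % 2

    def truth_tracts(self) -> TractSet:
        rows = []
        for h, blks in enumerate(self.blocks):
            sample, hap = self.hap_name(h)
            cur = None
            for f, s, e in blks:
                lab = self.founder_ancestry[f]
                if cur is not None and cur[5] == lab:
                    cur[4] = e
                else:
                    if cur is not None:
                        rows.append(tuple(cur))
                    cur = [sample, hap, self.chrom, s, e, lab]
            rows.append(tuple(cur))
        df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
        return TractSet(
            df=df, alphabet=list(self.alphabet), chrom_lengths={self.chrom: self.chrom_length}
        )

    def ancestry_fractions(self) -> pd.DataFrame:
        """Per-individual ancestry fractions straight from the pedigree blocks."""
        data = {}
        for h, blks in enumerate(self.blocks):
            sample, _ = self.hap_name(h)
            d = data.setdefault(sample, {a: 0.0 for a in self.alphabet})
            for f, s, e in blks:
                d[self.founder_ancestry[f]] += e - s
        df = pd.DataFrame(data).T.reindex(columns=self.alphabet)
        return df.div(df.sum(axis=1), axis=0)

    def subset(self, n_individuals: int) -> "Cohort":
        """The first ``n_individuals`` diploids as a new cohort (a sample)."""
        h = 2 * n_individuals
        if h > self.n_haplotypes:
            raise ValueError("subset larger than the cohort")
        return Cohort(
            chrom=self.chrom,
            chrom_length=self.chrom_length,
            gmap=self.gmap,
            blocks=[list(b) for b in self.blocks[:h]],
            founder_ancestry=self.founder_ancestry,
            alphabet=list(self.alphabet),
            n_generations=self.n_generations,
            site_positions=self.site_positions,
            haplotypes=self.haplotypes[:, :h] if self.haplotypes is not None else None,
        )

    # ------------------------------------------------------------------- output
    def write_hap_tsv(self, path) -> None:
        """Plain haplotype matrix: rows = sites, columns = haplotypes."""
        if self.haplotypes is None:
            raise ValueError("cohort was simulated without allele materialization")
        cols = [f"{s}.{h}" for s, h in (self.hap_name(i) for i in range(self.n_haplotypes))]
        df = pd.DataFrame(self.haplotypes, columns=cols)
        df.insert(0, "pos", self.site_positions)
        df.insert(0, "chrom", self.chrom)
        df.to_csv(path, sep="\t", index=False)

    def write_vcf(self, path) -> None:
        """Minimal phased VCF (GT fields only)."""
        if self.haplotypes is None:
            raise ValueError("cohort was simulated without allele materialization")
        samples = self.sample_ids
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom},length={self.chrom_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples) + "\n"
            )
            for i, pos in enumerate(self.site_positions):
                gts = "\t".join(
                    f"{self.haplotypes[i, 2 * j]}|{self.haplotypes[i, 2 * j + 1]}"
                    for j in range(len(samples))
                )
                fh.write(f"{self.chrom}\t{pos + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_admixture_genome(
    founders: list[FounderPanel],
    schedule: GeneFlowSchedule,
    gmaps: list[RecombinationMap],
    n_individuals: int,
    n_generations: int,
    seed,
    materialize_alleles: bool = True,
) -> list[Cohort]:
    """Multi-chromosome admixture simulation with one shared pedigree.

    ``founders[i]`` is the panel for chromosome ``gmaps[i]``; panel haplotype
    index j must denote the same founder individual on every chromosome (the
    panels must share the ``hap_ancestry`` layout).  Parent choices are made
    once per offspring and transmission is simulated per chromosome with
    independent crossovers (independent assortment), so relatedness is
    consistent across the genome.  Deterministic given seed.
    """
    if len(founders) != len(gmaps) or not founders:
        raise ValueError("need one founder panel per chromosome map")
    layout = founders[0].hap_ancestry
    for p in founders[1:]:
        if len(p.hap_ancestry) != len(layout) or np.any(p.hap_ancestry != layout):
            raise ValueError("founder panels must share the haplotype-ancestry layout")
    if n_individuals < 2:
        raise ValueError("population size must be >= 2")
    max_start = max((s for _, s, _ in schedule.events), default=0)
    if max_start > n_generations:
        raise ValueError("schedule events start before the simulation begins")
    for src, _, _ in schedule.events:
        founders[0].hap_ids(src)  # raises if the panel cannot serve an active ancestry
    rng = _rng(seed)
    n_chrom = len(gmaps)
    lengths = [int(g.span[1]) for g in gmaps]

    # mating is tracked in panel space: block ids are panel haplotype indices
    comp = schedule.initial_composition or {schedule.base_ancestry: 1.0}
    comp_labels = list(comp)
    comp_probs = np.asarray([comp[k] for k in comp_labels], dtype=float)
    Hap = list[list[Block]]  # one block list per chromosome
    pop: list[Hap] = []
    for _ in range(2 * n_individuals):
        lab = comp_labels[int(rng.choice(len(comp_labels), p=comp_probs))]
        hid = int(rng.choice(founders[0].hap_ids(lab)))
        pop.append([[(hid, 0, lengths[c])] for c in range(n_chrom)])

    def fresh_hap(label: str) -> Hap:
        hid = int(rng.choice(founders[0].hap_ids(label)))
        return [[(hid, 0, lengths[c])] for c in range(n_chrom)]

    for t in range(n_generations - 1, -1, -1):
        active = schedule.active_fractions(t)
        newpop: list[Hap] = []
        for _ in range(n_individuals):
            resident_idx: list[int] = []
            for slot in range(2):
                u = rng.random()
                cum = 0.0
                parent = None
                for src, f in active:
                    cum += f
                    if u < cum:
                        parent = (fresh_hap(src), fresh_hap(src))
                        break
                if parent is None:
                    while True:
                        j = int(rng.integers(n_individuals))
                        if j not in resident_idx:
                            break
                    resident_idx.append(j)
                    parent = (pop[2 * j], pop[2 * j + 1])
                gam: Hap = []
                for c in range(n_chrom):
                    xo = sample_crossovers(gmaps[c], rng)
                    gam.append(_gamete(parent[0][c], parent[1][c], xo, lengths[c], rng))
                newpop.append(gam)
        pop = newpop

    cohorts = []
    for c in range(n_chrom):
        panel = founders[c]
        chrom_pop = [hap[c] for hap in pop]
        haplotypes = None
        if materialize_alleles and panel.alleles.size:
            n_sites = len(panel.site_positions)
            haplotypes = np.empty((n_sites, len(chrom_pop)), dtype=np.int8)
            for h, blks in enumerate(chrom_pop):
                for hid, s, e in blks:
                    i0 = np.searchsorted(panel.site_positions, s, side="left")
                    i1 = np.searchsorted(panel.site_positions, e, side="left")
                    haplotypes[i0:i1, h] = panel.alleles[i0:i1, hid]
        if panel.founder_blocks is None:
            ultimate = chrom_pop
        else:
            ultimate = []
            for blks in chrom_pop:
                out: list[Block] = []
                for hid, s, e in blks:
                    out.extend(_slice_blocks(panel.blocks_of(hid, lengths[c]), s, e))
                ultimate.append(_compact(out))
        cohorts.append(
            Cohort(
                chrom=gmaps[c].chrom,
                chrom_length=lengths[c],
                gmap=gmaps[c],
                blocks=ultimate,
                founder_ancestry=panel.founder_ancestry,
                alphabet=list(dict.fromkeys(list(panel.ancestries))),
                n_generations=n_generations,
                site_positions=panel.site_positions if haplotypes is not None else None,
                haplotypes=haplotypes,
            )
        )
    return cohorts


def simulate_admixture(
    founders: FounderPanel,
    schedule: GeneFlowSchedule,
    gmap: RecombinationMap,
    n_individuals: int,
    n_generations: int,
    seed,
    materialize_alleles: bool = True,
) -> Cohort:
    """Random-mating forward simulation under a continuous gene-flow schedule.

    Migrant parents are fresh diploids drawn (with replacement) from the
    founder panel of the migrating ancestry; resident parents are distinct
    individuals of the previous generation (no selfing).  Each offspring
    haplotype is one gamete of one parent.  Single chromosome per run (see
    :func:`simulate_admixture_genome` for a shared-pedigree genome).
    """
    return simulate_admixture_genome(
        [founders], schedule, [gmap], n_individuals, n_generations, seed, materialize_alleles
    )[0]


# -------------------------------------------------------------------- true IBD


def _pair_shared_runs(ba: list[Block], bb: list[Block]) -> list[tuple[int, int, int]]:
    """Maximal runs where two haplotypes carry the same founder id.

    Contiguous matching runs are merged across founder-id changes (descent
    through a shared ancestor haplotype is continuous at a breakpoint both
    copies inherited); the reported founder id is the one at the run start.
    """
    runs: list[tuple[int, int, int]] = []
    i = j = 0
    cur: list[int] | None = None  # [founder_at_start, start, end]
    while i < len(ba) and j < len(bb):
        fa, sa, ea = ba[i]
        fb, sb, eb = bb[j]
        s = max(sa, sb)
        e = min(ea, eb)
        if e > s and fa == fb:
            if cur is not None and cur[2] == s:
                cur[2] = e
            else:
                if cur is not None:
                    runs.append((cur[0], cur[1], cur[2]))
                cur = [fa, s, e]
        if ea <= eb:
            i += 1
        if eb <= ea:
            j += 1
    if cur is not None:
        runs.append((cur[0], cur[1], cur[2]))
    return runs


def extract_true_ibd(cohort: Cohort, min_cm: float = 0.0) -> pd.DataFrame:
    """True IBD segments: maximal intervals over which a haplotype pair
    descends from the same founder haplotype, with genetic length from the
    cohort's own map; segments shorter than ``min_cm`` are dropped."""
    if min_cm < 0:
        raise ValueError("min_cm must be >= 0")
    gmap = cohort.gmap
    edges_cm = {}
    rows = []
    H = cohort.n_haplotypes
    for a in range(H):
        sa, ha = cohort.hap_name(a)
        for b in range(a + 1, H):
            sb, hb = cohort.hap_name(b)
            for f, s, e in _pair_shared_runs(cohort.blocks[a], cohort.blocks[b]):
                if s not in edges_cm:
                    edges_cm[s] = gmap.interp_cm(s)
                if e not in edges_cm:
                    edges_cm[e] = gmap.interp_cm(e)
                lcm = edges_cm[e] - edges_cm[s]
                if lcm >= min_cm:
                    rows.append((sa, ha, sb, hb, cohort.chrom, s, e, lcm, f))
    df = pd.DataFrame(rows, columns=IBD_COLUMNS)
    return df.sort_values(["sample_a", "hap_a", "sample_b", "hap_b", "start"]).reset_index(drop=True)


# ------------------------------------------------------------- tract corruption


def corrupt_tracts(
    tracts: TractSet, switch_error_per_mb: float, seed, window_bp: int = 500_000
) -> TractSet:
    """Emulate local-ancestry miscalls: windows seeded by a Poisson process at
    ``switch_error_per_mb`` get their labels flipped to a random other label.

    Each event covers ``window_bp`` from its seed position; within the window
    every underlying tract label is shifted by the event's random nonzero
    offset in the ancestry alphabet (so the new label always differs from the
    old one).  The tiling invariant is preserved.
    """
    if switch_error_per_mb < 0:
        raise ValueError("rate must be >= 0")
    k = len(tracts.alphabet)
    if switch_error_per_mb > 0 and k < 2:
        raise ValueError("cannot corrupt tracts over a single-ancestry alphabet")
    if switch_error_per_mb == 0:
        return TractSet(
            df=tracts.df.copy(), alphabet=list(tracts.alphabet),
            chrom_lengths=dict(tracts.chrom_lengths),
        )
    rng = _rng(seed)
    index = {a: i for i, a in enumerate(tracts.alphabet)}
    rows = []
    for sample, hap in tracts.haplotypes():
        for chrom, length in tracts.chrom_lengths.items():
            edges, labels = tracts.partition(sample, hap, chrom)
            n_events = rng.poisson(switch_error_per_mb * length / 1e6)
            starts = np.sort(rng.integers(0, length, size=n_events))
            offsets = rng.integers(1, k, size=n_events)
            cut = set(edges.tolist())
            for s in starts:
                cut.add(int(s))
                cut.add(min(int(s) + window_bp, length))
            all_edges = np.asarray(sorted(cut))
            lab = tracts.labels_at(sample, hap, chrom, all_edges)
            codes = np.asarray([index[x] for x in lab])
            for s, off in zip(starts, offsets):
                e = min(int(s) + window_bp, length)
                i0 = np.searchsorted(all_edges, s)
                i1 = np.searchsorted(all_edges, e)
                codes[i0:i1] = (codes[i0:i1] + off) % k
            cur = None
            for i in range(len(codes)):
                a = tracts.alphabet[codes[i]]
                if cur is not None and cur[5] == a:
                    cur[4] = int(all_edges[i + 1])
                else:
                    if cur is not None:
                        rows.append(tuple(cur))
                    cur = [sample, hap, chrom, int(all_edges[i]), int(all_edges[i + 1]), a]
            rows.append(tuple(cur))
    df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    return TractSet(df=df, alphabet=list(tracts.alphabet), chrom_lengths=dict(tracts.chrom_lengths))


# ------------------------------------------------------------------ gene ranges


def generate_gene_ranges(
    chrom: str, chrom_length: int, n_genes: int, seed, mean_length_bp: int = 60_000
) -> pd.DataFrame:
    """Synthetic gene range list (chrom, start, end, symbol) with
    exponentially distributed gene lengths at random non-identical starts."""
    rng = _rng(seed)
    starts = np.sort(rng.choice(chrom_length, size=n_genes, replace=False))
    lengths = np.maximum(rng.exponential(mean_length_bp, size=n_genes).astype(np.int64), 1000)
    ends = np.minimum(starts + lengths, chrom_length)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "symbol": [f"GENE{i:05d}" for i in range(n_genes)],
        }
    )
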