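"""Desk-scale validation experiments composed from the pipeline stages.

These functions run the whole method on synthetic data at sizes a laptop
handles in minutes: simulator calibration against the closed-form admixture
expectations, Wright-Fisher parameter recovery for the IBD-spectrum N_e
model (single-population and per-ancestry), local-ancestry corruption
scoring, and the dual-map iHS sensitivity experiment.  Both the test suite
and the reproduction script drive the package through this module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ibd, ihs, maps, ne, simulate, tracts

__all__ = [
    "allele_free_panel",
    "uniform_maps",
    "simulator_calibration",
    "wright_fisher_segments",
    "constant_n_recovery",
    "two_ancestry_recovery",
    "lai_corruption_experiment",
    "map_sensitivity_experiment",
]


def allele_free_panel(hap_counts: dict[str, int]) -> simulate.FounderPanel:
    """A founder panel carrying pedigree identity only (no allele matrix);
    enough for demographic experiments that never touch genotypes."""
    anc: list[str] = []
    for label, n in hap_counts.items():
        anc.extend([label] * n)
    return simulate.FounderPanel(
        ancestries=list(hap_counts),
        site_positions=np.empty(0, dtype=np.int64),
        alleles=np.zeros((0, len(anc)), dtype=np.int8),
        hap_ancestry=np.asarray(anc, dtype=object),
    )


def uniform_maps(n_chrom: int, cm_per_chrom: float, rate: float = 1e-8) -> list[maps.RecombinationMap]:
    """One uniform map per chromosome (names "1".."n") at ``rate`` per bp."""
    length = int(round(cm_per_chrom / (rate * 100.0)))
    return [
        maps.RecombinationMap(chrom=str(c + 1), starts=[0], ends=[length], rates=[rate])
        for c in range(n_chrom)
    ]


# ------------------------------------------------------------- calibration


def simulator_calibration(
    schedule: simulate.GeneFlowSchedule | None = None,
    n_individuals: int = 200,
    n_generations: int = 14,
    n_seeds: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort-mean ancestry fractions over replicate seeds vs the exact
    expectations of the gene-flow model (columns: one row per seed)."""
    schedule = schedule or simulate.three_way_schedule()
    labels = sorted(schedule.expected_fractions(n_generations))
    panel = allele_free_panel({lab: 22 for lab in labels})
    gmap = uniform_maps(1, 30.0)[0]
    rows = []
    for i in range(n_seeds):
        cohort = simulate.simulate_admixture(
            panel, schedule, gmap, n_individuals, n_generations,
            seed=seed + i, materialize_alleles=False,
        )
        fr = cohort.ancestry_fractions().mean()
        rows.append([fr.get(lab, 0.0) for lab in labels])
    return pd.DataFrame(rows, columns=labels)


# -------------------------------------------------- Wright-Fisher recovery


def wright_fisher_segments(
    n_diploids: int,
    n_sample: int,
    n_chrom: int,
    cm_per_chrom: float,
    n_generations: int,
    seed: int,
    min_cm: float = 3.0,
) -> tuple[list[pd.DataFrame], list["simulate.Cohort"]]:
    """True IBD (per chromosome) for a sample from a constant-size
    Wright-Fisher population simulated forward with a shared pedigree."""
    panels = [allele_free_panel({"POP": 2 * n_diploids}) for _ in range(n_chrom)]
    gmaps = uniform_maps(n_chrom, cm_per_chrom)
    cohorts = simulate.simulate_admixture_genome(
        panels, simulate.GeneFlowSchedule(base_ancestry="POP"), gmaps,
        n_individuals=n_diploids, n_generations=n_generations,
        seed=seed, materialize_alleles=False,
    )
    samples = [c.subset(n_sample) for c in cohorts]
    segments = [simulate.extract_true_ibd(c, min_cm=min_cm) for c in samples]
    return segments, samples


def constant_n_recovery(
    n_true: int = 200,
    n_sample: int = 100,
    n_chrom: int = 10,
    cm_per_chrom: float = 35.0,
    n_generations: int = 100,
    seed: int = 1,
    grid: np.ndarray | None = None,
    smooth_penalty: float = 0.02,
) -> dict:
    """Fit the IBD-spectrum N_e model to truth IBD from a constant-size
    Wright-Fisher cohort and report the recovery error per generation.

    The fit grid extends down to generation 1 so that coalescences among
    close relatives (always present when the sample is a sizeable fraction
    of a small population) are explained by their own parameters instead of
    distorting the reported recent generations; the simulation runs 100
    generations so that segment production above the grid is negligible at
    the 3 cM threshold."""
    segments, _ = wright_fisher_segments(
        n_true, n_sample, n_chrom, cm_per_chrom, n_generations, seed
    )
    genome_cm = n_chrom * cm_per_chrom
    all_segs = pd.concat(segments, ignore_index=True)
    n_pairs = n_sample * 2 * (n_sample * 2 - 1) / 2
    spectrum = ne.spectrum_from_lengths(
        all_segs["length_cm"].to_numpy(), n_pairs, genome_cm,
        chrom_lengths_cm=np.full(n_chrom, cm_per_chrom),
    )
    if grid is None:
        grid = np.arange(1, 51).astype(float)
    traj = ne.fit_ne(spectrum, grid=grid, smooth_penalty=smooth_penalty)
    rel_err = traj.ne / n_true - 1.0
    return {
        "trajectory": traj,
        "segments": all_segs,
        "per_chrom_segments": segments,
        "n_pairs": n_pairs,
        "genome_cm": genome_cm,
        "rel_err": rel_err,
        "n_true": n_true,
    }


def two_ancestry_recovery(
    n_a: int = 150,
    n_b: int = 450,
    labels: tuple[str, str] = ("SAN", "EUR"),
    n_chrom: int = 8,
    cm_per_chrom: float = 35.0,
    source_generations: int = 100,
    admixed_generations: int = 3,
    n_sample: int = 100,
    seed: int = 1,
    min_fraction: float = 0.9,
    eval_window: tuple[int, int] = (10, 40),
) -> dict:
    """Per-ancestry N_e recovery in an admixed cohort.

    Two constant-size sources evolve separately, then merge into one
    random-mating population of size ``n_a + n_b`` with initial composition
    proportional to the source sizes; for every generation older than the
    short admixed phase each ancestry's coalescence rate is that of its own
    source, so per-ancestry IBD partitions should recover each source's size.
    Reported per ancestry: the geometric mean fitted N over ``eval_window``.
    """
    la, lb = labels
    gmaps = uniform_maps(n_chrom, cm_per_chrom)
    source_cohorts = {}
    for i, (lab, n) in enumerate(((la, n_a), (lb, n_b))):
        panels = [allele_free_panel({lab: 2 * n}) for _ in range(n_chrom)]
        source_cohorts[lab] = simulate.simulate_admixture_genome(
            panels, simulate.GeneFlowSchedule(base_ancestry=lab), gmaps,
            n_individuals=n, n_generations=source_generations,
            seed=seed + i, materialize_alleles=False,
        )
    stage2_panels = [
        simulate.FounderPanel.from_cohorts({la: source_cohorts[la][c], lb: source_cohorts[lb][c]})
        for c in range(n_chrom)
    ]
    n_adm = n_a + n_b
    schedule = simulate.GeneFlowSchedule(
        base_ancestry=la,
        initial_composition={la: n_a / n_adm, lb: n_b / n_adm},
    )
    admixed = simulate.simulate_admixture_genome(
        stage2_panels, schedule, gmaps,
        n_individuals=n_adm, n_generations=admixed_generations,
        seed=seed + 17, materialize_alleles=False,
    )
    samples = [c.subset(n_sample) for c in admixed]
    genome_cm = n_chrom * cm_per_chrom
    seg_list = [simulate.extract_true_ibd(c, min_cm=3.0) for c in samples]

    # label segments with the ancestry both haplotypes carry (truth tracts)
    labelled = []
    pair_counts = {la: [], lb: []}
    for c, segs in zip(samples, seg_list):
        tr = c.truth_tracts()
        labelled.append(ibd.assign_ibd_ancestry(segs.assign(score=0.0), tr, min_fraction=min_fraction))
        for lab in (la, lb):
            pair_counts[lab].append(ibd.effective_pair_count(tr, lab))
    labelled_df = pd.concat(labelled, ignore_index=True)
    parts = ibd.partition_by_ancestry(labelled_df, min_cm=3.0)

    results = {}
    truth = {la: n_a, lb: n_b}
    lo, hi = eval_window
    grid = np.arange(1, 51).astype(float)
    for lab in (la, lb):
        n_pairs = float(np.mean(pair_counts[lab]))
        lengths = parts.get(lab, pd.DataFrame(columns=["length_cm"]))["length_cm"].to_numpy()
        spectrum = ne.spectrum_from_lengths(
            lengths, n_pairs, genome_cm, chrom_lengths_cm=np.full(n_chrom, cm_per_chrom)
        )
        traj = ne.fit_ne(spectrum, grid=grid)
        window = (traj.generations >= lo) & (traj.generations <= hi)
        n_hat = float(np.exp(np.mean(np.log(traj.ne[window]))))
        results[lab] = {
            "trajectory": traj,
            "n_hat": n_hat,
            "n_true": truth[lab],
            "rel_err": n_hat / truth[lab] - 1.0,
            "n_segments": int(len(lengths)),
            "n_pairs": n_pairs,
        }
    return results


# -------------------------------------------------------------- LAI scoring


def lai_corruption_experiment(
    switch_error_per_mb: float = 0.2,
    n_individuals: int = 60,
    n_generations: int = 14,
    chrom_cm: float = 50.0,
    seed: int = 0,
) -> dict:
    """Corrupt truth tracts at a given switch-error rate and score them."""
    schedule = simulate.three_way_schedule()
    panel = allele_free_panel({lab: 22 for lab in ("SAN", "EUR", "BNT")})
    gmap = uniform_maps(1, chrom_cm)[0]
    cohort = simulate.simulate_admixture(
        panel, schedule, gmap, n_individuals, n_generations,
        seed=seed, materialize_alleles=False,
    )
    truth = cohort.truth_tracts()
    noisy = simulate.corrupt_tracts(truth, switch_error_per_mb, seed + 1)
    report = tracts.lai_accuracy(truth, noisy)
    return {"truth": truth, "inferred": noisy, "report": report}


# ------------------------------------------------------- map sensitivity


def map_sensitivity_experiment(
    shared_fractions: tuple[float, ...] = (0.2, 0.5, 0.8, 1.0),
    chrom_length_bp: int = 40_000_000,
    n_sites: int = 4000,
    n_individuals: int = 64,
    n_generations: int = 14,
    n_genes: int = 800,
    fraction: float = 0.01,
    seed: int = 0,
) -> dict:
    """iHS scans of one simulated cohort under a nested family of sibling maps.

    All scans reuse the same EHH curves; only the iHH integration sees each
    map.  For every sibling map the report carries the top-|iHS| candidate
    gene overlap with the base-map scan and the per-SNP Pearson correlation.

    The base map concentrates roughly half its genetic length in hotspots
    (0.5 cM/Mb background, 1.5 hotspots/Mb at 400x over 2 kb), the regime in
    which fine-scale map differences can actually move haplotype-length
    integrals; a map with weak hotspots makes all siblings near-identical.
    """
    base = simulate.synth_map(
        simulate.GeneticMapSpec(
            chrom_length_bp=chrom_length_bp, background_rate=0.5e-8,
            hotspot_rate=1.5, hotspot_width_bp=2000, intensity_fold=400.0, seed=seed,
        )
    )
    siblings = {p: simulate.derive_sibling_map(base, p, seed + 1) for p in shared_fractions}
    founders = simulate.generate_founders(11, n_sites, 0.15, chrom_length_bp, seed + 2)
    cohort = simulate.simulate_admixture(
        founders, simulate.three_way_schedule(), base, n_individuals, n_generations, seed + 3
    )
    hapmat = ihs.HaplotypeMatrix.from_cohort(cohort)
    all_maps = {"base": base, **{f"sib{p}": m for p, m in siblings.items()}}
    raw = ihs.scan_with_maps(hapmat, all_maps)
    tables = {k: ihs.standardize_ihs(v) for k, v in raw.items()}
    genes = simulate.generate_gene_ranges(base.chrom, chrom_length_bp, n_genes, seed + 4)
    reports = {}
    for p in shared_fractions:
        reports[p] = ihs.compare_runs(
            tables["base"], tables[f"sib{p}"], genes, fraction=fraction, chrom=base.chrom
        )
    return {"tables": tables, "reports": reports, "maps": all_maps, "genes": genes}
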