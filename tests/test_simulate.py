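"""Forward simulator: maps, founders, crossovers, admixture, truth IBD, corruption."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixne import ibd, maps, simulate, tracts
from admixne.simulate import GeneFlowSchedule, GeneticMapSpec


class TestSynthMap:
    def test_no_hotspots_gives_uniform_closed_form(self):
        spec = GeneticMapSpec(chrom_length_bp=1_000_000, background_rate=1e-8, hotspot_rate=0.0, seed=1)
        m = simulate.synth_map(spec)
        assert m.total_cm == pytest.approx(1.0)  # 1e6 * 1e-8 * 100

    def test_fold_one_is_uniform_regardless_of_hotspots(self):
        spec = GeneticMapSpec(
            chrom_length_bp=5_000_000, background_rate=1e-8, hotspot_rate=2.0,
            intensity_fold=1.0, seed=3,
        )
        m = simulate.synth_map(spec)
        np.testing.assert_allclose(m.rates, 1e-8)
        assert m.total_cm == pytest.approx(5.0)

    def test_hotspot_count_follows_poisson_law(self):
        """10 Mb at 1 hotspot/Mb: mean count over 200 seeds inside the 99% band."""
        counts = []
        for seed in range(200):
            spec = GeneticMapSpec(chrom_length_bp=10_000_000, hotspot_rate=1.0, seed=seed)
            counts.append(len(simulate.synth_map(spec).hotspots))
        mean = np.mean(counts)
        # mean of 200 Poisson(10) draws: sd = sqrt(10/200)
        half = 2.576 * np.sqrt(10 / 200)
        assert 10 - half <= mean <= 10 + half

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GeneticMapSpec(chrom_length_bp=0)
        with pytest.raises(ValueError):
            GeneticMapSpec(chrom_length_bp=100, background_rate=-1e-9)
        with pytest.raises(ValueError):
            GeneticMapSpec(chrom_length_bp=100, intensity_fold=0.5)

    def test_determinism(self):
        spec = GeneticMapSpec(chrom_length_bp=10_000_000, hotspot_rate=1.0, seed=11)
        a, b = simulate.synth_map(spec), simulate.synth_map(spec)
        np.testing.assert_array_equal(a.hotspots, b.hotspots)
        np.testing.assert_array_equal(a.rates, b.rates)


class TestSiblingMap:
    def test_full_sharing_preserves_hotspots(self, hotspot_map):
        sib = simulate.derive_sibling_map(hotspot_map, 1.0, seed=5)
        np.testing.assert_array_equal(sib.hotspots, hotspot_map.hotspots)

    def test_zero_sharing_has_no_common_hotspot(self, hotspot_map):
        sib = simulate.derive_sibling_map(hotspot_map, 0.0, seed=5)
        orig = {tuple(h) for h in hotspot_map.hotspots}
        assert orig.isdisjoint({tuple(h) for h in sib.hotspots})
        assert len(sib.hotspots) == len(hotspot_map.hotspots)

    def test_shared_count_within_binomial_interval(self):
        spec = GeneticMapSpec(chrom_length_bp=200_000_000, hotspot_rate=1.0, seed=2)
        m = simulate.synth_map(spec)
        n = len(m.hotspots)
        assert n > 150
        sib = simulate.derive_sibling_map(m, 0.5, seed=8)
        shared = len({tuple(h) for h in m.hotspots} & {tuple(h) for h in sib.hotspots})
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= shared <= hi

    def test_nested_family_under_common_seed(self, hotspot_map):
        """Raising shared_fraction only converts private hotspots to shared."""
        orig = {tuple(h) for h in hotspot_map.hotspots}
        prev_shared: set = set()
        for p in (0.2, 0.5, 0.8, 1.0):
            sib = simulate.derive_sibling_map(hotspot_map, p, seed=4)
            shared = orig & {tuple(h) for h in sib.hotspots}
            assert prev_shared <= shared
            prev_shared = shared

    def test_unannotated_map_rejected(self, uniform_map):
        with pytest.raises(ValueError, match="hotspot"):
            simulate.derive_sibling_map(uniform_map, 0.5, seed=1)


class TestFounders:
    def test_same_seed_identical_panel(self):
        a = simulate.generate_founders(5, 200, 0.2, 1_000_000, seed=3)
        b = simulate.generate_founders(5, 200, 0.2, 1_000_000, seed=3)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        np.testing.assert_array_equal(a.site_positions, b.site_positions)

    def test_low_fst_limit_frequencies_converge(self):
        panel = simulate.generate_founders(5, 3000, 1e-6, 10_000_000, seed=1)
        diffs = (panel.freqs["SAN"] - panel.freqs["EUR"]).abs().mean()
        assert diffs < 0.01

    def test_hudson_fst_near_nominal(self):
        """Hudson estimator over generated per-ancestry frequencies ~ 0.2."""
        panel = simulate.generate_founders(50, 2000, 0.2, 50_000_000, seed=7)
        p1 = panel.alleles[:, panel.hap_ids("SAN")].mean(axis=1)
        p2 = panel.alleles[:, panel.hap_ids("EUR")].mean(axis=1)
        n1 = n2 = len(panel.hap_ids("SAN"))
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num.sum() / den.sum()
        assert 0.15 <= fst <= 0.25

    def test_too_many_sites_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_founders(2, 1000, 0.1, 500, seed=0)


class TestCrossovers:
    def test_mean_count_matches_map_morgans(self, uniform_map):
        rng = np.random.default_rng(0)
        n = [len(simulate.sample_crossovers(uniform_map, rng)) for _ in range(10_000)]
        # 0.1 Morgans; 3 SE band
        se = np.sqrt(0.1 / 10_000)
        assert abs(np.mean(n) - 0.1) <= 3 * se

    def test_all_rate_in_hotspot_confines_positions(self):
        m = maps.RecombinationMap(
            "1", [0, 400_000, 402_000], [400_000, 402_000, 1_000_000], [0.0, 1e-4, 0.0]
        )
        rng = np.random.default_rng(1)
        pos = np.concatenate([simulate.sample_crossovers(m, rng) for _ in range(200)])
        assert len(pos) > 0
        assert np.all((pos >= 400_000) & (pos <= 402_000))

    def test_rate_ratio_splits_binomially(self):
        # two segments with 9:1 genetic length
        m = maps.RecombinationMap("1", [0, 500_000], [500_000, 1_000_000], [9e-8, 1e-8])
        rng = np.random.default_rng(2)
        pos = np.concatenate([simulate.sample_crossovers(m, rng) for _ in range(30_000)])
        frac = np.mean(pos < 500_000)
        n = len(pos)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.9) / n
        assert lo <= frac <= hi


class TestSchedule:
    def test_fractions_must_stay_below_one(self):
        with pytest.raises(ValueError):
            GeneFlowSchedule(events=[("A", 5, 0.6), ("B", 5, 0.5)])

    def test_expected_fraction_recursion_single_event(self):
        s = GeneFlowSchedule(events=[("EUR", 8, 0.01)], base_ancestry="SAN")
        m = s.expected_fractions(14)
        assert m["EUR"] == pytest.approx(1 - 0.99**8)
        assert m["SAN"] == pytest.approx(0.99**8)


class TestAdmixture:
    def test_no_events_all_base_ancestry(self, uniform_map):
        panel = simulate.generate_founders(4, 50, 0.1, 10_000_000, seed=1)
        c = simulate.simulate_admixture(
            panel, GeneFlowSchedule(base_ancestry="SAN"), uniform_map, 10, 5, seed=2
        )
        assert set(c.truth_tracts().df["ancestry"]) == {"SAN"}

    def test_single_full_migrant_event(self, uniform_map):
        panel = simulate.generate_founders(4, 50, 0.1, 10_000_000, seed=1)
        sched = GeneFlowSchedule(events=[("EUR", 1, 1.0)], base_ancestry="SAN")
        c = simulate.simulate_admixture(panel, sched, uniform_map, 10, 1, seed=2)
        assert set(c.truth_tracts().df["ancestry"]) == {"EUR"}

    def test_single_event_european_fraction_matches_closed_form(self, uniform_map):
        """European-only 1%/gen for 8 generations: mean fraction ~ 1 - 0.99^8."""
        panel = simulate.generate_founders(11, 50, 0.15, 10_000_000, seed=1)
        sched = GeneFlowSchedule(events=[("EUR", 8, 0.01)], base_ancestry="SAN")
        fractions = []
        for seed in range(12):
            c = simulate.simulate_admixture(panel, sched, uniform_map, 150, 8, seed=seed,
                                            materialize_alleles=False)
            fractions.append(c.ancestry_fractions()["EUR"].mean())
        mean, se = np.mean(fractions), np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean - (1 - 0.99**8)) <= 2.576 * se

    def test_tract_tiling_and_fraction_conservation(self, small_cohort):
        t = small_cohort.truth_tracts()
        t.validate()  # tiling invariant
        fr = small_cohort.ancestry_fractions()
        np.testing.assert_allclose(fr.sum(axis=1), 1.0)

    def test_determinism_bit_identical(self, uniform_map):
        panel = simulate.generate_founders(5, 100, 0.15, 10_000_000, seed=1)
        sched = simulate.three_way_schedule()
        a = simulate.simulate_admixture(panel, sched, uniform_map, 20, 14, seed=9)
        b = simulate.simulate_admixture(panel, sched, uniform_map, 20, 14, seed=9)
        assert a.blocks == b.blocks
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_population_too_small_rejected(self, uniform_map):
        panel = simulate.generate_founders(2, 10, 0.1, 10_000_000, seed=1)
        with pytest.raises(ValueError):
            simulate.simulate_admixture(panel, GeneFlowSchedule(base_ancestry="SAN"),
                                        uniform_map, 1, 2, seed=0)

    def test_missing_source_panel_rejected(self, uniform_map):
        panel = simulate.generate_founders(2, 10, 0.1, 10_000_000, seed=1, ancestries=("SAN",))
        sched = GeneFlowSchedule(events=[("EUR", 2, 0.5)], base_ancestry="SAN")
        with pytest.raises(ValueError, match="EUR"):
            simulate.simulate_admixture(panel, sched, uniform_map, 5, 3, seed=0)


def brute_force_true_ibd(cohort, min_cm=0.0):
    """Independent oracle: per-founder interval intersection + contiguity merge."""
    rows = []
    H = cohort.n_haplotypes
    for a in range(H):
        for b in range(a + 1, H):
            per_f = []
            founders_a = {}
            for f, s, e in cohort.blocks[a]:
                founders_a.setdefault(f, []).append((s, e))
            for f, s, e in cohort.blocks[b]:
                for (s2, e2) in founders_a.get(f, []):
                    lo, hi = max(s, s2), min(e, e2)
                    if hi > lo:
                        per_f.append((lo, hi, f))
            per_f.sort()
            merged = []
            for lo, hi, f in per_f:
                if merged and merged[-1][1] == lo:
                    merged[-1][1] = hi
                else:
                    merged.append([lo, hi, f])
            for lo, hi, f in merged:
                lcm = cohort.gmap.cm_between(lo, hi)
                if lcm >= min_cm:
                    sa, ha = cohort.hap_name(a)
                    sb, hb = cohort.hap_name(b)
                    rows.append((sa, ha, sb, hb, cohort.chrom, lo, hi, lcm, f))
    df = pd.DataFrame(rows, columns=simulate.IBD_COLUMNS)
    return df.sort_values(["sample_a", "hap_a", "sample_b", "hap_b", "start"]).reset_index(drop=True)


class TestTrueIBD:
    def test_copies_of_same_founder_span_chromosome(self, uniform_map):
        c = simulate.Cohort(
            chrom="1", chrom_length=10_000_000, gmap=uniform_map,
            blocks=[[(0, 0, 10_000_000)], [(0, 0, 10_000_000)]],
            founder_ancestry=np.asarray(["A"], dtype=object), alphabet=["A"],
            n_generations=0,
        )
        segs = simulate.extract_true_ibd(c)
        assert len(segs) == 1
        assert segs.loc[0, "start"] == 0 and segs.loc[0, "end"] == 10_000_000

    def test_disjoint_founder_sets_no_ibd(self, uniform_map):
        c = simulate.Cohort(
            chrom="1", chrom_length=10_000_000, gmap=uniform_map,
            blocks=[[(0, 0, 10_000_000)], [(1, 0, 10_000_000)]],
            founder_ancestry=np.asarray(["A", "A"], dtype=object), alphabet=["A"],
            n_generations=0,
        )
        assert simulate.extract_true_ibd(c).empty

    def test_negative_min_cm_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            simulate.extract_true_ibd(small_cohort, min_cm=-1)

    def test_matches_brute_force_oracle_on_random_cohorts(self, uniform_map):
        panel = simulate.generate_founders(3, 20, 0.2, 10_000_000, seed=0)
        for seed in range(8):
            c = simulate.simulate_admixture(
                panel, simulate.three_way_schedule(), uniform_map, 10, 14, seed=seed,
                materialize_alleles=False,
            )
            got = simulate.extract_true_ibd(c, min_cm=0.0)
            want = brute_force_true_ibd(c, min_cm=0.0)
            pd.testing.assert_frame_equal(got, want)


class TestCorruptTracts:
    def test_rate_zero_is_identity(self, small_cohort):
        t = small_cohort.truth_tracts()
        out = simulate.corrupt_tracts(t, 0.0, seed=1)
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_single_ancestry_alphabet_rejected(self, uniform_map):
        df = pd.DataFrame(
            [("s0", 0, "1", 0, 10_000_000, "A"), ("s0", 1, "1", 0, 10_000_000, "A")],
            columns=tracts.TRACT_COLUMNS,
        )
        t = tracts.TractSet(df=df, alphabet=["A"])
        with pytest.raises(ValueError):
            simulate.corrupt_tracts(t, 1.0, seed=0)

    def test_high_rate_limit_accuracy_near_one_over_k(self, small_cohort):
        t = small_cohort.truth_tracts()
        noisy = simulate.corrupt_tracts(t, 50.0, seed=3, window_bp=1_000_000)
        rep = tracts.lai_accuracy(t, noisy)
        assert abs(rep.global_accuracy - 1 / 3) < 0.08

    def test_tiling_preserved(self, small_cohort):
        t = small_cohort.truth_tracts()
        noisy = simulate.corrupt_tracts(t, 1.0, seed=5)
        noisy.validate()

    def test_error_matches_per_base_count_on_realization(self, uniform_map):
        """Global error equals direct per-base counting on the realized windows."""
        df = pd.DataFrame(
            [("s0", 0, "1", 0, 10_000_000, "A")], columns=tracts.TRACT_COLUMNS
        )
        t = tracts.TractSet(df=df, alphabet=["A", "B", "C"])
        noisy = simulate.corrupt_tracts(t, 1.0, seed=7, window_bp=500_000)
        rep_len = 10_000_000
        base = np.zeros(rep_len // 1000, dtype=object)  # 1-kb resolution is exact here
        base[:] = "A"
        got = np.zeros_like(base)
        for r in noisy.df.itertuples(index=False):
            got[r.start // 1000 : r.end // 1000] = r.ancestry
        per_base_acc = np.mean(got == base)
        rep = tracts.lai_accuracy(t, noisy)
        assert rep.global_accuracy == pytest.approx(per_base_acc, abs=1e-3)
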