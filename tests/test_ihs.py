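"""EHH / iHH / iHS scan and the two-map comparison machinery."""

import numpy as np
import pandas as pd
import pytest

from admixne import ihs, maps, simulate
from admixne.ihs import HaplotypeMatrix


def matrix(rows, positions=None):
    A = np.asarray(rows, dtype=np.uint8)
    pos = positions if positions is not None else (np.arange(A.shape[0]) + 1) * 1000
    return HaplotypeMatrix(np.asarray(pos), A)


@pytest.fixture(scope="module")
def cm_map():
    return maps.RecombinationMap("1", [0], [100_000_000], [1e-8])


# ------------------------------------------------------------ brute force


def brute_force_ehh(A, core, cls, direction, cutoff=0.05):
    """String-enumeration oracle."""
    want = 1 if cls == "derived" else 0
    carriers = [h for h in range(A.shape[1]) if A[core, h] == want]
    n = len(carriers)
    out_idx, out_val = [core], [1.0]
    span = []
    order = range(core + 1, A.shape[0]) if direction == "right" else range(core - 1, -1, -1)
    for j in order:
        f = A[j].mean()
        if f in (0.0, 1.0):
            continue
        span.append(j)
        groups = {}
        for h in carriers:
            key = "".join(str(A[k, h]) for k in sorted(span))
            groups[key] = groups.get(key, 0) + 1
        val = sum(c * (c - 1) / 2 for c in groups.values()) / (n * (n - 1) / 2)
        out_idx.append(j)
        out_val.append(val)
        if val < cutoff:
            break
    return np.asarray(out_idx), np.asarray(out_val)


def brute_force_ihs_table(A, pos, gmap, maf_min=0.05, cutoff=0.05):
    rows = []
    hm = HaplotypeMatrix(pos, A)
    for core in range(A.shape[0]):
        f = A[core].mean()
        if min(f, 1 - f) < maf_min or (A[core] == 1).sum() < 2 or (A[core] == 0).sum() < 2:
            rows.append((pos[core], f, np.nan))
            continue
        vals = {}
        ok = True
        for cls in ("derived", "ancestral"):
            tot = 0.0
            for d in ("left", "right"):
                idx, e = brute_force_ehh(A, core, cls, d, cutoff)
                v, why = ihs.integrate_ehh(pos[idx], e, gmap, cutoff)
                if v is None:
                    ok = False
                    break
                tot += v
            vals[cls] = tot
        if not ok or vals["derived"] <= 0 or vals["ancestral"] <= 0:
            rows.append((pos[core], f, np.nan))
        else:
            rows.append((pos[core], f, np.log(vals["ancestral"] / vals["derived"])))
    return pd.DataFrame(rows, columns=["pos", "derived_freq", "ihs_unstd"])


class TestEhh:
    def test_identical_carriers_stay_at_one(self, cm_map):
        A = np.zeros((10, 6), dtype=np.uint8)
        A[5, :3] = 1  # derived carriers identical everywhere else
        A[2, 3:] = 1  # keep some other site polymorphic
        hm = matrix(A)
        idx, vals = ihs.ehh(hm, 5, "derived", "right")
        assert np.all(vals == 1.0)

    def test_two_two_split_gives_third(self):
        # 4 derived carriers split 2/2 at the first informative flanking site
        A = np.array([
            [1, 1, 1, 1, 0, 0],
            [1, 1, 0, 0, 1, 0],
        ], dtype=np.uint8).T  # shape sites x haps -> transpose builds haps rows
        A = np.array([
            [1, 1, 1, 1, 0, 0],  # core: carriers 0-3
            [1, 1, 0, 0, 1, 0],  # splits carriers 2/2
        ], dtype=np.uint8)
        hm = matrix(A)
        idx, vals = ihs.ehh(hm, 0, "derived", "right")
        assert vals[1] == pytest.approx((1 + 1) / 6)

    def test_two_carriers_differing_hit_zero(self):
        A = np.array([
            [1, 1, 0, 0],
            [1, 0, 1, 0],
        ], dtype=np.uint8)
        hm = matrix(A)
        idx, vals = ihs.ehh(hm, 0, "derived", "right")
        assert vals[-1] == 0.0

    def test_fewer_than_two_carriers_rejected(self):
        A = np.array([[1, 0, 0, 0], [0, 1, 1, 0]], dtype=np.uint8)
        with pytest.raises(ValueError, match="carriers"):
            ihs.ehh(matrix(A), 0, "derived", "right")

    def test_monotone_nonincreasing(self, small_cohort):
        hm = HaplotypeMatrix.from_cohort(small_cohort)
        cores = ihs._qualifying_sites(hm, 0.05)[:20]
        for core in cores:
            for cls in ("derived", "ancestral"):
                for d in ("left", "right"):
                    _, vals = ihs.ehh(hm, int(core), cls, d)
                    assert np.all(np.diff(vals) <= 1e-12)

    def test_pure_python_fallback_matches_kernel(self):
        """The numpy fallback walker and the jit kernel are interchangeable."""
        rng = np.random.default_rng(12)
        A = np.ascontiguousarray((rng.random((60, 14)) < 0.5).astype(np.uint8))
        hm = matrix(A)
        mono = hm.monomorphic
        for core in ihs._qualifying_sites(hm, 0.05)[:10]:
            carriers = np.flatnonzero(A[core] == 1).astype(np.int64)
            if len(carriers) < 2:
                continue
            for step in (1, -1):
                i_py, v_py = ihs._walk_py(A, mono, int(core), carriers, step, 0.05)
                i_k, v_k = ihs._walk(A, mono, int(core), carriers, step, 0.05)
                np.testing.assert_array_equal(i_py, i_k)
                np.testing.assert_allclose(v_py, v_k)

    def test_matches_string_enumeration(self):
        rng = np.random.default_rng(8)
        A = (rng.random((40, 10)) < 0.4).astype(np.uint8)
        hm = matrix(A)
        for core in range(40):
            f = A[core].mean()
            if min(f, 1 - f) < 0.05 or (A[core] == 1).sum() < 2 or (A[core] == 0).sum() < 2:
                continue
            for cls in ("derived", "ancestral"):
                for d in ("left", "right"):
                    i1, v1 = ihs.ehh(hm, core, cls, d)
                    i2, v2 = brute_force_ehh(A, core, cls, d)
                    np.testing.assert_array_equal(i1, i2)
                    np.testing.assert_allclose(v1, v2)


class TestIntegrate:
    def test_rectangle_of_height_one(self, cm_map):
        # EHH = 1 over 1 cM (1 Mb at 1 cM/Mb), fine spacing, no gaps
        pos = np.arange(0, 1_000_001, 10_000)
        e = np.ones(len(pos))
        v, why = ihs.integrate_ehh(pos, e, cm_map)
        assert why is None
        assert v == pytest.approx(1.0)

    def test_hand_trapezoid_with_cutoff_crossing(self, cm_map):
        pos = np.array([0, 10_000, 20_000, 30_000])
        e = np.array([1.0, 0.5, 0.2, 0.01])
        # full trapezoids to 0.2, then partial to the 0.05 crossing
        w = 0.01  # cM per 10 kb
        t = (0.2 - 0.05) / (0.2 - 0.01)
        want = (1.5 / 2) * w + (0.7 / 2) * w + ((0.2 + 0.05) / 2) * w * t
        v, why = ihs.integrate_ehh(pos, e, cm_map)
        assert v == pytest.approx(want)

    def test_gap_scaling_halves_wide_trapezoid(self, cm_map):
        pos = np.array([0, 40_000])
        e = np.array([1.0, 0.8])
        v, _ = ihs.integrate_ehh(pos, e, cm_map, scale_gap_bp=20_000)
        # genetic width 0.04 cM scaled by 20/40
        assert v == pytest.approx(0.9 * 0.04 * 0.5)

    def test_max_gap_censors(self, cm_map):
        pos = np.array([0, 300_000])
        e = np.array([1.0, 0.8])
        v, why = ihs.integrate_ehh(pos, e, cm_map, max_gap_bp=200_000)
        assert v is None and "gap" in why


class TestScan:
    def test_symmetric_site_scores_zero(self, cm_map):
        # derived and ancestral carrier classes with mirror-image structure
        A = np.array([
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 0],
        ], dtype=np.uint8)
        hm = matrix(A, positions=np.array([1000, 2000, 3000, 4000]))
        tab = ihs.ihs_scores(hm, cm_map, maf_min=0.0)
        row = tab[tab["pos"] == 3000].iloc[0]
        assert row["ihs_unstd"] == pytest.approx(0.0, abs=1e-12)

    def test_polarity_swap_negates_scores(self, cm_map):
        rng = np.random.default_rng(3)
        A = (rng.random((60, 12)) < 0.5).astype(np.uint8)
        pos = np.sort(rng.choice(2_000_000, 60, replace=False))
        t1 = ihs.ihs_scores(HaplotypeMatrix(pos, A), cm_map)
        t2 = ihs.ihs_scores(HaplotypeMatrix(pos, 1 - A), cm_map)
        s1 = t1["ihs_unstd"].to_numpy()
        s2 = t2["ihs_unstd"].to_numpy()
        both = ~np.isnan(s1) & ~np.isnan(s2)
        assert both.any()
        np.testing.assert_allclose(s1[both], -s2[both], atol=1e-12)

    def test_uniform_map_rescaling_leaves_scores_unchanged(self):
        """iHH scales by c under a rescaled map; the log-ratio does not move."""
        rng = np.random.default_rng(5)
        A = (rng.random((80, 16)) < 0.5).astype(np.uint8)
        pos = np.sort(rng.choice(1_500_000, 80, replace=False))
        hm = HaplotypeMatrix(pos, A)
        m1 = maps.RecombinationMap("1", [0], [2_000_000], [1e-8])
        m5 = maps.RecombinationMap("1", [0], [2_000_000], [5e-8])
        t1 = ihs.ihs_scores(hm, m1)
        t5 = ihs.ihs_scores(hm, m5)
        ok = t1["ihs_unstd"].notna() & t5["ihs_unstd"].notna()
        np.testing.assert_allclose(
            t5.loc[ok, "ihh_derived"], 5 * t1.loc[ok, "ihh_derived"], rtol=1e-9
        )
        np.testing.assert_allclose(
            t5.loc[ok, "ihs_unstd"], t1.loc[ok, "ihs_unstd"], atol=1e-9
        )

    def test_full_scan_equals_brute_force(self, cm_map):
        """Composed scan equals the string-enumeration oracle on small fixtures."""
        for seed in range(6):
            rng = np.random.default_rng(seed)
            A = (rng.random((50, 12)) < rng.uniform(0.3, 0.6)).astype(np.uint8)
            pos = np.sort(rng.choice(3_000_000, 50, replace=False))
            got = ihs.ihs_scores(HaplotypeMatrix(pos, A), cm_map)
            want = brute_force_ihs_table(A, pos, cm_map)
            merged = got.merge(want, on="pos", suffixes=("", "_bf"))
            g = merged["ihs_unstd"].to_numpy()
            b = merged["ihs_unstd_bf"].to_numpy()
            # scored on both sides must agree exactly
            both = ~np.isnan(g) & ~np.isnan(b)
            np.testing.assert_allclose(g[both], b[both], rtol=1e-10)
            assert (np.isnan(g) == np.isnan(b)).all()


class TestStandardize:
    def test_constant_shift_within_bin_removed(self):
        rng = np.random.default_rng(0)
        n = 50
        tab = pd.DataFrame({
            "pos": np.arange(n),
            "derived_freq": np.full(n, 0.42),
            "ihs_unstd": rng.normal(3.7, 1.0, n),  # shifted scores, one bin
            "flag": "",
        })
        out = ihs.standardize_ihs(tab)
        assert out["ihs_std"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["ihs_std"].std(ddof=0) == pytest.approx(1.0)

    def test_two_bin_hand_zscores(self):
        tab = pd.DataFrame({
            "pos": range(6),
            "derived_freq": [0.1, 0.1, 0.1, 0.9, 0.9, 0.9],
            "ihs_unstd": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
            "flag": "",
        })
        out = ihs.standardize_ihs(tab, n_freq_bins=2)
        lo = np.array([1.0, 2.0, 3.0])
        hi = np.array([10.0, 20.0, 30.0])
        np.testing.assert_allclose(
            out["ihs_std"][:3], (lo - lo.mean()) / lo.std(), atol=1e-12
        )
        np.testing.assert_allclose(
            out["ihs_std"][3:], (hi - hi.mean()) / hi.std(), atol=1e-12
        )

    def test_undersized_bin_merged_with_neighbor(self):
        tab = pd.DataFrame({
            "pos": range(5),
            "derived_freq": [0.1, 0.1, 0.1, 0.1, 0.92],
            "ihs_unstd": [1.0, 2.0, 3.0, 4.0, 9.0],
            "flag": "",
        })
        out = ihs.standardize_ihs(tab, n_freq_bins=10)
        assert out["ihs_std"].notna().all()
        # all 5 standardized together
        assert out["ihs_std"].mean() == pytest.approx(0.0, abs=1e-12)


class TestTopHitsAndGenes:
    def test_fraction_one_returns_all(self):
        tab = pd.DataFrame({
            "pos": range(10), "ihs_std": np.linspace(-2, 2, 10),
        })
        assert len(ihs.top_hits(tab, 1.0)) == 10

    def test_two_hundred_sites_top_percent(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200)
        tab = pd.DataFrame({"pos": range(200), "ihs_std": scores})
        hits = ihs.top_hits(tab, 0.01)
        assert len(hits) >= 2
        thr = np.quantile(np.abs(scores), 0.99, method="higher")
        assert set(hits["pos"]) == set(np.flatnonzero(np.abs(scores) >= thr))

    def test_total_tie_returns_everything(self):
        tab = pd.DataFrame({"pos": range(7), "ihs_std": np.full(7, 1.5)})
        assert len(ihs.top_hits(tab, 0.01)) == 7

    def test_gene_annotation_brute_force(self):
        genes = pd.DataFrame({
            "chrom": "1",
            "start": [100, 500, 900, 2000],
            "end": [300, 700, 1500, 2100],
            "symbol": ["G1", "G2", "G3", "G4"],
        })
        sites = np.array([150, 750, 1000, 1499, 3000])
        got = ihs.annotate_genes(sites, genes, chrom="1")
        want = set()
        for _, g in genes.iterrows():
            if any(g.start <= s < g.end for s in sites):
                want.add(g.symbol)
        assert got == want == {"G1", "G3"}

    def test_site_in_intergenic_space_empty(self):
        genes = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200], "symbol": ["G"]})
        assert ihs.annotate_genes(np.array([500]), genes) == set()

    def test_gene_ranges_format_error_with_line(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("1 100 200 G1\n1 300 G2\n")
        with pytest.raises(ValueError, match="line 2"):
            ihs.read_gene_ranges(p)


@pytest.fixture(scope="module")
def scored_table():
    rng = np.random.default_rng(2)
    n = 400
    return pd.DataFrame({
        "pos": np.sort(rng.choice(10_000_000, n, replace=False)),
        "derived_freq": rng.uniform(0.05, 0.95, n),
        "ihs_unstd": rng.normal(size=n),
        "flag": "",
        "ihs_std": rng.normal(size=n),
    })


@pytest.fixture(scope="module")
def genes():
    return simulate.generate_gene_ranges("1", 10_000_000, 200, seed=0)


class TestCompareRuns:
    def test_identical_tables_full_overlap(self, scored_table, genes):
        rep = ihs.compare_runs(scored_table, scored_table, genes, 0.05)
        assert rep["overlap_fraction"] == 1.0
        assert rep["n_unique_a"] == rep["n_unique_b"] == 0
        assert rep["pearson_r"] == pytest.approx(1.0)

    def test_negated_table_antisymmetry(self, scored_table, genes):
        neg = scored_table.assign(ihs_std=-scored_table["ihs_std"])
        rep = ihs.compare_runs(scored_table, neg, genes, 0.05)
        assert rep["pearson_r"] == pytest.approx(-1.0)
        assert rep["overlap_fraction"] == 1.0  # |iHS| top sets identical

    def test_disjoint_sites_rejected(self, scored_table, genes):
        other = scored_table.copy()
        other["pos"] = other["pos"] + 1
        with pytest.raises(ValueError, match="share"):
            ihs.compare_runs(scored_table, other, genes, 0.05)


class TestHaplotypeIO:
    def test_tsv_roundtrip(self, tmp_path, small_cohort):
        p = tmp_path / "h.tsv"
        small_cohort.write_hap_tsv(p)
        hm = HaplotypeMatrix.read_tsv(p)
        np.testing.assert_array_equal(hm.alleles, small_cohort.haplotypes)
        np.testing.assert_array_equal(hm.positions, small_cohort.site_positions)

    def test_vcf_roundtrip(self, tmp_path, small_cohort):
        p = tmp_path / "h.vcf"
        small_cohort.write_vcf(p)
        hm = HaplotypeMatrix.read_vcf(p)
        np.testing.assert_array_equal(hm.alleles, small_cohort.haplotypes)
        np.testing.assert_array_equal(hm.positions, small_cohort.site_positions)
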