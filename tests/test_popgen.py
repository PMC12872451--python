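"""Heterozygosity, distances/UPGMA, FST, f-statistics, jackknife, continuity, TT scaffold."""

import numpy as np
import pandas as pd
import pytest

from sapiens_catalog import polarize as pol
from sapiens_catalog import popgen
from sapiens_catalog import simulate as sim
from sapiens_catalog.datatypes import (
    ALLELE_ABSENT,
    ChromTable,
    GenotypePanel,
    IndividualMeta,
    PanelError,
)

from conftest import make_dd, random_dd


def _diploid_panel(genos, ids=None, chrom="1"):
    """Panel from a (sites x individuals) list of 'ab' genotype strings (0/1/.)"""
    n_sites = len(genos)
    n_ind = len(genos[0])
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": (np.arange(n_sites) + 1) * 10, "ref": "A", "alt": "C"}
    )
    calls = np.zeros((n_sites, n_ind, 2), dtype=np.int8)
    for i, row in enumerate(genos):
        for j, g in enumerate(row):
            for s, ch in enumerate(g):
                calls[i, j, s] = -1 if ch == "." else int(ch)
    ids = ids or [f"i{j}" for j in range(n_ind)]
    return GenotypePanel(sites, calls, [IndividualMeta(id=i, group=i) for i in ids])


class TestHeterozygosity:
    def test_all_homozygous_is_zero(self):
        panel = _diploid_panel([["00"], ["11"], ["00"]])
        assert popgen.heterozygosity(panel, "i0") == 0.0

    def test_simple_ratio(self):
        genos = [["01"], ["01"]] + [["00"]] * 7 + [["11"]]
        panel = _diploid_panel(genos)
        assert popgen.heterozygosity(panel, "i0") == pytest.approx(0.2)

    def test_missing_genotypes_excluded(self):
        panel = _diploid_panel([["01"], ["0."], [".."], ["00"]])
        assert popgen.heterozygosity(panel, "i0") == pytest.approx(0.5)

    def test_hwe_expectation_recovered(self):
        """Genotypes at HWE with p = 0.3 -> het rate 2p(1-p) = 0.42."""
        rng = np.random.default_rng(42)
        n = 50_000
        p = 0.3
        g = rng.binomial(1, p, size=(n, 2)).astype(np.int8)
        sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, n + 1), "ref": "A", "alt": "C"})
        panel = GenotypePanel(sites, g[:, None, :], [IndividualMeta(id="x", group="g")])
        expected = 2 * p * (1 - p)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(popgen.heterozygosity(panel, "x") - expected) < 3 * se


class TestPairwiseDistances:
    def test_identical_genomes_distance_zero(self, chrom_table):
        panel = _diploid_panel([["00", "00"], ["11", "11"], ["01", "01"]])
        dm = popgen.pairwise_distances(panel, chrom_table)
        assert dm.matrix[0, 1] == 0.0

    def test_one_in_thousand_differs(self, chrom_table):
        genos = [["00", "00"]] * 999 + [["00", "11"]]
        dm = popgen.pairwise_distances(_diploid_panel(genos), chrom_table)
        assert dm.matrix[0, 1] == pytest.approx(1e-3)

    def test_two_chromosome_weighting(self):
        table = ChromTable({"1": 30_000_000, "2": 10_000_000})
        genos_1 = [["00", "11"], ["00", "00"]]  # chrom 1: d = 0.5
        genos_2 = [["00", "11"], ["00", "11"]]  # chrom 2: d = 1.0
        p1 = _diploid_panel(genos_1, chrom="1")
        p2 = _diploid_panel(genos_2, chrom="2")
        sites = pd.concat([p1.sites, p2.sites], ignore_index=True)
        calls = np.concatenate([p1.calls, p2.calls])
        panel = GenotypePanel(sites, calls, p1.individuals)
        dm = popgen.pairwise_distances(panel, table)
        assert dm.matrix[0, 1] == pytest.approx(0.75 * 0.5 + 0.25 * 1.0)
        assert sum(dm.weights.values()) == pytest.approx(1.0)

    def test_symmetry_and_zero_diagonal(self, rng, chrom_table):
        panel, _ = sim.simulate_panel(sim.preset_two_pop(n_per_group=4, n_sites=300, seed=9))
        dm = popgen.pairwise_distances(panel, chrom_table, panel.ids_in_group("pop1"))
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)


class TestUpgma:
    def test_two_leaves_split_distance(self):
        nwk = popgen.upgma(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert nwk == "(A:0.5,B:0.5);"

    def test_recovers_constructed_ultrametric_tree(self):
        """((A,B),(C,D)) with heights 1 and 3: distances 2 within pairs, 6 across."""
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        nwk = popgen.upgma(labels, d)
        assert nwk == "((A:1,B:1):2,(C:1,D:1):2);"

    def test_tie_broken_by_lexicographic_pair(self):
        # all distances equal: first merge must be (A, B)
        d = np.ones((3, 3)) - np.eye(3)
        nwk = popgen.upgma(["C", "A", "B"], d[[1, 2, 0]][:, [1, 2, 0]] if False else d)
        assert nwk.startswith("((A:0.5,B:0.5)")

    def test_ultrametric_output(self, rng, chrom_table):
        panel, _ = sim.simulate_panel(sim.preset_two_pop(n_per_group=3, n_sites=400, seed=5))
        ids = panel.ids_in_group("pop1") + panel.ids_in_group("pop2")
        dm = popgen.pairwise_distances(panel, chrom_table, ids)
        import skbio

        tree = skbio.TreeNode.read([popgen.upgma(dm.labels, dm.matrix)])
        depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_nan_rejected(self):
        with pytest.raises(PanelError):
            popgen.upgma(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))


def brute_force_wc_fst(dosage, called, idx_a, idx_b):
    """Straight transcription of the two-population variance components."""
    thetas, nums, dens = [], [], []
    for i in range(dosage.shape[0]):
        ns, ps, hs = [], [], []
        for idx in (idx_a, idx_b):
            g = [dosage[i, j] for j in idx if called[i, j] == 2]
            if len(g) < 1:
                ns = None
                break
            ns_i = len(g)
            ps.append(sum(g) / (2 * ns_i))
            hs.append(sum(1 for x in g if x == 1) / ns_i)
            ns = ns if ns is None else ns + [ns_i] if isinstance(ns, list) else [ns_i]
        if ns is None:
            thetas.append(np.nan)
            continue
        n1, n2 = ns
        p1, p2 = ps
        h1, h2 = hs
        r = 2
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        if nbar <= 1:
            thetas.append(np.nan)
            continue
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        if a + b + c == 0 or not np.isfinite(a + b + c):
            thetas.append(np.nan)
            continue
        thetas.append(a / (a + b + c))
        nums.append(a)
        dens.append(a + b + c)
    return np.array(thetas), sum(nums) / sum(dens)


class TestWeirCockerhamFst:
    def test_per_site_matches_brute_force(self, rng):
        dd = random_dd(rng, n_sites=200, n_ind=10, missing=0.1)
        res = popgen.weir_cockerham_fst(dd, dd.ids[:5], dd.ids[5:])
        expected, weighted = brute_force_wc_fst(
            dd.dosage.astype(np.float64), dd.called, range(5), range(5, 10)
        )
        np.testing.assert_allclose(
            np.nan_to_num(res.per_site, nan=-9), np.nan_to_num(expected, nan=-9), atol=1e-12
        )
        assert res.weighted == pytest.approx(weighted, abs=1e-12)

    def test_fixed_difference_per_site_near_one(self):
        dosage = np.tile(np.array([[2.0] * 20 + [0.0] * 20]), (5, 1))
        dd = make_dd(dosage)
        res = popgen.weir_cockerham_fst(dd, dd.ids[:20], dd.ids[20:])
        assert res.per_site[0] == pytest.approx(1.0)

    def test_null_simulation_centred_at_zero(self):
        """Same allele frequencies in both groups -> aggregate near 0."""
        rng = np.random.default_rng(7)
        n_sites, n = 20_000, 20
        p = rng.uniform(0.1, 0.9, n_sites)
        dosage = rng.binomial(2, p[:, None], size=(n_sites, 2 * n)).astype(np.float32)
        dd = make_dd(dosage)
        res = popgen.weir_cockerham_fst(dd, dd.ids[:n], dd.ids[n:])
        assert abs(res.weighted) < 0.01

    def test_aggregate_within_per_site_envelope(self, rng):
        dd = random_dd(rng, n_sites=150, n_ind=12, missing=0.05)
        res = popgen.weir_cockerham_fst(dd, dd.ids[:6], dd.ids[6:])
        assert np.nanmin(res.per_site) <= res.weighted <= np.nanmax(res.per_site)

    def test_balding_nichols_parameter_recovery(self):
        """F = 0.05 recovered by the weighted aggregate within [0.04, 0.06]."""
        panel, _ = sim.simulate_panel(sim.preset_two_pop(F=0.05, n_per_group=25, n_sites=50_000, seed=2))
        dd = pol.derived_dosage(panel, pol.assign_ancestral_panel(panel))
        res = popgen.weir_cockerham_fst(dd, panel.ids_in_group("pop1"), panel.ids_in_group("pop2"))
        assert 0.04 <= res.weighted <= 0.06


def brute_force_block_jackknife(values, blocks):
    """Textbook weighted delete-one-block jackknife (independent transcription)."""
    values = np.asarray(values, float)
    blocks = np.asarray(blocks)
    uniq = [b for b in np.unique(blocks) if (blocks == b).sum() > 0]
    theta = values.mean()
    n = len(values)
    loo, m = [], []
    for b in uniq:
        keep = blocks != b
        loo.append(values[keep].mean())
        m.append((~keep).sum())
    loo, m = np.array(loo), np.array(m, float)
    g = len(uniq)
    h = n / m
    theta_J = g * theta - ((1 - m / n) * loo).sum()
    tau = h * theta - (h - 1) * loo
    var = np.sum((tau - theta_J) ** 2 / (h - 1)) / g
    return theta, np.sqrt(var)


class TestBlockJackknife:
    def test_identical_values_zero_se(self, chrom_table):
        n = 100
        est = popgen.block_jackknife(
            np.full(n, 0.3), np.repeat("1", n), np.arange(1, n + 1) * 900_000, chrom_table
        )
        assert est.se == pytest.approx(0.0, abs=1e-15)
        assert est.value == pytest.approx(0.3)

    def test_two_equal_blocks_closed_form(self, chrom_table):
        # 2 blocks of 2 sites; leave-one-out values v1, v2 -> SE = |v1 - v2| / 2
        values = np.array([1.0, 3.0, 2.0, 6.0])
        pos = np.array([1, 2, 5_000_001, 5_000_002])
        est = popgen.block_jackknife(values, np.repeat("1", 4), pos, chrom_table)
        v1 = values[2:].mean()  # leave block 1 out
        v2 = values[:2].mean()
        assert est.se == pytest.approx(abs(v1 - v2) / 2)

    def test_matches_independent_implementation(self, rng, chrom_table):
        n = 500
        values = rng.normal(size=n)
        chroms = np.where(np.arange(n) < 250, "1", "2")
        positions = (np.arange(n) % 250 + 1) * 150_000
        est = popgen.block_jackknife(values, chroms, positions, chrom_table)
        blocks = popgen.assign_blocks(chroms, positions)
        theta, se = brute_force_block_jackknife(values, blocks)
        assert est.value == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_single_block_rejected(self, chrom_table):
        with pytest.raises(PanelError):
            popgen.block_jackknife(
                np.ones(10), np.repeat("1", 10), np.arange(1, 11), chrom_table
            )


class TestFStatistics:
    def _dd(self, rng, n_sites=500):
        return random_dd(rng, n_sites=n_sites, n_ind=16, missing=0.1)

    def test_f4_identity_zero_for_repeated_group(self, rng, chrom_table):
        dd = self._dd(rng)
        groups = [dd.ids[:4], dd.ids[:4], dd.ids[8:12], dd.ids[12:]]
        est = popgen.f4(dd, *groups, chrom_table)
        assert est.value == 0.0

    def test_f4_antisymmetry_and_pair_swap(self, rng, chrom_table):
        dd = self._dd(rng)
        a, b, c, d = dd.ids[:4], dd.ids[4:8], dd.ids[8:12], dd.ids[12:]
        e1 = popgen.f4(dd, a, b, c, d, chrom_table)
        e2 = popgen.f4(dd, b, a, c, d, chrom_table)
        e3 = popgen.f4(dd, c, d, a, b, chrom_table)
        assert e1.value == pytest.approx(-e2.value, abs=1e-15)
        assert e1.value == pytest.approx(e3.value, abs=1e-15)

    def test_f4_brute_force_site_loop(self, rng, chrom_table):
        dd = self._dd(rng)
        a, b, c, d = dd.ids[:4], dd.ids[4:8], dd.ids[8:12], dd.ids[12:]
        est = popgen.f4(dd, a, b, c, d, chrom_table)
        total, n = 0.0, 0
        for i in range(dd.n_sites):
            freqs = []
            for ids in (a, b, c, d):
                dsum = csum = 0
                for j in dd.indices_of(ids):
                    if dd.called[i, j] > 0:
                        dsum += float(dd.dosage[i, j])
                        csum += int(dd.called[i, j])
                freqs.append(dsum / csum if csum else np.nan)
            v = (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])
            if not np.isnan(v):
                total += v
                n += 1
        assert est.value == pytest.approx(total / n, abs=1e-12)

    def test_f3_brute_force_and_target_identity(self, rng, chrom_table):
        dd = self._dd(rng)
        t, a, b = dd.ids[:4], dd.ids[4:8], dd.ids[8:12]
        est = popgen.f3_vanilla(dd, t, a, b, chrom_table)
        pt = dd.group_frequency(t)
        pa = dd.group_frequency(a)
        pb = dd.group_frequency(b)
        vals = (pt - pa) * (pt - pb)
        assert est.value == pytest.approx(np.nanmean(vals), abs=1e-12)
        same = popgen.f3_vanilla(dd, t, t, b, chrom_table)
        assert same.value == 0.0

    def test_f3_admixed_target_significantly_negative(self):
        panel, _ = sim.simulate_panel(sim.preset_admixture(alpha=0.5, n_sites=30_000, seed=3))
        dd = pol.derived_dosage(panel, pol.assign_ancestral_panel(panel))
        ct = ChromTable({"1": 50_000_000, "2": 50_000_000})
        est = popgen.f3_vanilla(
            dd, panel.ids_in_group("target"), panel.ids_in_group("srcA"), panel.ids_in_group("srcB"), ct
        )
        assert est.value < 0
        assert est.z < -3

    def test_f4_clean_tree_consistent_with_zero(self):
        """Outgroup-anchored quartet on an unadmixed tree: |Z| < 3."""
        cfg = sim.preset_study_panel(n_sites=20_000, seed=11)
        panel, _ = sim.simulate_panel(cfg)
        dd = pol.derived_dosage(panel, pol.assign_ancestral_panel(panel))
        ct = cfg.chrom_table()
        est = popgen.f4(
            dd,
            ["archaic_4"],  # the Denisovan
            ["ancient_southern_1"],
            panel.ids_in_group("panel_1kgp")[24:32],  # an eastern population
            panel.ids_in_group("panel_1kgp")[:8],  # a western population
            ct,
        )
        assert abs(est.z) < 3

    def test_archaic_polymorphic_ascertainment_restricts_sites(self):
        cfg = sim.preset_study_panel(n_sites=4_000, seed=13)
        panel, _ = sim.simulate_panel(cfg)
        dd = pol.derived_dosage(panel, pol.assign_ancestral_panel(panel))
        mask = popgen.archaic_polymorphic_mask(dd, "archaic_1", "archaic_4")
        assert 0 < mask.sum() < dd.n_sites
        i1, i4 = dd.indices_of(["archaic_1", "archaic_4"])
        for i in np.flatnonzero(mask)[:50]:
            d = dd.dosage[i, i1] + dd.dosage[i, i4]
            c = dd.called[i, i1] + dd.called[i, i4]
            assert 0 < d < c


class TestContinuity:
    def test_anchor_probed_against_itself_is_half(self, rng):
        dd = random_dd(rng, n_sites=300, n_ind=4, missing=0.1)
        est = popgen.continuity_statistic(dd, "i0", "i0")
        assert est.value == 0.5

    def test_same_population_pair_near_half(self):
        """Constant-size, no-admixture population with a symmetric frequency
        spectrum: drift is a martingale, so the statistic stays at 1/2."""
        cfg = sim.preset_single_population(n_sites=20_000, seed=21)
        panel, _ = sim.simulate_panel(cfg)
        dd = pol.derived_dosage(panel, pol.assign_ancestral_panel(panel))
        probes = panel.ids_in_group("pop")[1:]
        est = popgen.continuity_statistic(dd, "pop_1", probes)
        assert abs(est.value - 0.5) < 3 * est.se

    def test_value_in_unit_interval(self, rng):
        dd = random_dd(rng, n_sites=200, n_ind=6, missing=0.2)
        est = popgen.continuity_statistic(dd, "i0", ["i1", "i2"])
        assert 0.0 <= est.value <= 1.0

    def test_no_het_sites_rejected(self):
        dd = make_dd(np.zeros((10, 2)))
        with pytest.raises(PanelError):
            popgen.continuity_statistic(dd, "i0", "i1")


class TestTtSiteFilter:
    def _cfg(self):
        return popgen.DivergenceConfig()

    def test_qual_boundary_fails(self):
        sites = pd.DataFrame({"qual": [30.0, 30.5]})
        depths = np.full((2, 2), 10.0)
        ad = np.full((2, 2), 5.0)
        ok, reasons = popgen.tt_site_filter(sites, depths, ad, self._cfg())
        assert list(ok) == [False, True]
        assert reasons[0] == "qual"

    def test_allele_depth_below_minimum_fails(self):
        sites = pd.DataFrame({"qual": [40.0]})
        ok, reasons = popgen.tt_site_filter(
            sites, np.full((1, 2), 10.0), np.array([[3.0, 5.0]]), self._cfg()
        )
        assert reasons == ["depth"]

    def test_staged_truth_table(self, rng):
        n = 50
        qual = rng.uniform(10, 60, n)
        depths = rng.integers(1, 40, size=(n, 2)).astype(float)
        ad = rng.integers(0, 12, size=(n, 2)).astype(float)
        anc_ok = rng.random(n) < 0.8
        sites = pd.DataFrame({"qual": qual})
        cfg = self._cfg()
        ok, reasons = popgen.tt_site_filter(sites, depths, ad, cfg, anc_ok)
        lo = np.percentile(depths, 5, axis=0)
        hi = np.percentile(depths, 95, axis=0)
        for i in range(n):
            expected = (
                qual[i] > 30
                and anc_ok[i]
                and all(lo[j] <= depths[i, j] <= hi[j] for j in range(2))
                and all(ad[i, j] >= 4 for j in range(2))
            )
            assert ok[i] == expected


class TestTwoByTwoSfs:
    def test_identical_ancestral_genomes_all_mass_at_origin(self, chrom_table):
        dos = np.zeros(20)
        pos = (np.arange(20) + 1) * 400_000
        tt = popgen.two_by_two_sfs(dos, dos, np.repeat("1", 20), pos, chrom_table)
        assert tt.counts[0, 0] == 20
        assert tt.counts.sum() == 20

    def test_hand_built_six_site_fixture(self, chrom_table):
        dos1 = np.array([0, 1, 2, 1, 0, 2], float)
        dos2 = np.array([0, 0, 2, 1, 2, 0], float)
        pos = (np.arange(6) + 1) * 100
        tt = popgen.two_by_two_sfs(dos1, dos2, np.repeat("1", 6), pos, chrom_table)
        expected = np.zeros((3, 3))
        for a, b in zip(dos1, dos2):
            expected[int(a), int(b)] += 1
        assert np.array_equal(tt.counts, expected)

    def test_marginals_equal_single_genome_spectra(self, rng, chrom_table):
        dos1 = rng.integers(0, 3, 100).astype(float)
        dos2 = rng.integers(0, 3, 100).astype(float)
        pos = (np.arange(100) + 1) * 10_000
        tt = popgen.two_by_two_sfs(dos1, dos2, np.repeat("1", 100), pos, chrom_table)
        for k in range(3):
            assert tt.counts[k, :].sum() == (dos1 == k).sum()
            assert tt.counts[:, k].sum() == (dos2 == k).sum()

    def test_zero_informative_rejected(self, chrom_table):
        with pytest.raises(PanelError):
            popgen.two_by_two_sfs(
                np.array([np.nan]), np.array([1.0]), np.array(["1"]), np.array([5]), chrom_table
            )


class TestEstimateDivergence:
    def test_rescaling_arithmetic(self):
        """A spectrum engineered to give T = 10,000 generations -> 290,000 years."""
        cfg = popgen.DivergenceConfig()  # mu = 1.45e-8, g = 29
        table = ChromTable({"1": 10_000_000})
        n_fixed_diff = int(round(2 * cfg.mutation_rate * 10_000 * table.total_length))
        pos = np.linspace(1, 10_000_000, n_fixed_diff).astype(int)
        dos1 = np.full(n_fixed_diff, 2.0)
        dos2 = np.zeros(n_fixed_diff)
        tt = popgen.two_by_two_sfs(dos1, dos2, np.repeat("1", n_fixed_diff), pos, table)
        est = popgen.estimate_divergence(tt, cfg)
        assert est.t_generations == pytest.approx(10_000, rel=1e-3)
        assert est.t_years == pytest.approx(est.t_generations * 29)

    def test_split_recovery_within_jackknife_ci(self):
        """Coalescent truth tau = 1,000 generations (tau/2N = 0.05) recovered."""
        from sapiens_catalog.coalescent import simulate_split_pair

        d1, d2, ch, pos, ct = simulate_split_pair(
            1_000, ne=10_000, chrom_length=20e6, n_chrom=2, seed=11
        )
        tt = popgen.two_by_two_sfs(d1, d2, ch, pos, ct)
        est = popgen.estimate_divergence(tt, popgen.DivergenceConfig())
        lo, hi = est.ci95_generations()
        assert lo <= 1_000 <= hi

    def test_degenerate_sfs_rejected(self):
        table = ChromTable({"1": 1_000})
        with pytest.raises(PanelError):
            tt = popgen.TwoByTwoSfs(
                counts=np.zeros((3, 3)),
                block_counts=np.zeros((1, 3, 3)),
                block_lengths=np.array([1000.0]),
                total_length=1000.0,
            )
            popgen.estimate_divergence(tt, popgen.DivergenceConfig())
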